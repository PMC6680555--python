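import numpy as np
import pytest

import spectrafuse as sf
from spectrafuse.fuse import FusionDecision, fuzzy_vote, high_level_fuse, low_level_fuse, mid_level_fuse
from spectrafuse.select import SelectionResult
from spectrafuse.metrics_report import accuracy, confusion_counts


class TestLowLevelFuse:
    def test_full_scale_width(self):
        mir, nir = sf.simulate_blocks(seed=2)  # study-scale defaults
        fused, prov = low_level_fuse(mir, nir)
        assert fused.shape == (196, 2695)
        assert len(prov) == 2695
        assert prov[0][0] == "FTMIR" and prov[-1][0] == "NIR"

    def test_misaligned_ids_rejected(self, small_blocks):
        mir, nir = small_blocks
        nir2 = sf.SpectralBlock(nir.modality, nir.grid, nir.X,
                                [f"X{i}" for i in range(nir.n_samples)], nir.labels)
        with pytest.raises(ValueError, match="row-aligned"):
            low_level_fuse(mir, nir2)

    def test_column_order_does_not_change_predictions(self, small_blocks):
        from spectrafuse.models import fit_rf
        mir, nir = small_blocks
        ab, _ = low_level_fuse(mir, nir)
        ba, _ = low_level_fuse(nir, mir)
        y = mir.labels
        # same columns, different order; identical forests modulo column
        # identity are not guaranteed, but accuracy should agree closely
        acc_ab = np.mean(fit_rf(ab[:98], y[:98], n_tree=150, seed=5).predict(ab[98:]) == y[98:])
        acc_ba = np.mean(fit_rf(ba[:98], y[:98], n_tree=150, seed=5).predict(ba[98:]) == y[98:])
        assert abs(acc_ab - acc_ba) <= 0.05


class TestMidLevelFuse:
    def test_widths_add(self, small_blocks):
        mir, nir = small_blocks
        sa = SelectionResult(method="rfe", indices=np.arange(10))
        sb = SelectionResult(method="rfe", indices=np.arange(25))
        fused = mid_level_fuse(sa, mir, sb, nir)
        assert fused.shape == (mir.n_samples, 35)

    def test_all_columns_reduces_to_low_level(self, small_blocks):
        mir, nir = small_blocks
        sa = SelectionResult(method="rfe", indices=np.arange(mir.n_variables))
        sb = SelectionResult(method="rfe", indices=np.arange(nir.n_variables))
        fused = mid_level_fuse(sa, mir, sb, nir)
        low, _ = low_level_fuse(mir, nir)
        assert np.array_equal(fused, low)

    def test_pcs_route_width_is_kept_components(self, small_blocks):
        from spectrafuse.select import pca_extract
        mir, nir = small_blocks
        sa, sb = pca_extract(mir.X), pca_extract(nir.X)
        fused = mid_level_fuse(sa, mir, sb, nir)
        assert fused.shape[1] == sa.n_kept + sb.n_kept

    def test_empty_selection_rejected(self, small_blocks):
        mir, nir = small_blocks
        sa = SelectionResult(method="rfe", indices=np.array([], dtype=int))
        sb = SelectionResult(method="rfe", indices=np.arange(3))
        with pytest.raises(ValueError, match="empty selection"):
            mid_level_fuse(sa, mir, sb, nir)


class TestFuzzyVote:
    def test_unanimous(self):
        a = np.array([0.9, 0.05, 0.05])
        d = fuzzy_vote(a, a)
        assert d.final == frozenset({1}) and not d.multiple
        assert all(v == frozenset({1}) for v in d.operator_votes.values())

    def test_three_vs_one_plurality(self):
        # min/product/average favor class 3; max alone favors class 5
        a = np.array([0.15, 0.05, 0.70, 0.05, 0.05])
        b = np.array([0.00, 0.00, 0.28, 0.00, 0.72])
        d = fuzzy_vote(a, b)
        votes = list(d.operator_votes.values())
        assert votes.count(frozenset({3})) == 3
        assert votes.count(frozenset({5})) == 1
        assert d.final == frozenset({3})

    def test_eps_tie_two_class_vote(self):
        a = np.array([0.50, 0.49, 0.01])
        d = fuzzy_vote(a, a, eps=0.01)
        assert all(v == frozenset({1, 2}) for v in d.operator_votes.values())
        assert d.final == frozenset({1, 2}) and d.multiple

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_vote(np.ones(3) / 3, np.ones(4) / 4)

    def test_operator_consistency_on_equal_inputs(self, rng):
        for _ in range(20):
            a = rng.dirichlet(np.ones(5))
            d = fuzzy_vote(a, a, eps=0.0)
            sets = set(d.operator_votes.values())
            assert len(sets) == 1
            assert d.final == next(iter(sets))

    def test_class_permutation_equivariance(self, rng):
        a, b = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
        d = fuzzy_vote(a, b)
        perm = np.array([2, 0, 3, 1])
        dp = fuzzy_vote(a[perm], b[perm])
        relabel = {old + 1: int(np.where(perm == old)[0][0]) + 1 for old in range(4)}
        assert dp.final == frozenset(relabel[c] for c in d.final)

    def test_monotonicity_raising_a_class_keeps_it(self, rng):
        for _ in range(20):
            a, b = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
            d = fuzzy_vote(a, b)
            c = next(iter(d.final)) - 1
            a2, b2 = a.copy(), b.copy()
            a2[c] += 0.2
            b2[c] += 0.2
            d2 = fuzzy_vote(a2, b2)
            for op in d.operator_votes:
                if c + 1 in d.operator_votes[op]:
                    assert c + 1 in d2.operator_votes[op]

    def test_eps_zero_average_equals_argmax_of_mean(self, rng):
        for _ in range(30):
            a, b = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
            d = fuzzy_vote(a, b, eps=0.0)
            assert d.operator_votes["average"] == frozenset({int(np.argmax(a + b)) + 1})

    def test_inconsistent_flag_rejected(self):
        with pytest.raises(ValueError):
            FusionDecision(operator_votes={"min": frozenset({1})},
                           final=frozenset({1}), multiple=True)


class TestHighLevelFuse:
    def test_multiple_discrimination_semantics(self):
        # true class 1 predicted {1, 4}: counted correct, FP for class 4
        A = np.array([[0.5, 0.0, 0.0, 0.5, 0.0]])
        B = np.array([[0.5, 0.0, 0.0, 0.5, 0.0]])
        dec = high_level_fuse(A, B, true_labels=np.array([1]))
        assert dec[0].final == frozenset({1, 4})
        sets = [set(d.final) for d in dec]
        assert accuracy([1], sets) == 1.0
        cm = confusion_counts([1], sets, classes=[1, 2, 3, 4, 5])
        assert cm[1].tp == 1 and cm[4].fp == 1

    def test_confident_agreement_perfect(self, rng):
        n, K = 30, 5
        y = rng.integers(1, K + 1, n)
        S = np.zeros((n, K))
        S[np.arange(n), y - 1] = 1.0
        dec = high_level_fuse(S, S, true_labels=y)
        sets = [set(d.final) for d in dec]
        assert accuracy(y, sets) == 1.0
        cm = confusion_counts(y, sets, classes=list(range(1, K + 1)))
        assert all(cm[c].fp == 0 for c in cm)

    def test_accuracy_equals_manual_recount(self, rng):
        n, K = 40, 4
        y = rng.integers(1, K + 1, n)
        A = rng.dirichlet(np.ones(K), size=n)
        B = rng.dirichlet(np.ones(K), size=n)
        dec = high_level_fuse(A, B, true_labels=y)
        sets = [set(d.final) for d in dec]
        manual = sum(1 for t, s in zip(y, sets) if t in s) / n
        assert accuracy(y, sets) == manual

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            high_level_fuse(np.ones((3, 4)) / 4, np.ones((2, 4)) / 4)
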