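import numpy as np
import pytest

from spectrafuse.models import fit_plsda, vip
from spectrafuse.select import (
    SelectionResult,
    boruta_select,
    pca_extract,
    rfe_select,
    vip_select,
)


class TestPcaExtract:
    def test_two_correlated_variables_one_component(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x + 1])
        sel = pca_extract(X)
        assert sel.n_kept == 1
        assert np.allclose(sorted(sel.eigenvalues, reverse=True), [2.0, 0.0], atol=1e-10)

    def test_eigenvalue_sum_is_p(self, rng):
        X = rng.normal(size=(200, 5))
        sel = pca_extract(X)
        assert np.isclose(sel.eigenvalues.sum(), 5.0)
        # isotropic noise: roughly half the eigenvalues exceed 1
        assert 1 <= sel.n_kept <= 4

    def test_matches_independent_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.2])
        sel = pca_extract(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        # oracle: eigendecomposition of the correlation matrix
        C = np.corrcoef(X, rowvar=False)
        w, V = np.linalg.eigh(C)
        w, V = w[::-1], V[:, ::-1]
        assert np.allclose(sel.eigenvalues, w * (10 - 1) / (10 - 1), atol=1e-8)
        k = sel.n_kept
        scores = sel.transform(X)
        oracle_scores = Z @ V[:, :k]
        # component signs are arbitrary
        for a in range(k):
            assert (np.allclose(scores[:, a], oracle_scores[:, a], atol=1e-8)
                    or np.allclose(scores[:, a], -oracle_scores[:, a], atol=1e-8))

    def test_kept_count_invariant_to_column_order(self, rng):
        X = rng.normal(size=(50, 8))
        X[:, 0] = X[:, 1] * 2 + rng.normal(scale=0.1, size=50)
        perm = rng.permutation(8)
        assert pca_extract(X).n_kept == pca_extract(X[:, perm]).n_kept

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            sel = pca_extract(X)
        assert np.isclose(sel.eigenvalues.sum(), 3.0)

    def test_projector_reproduces_training_scores(self, rng):
        X = rng.normal(size=(40, 6))
        sel = pca_extract(X)
        assert sel.transform(X).shape == (40, sel.n_kept)


class TestRfeSelect:
    def test_recovers_informative_among_noise(self):
        # 10 informative variables, each individually weak and mutually
        # non-redundant (independent class-mean patterns), so every one is
        # needed to reach the CV error floor; 60 pure-noise distractors
        rng = np.random.default_rng(1)
        n, p_info, p_noise = 120, 10, 60
        y = np.repeat([1, 2, 3], n // 3)
        # equal-strength rotated one-vs-rest patterns: variable j elevates
        # class (j mod 3) + 1 by 0.9 sd -- individually weak, jointly strong
        class_means = np.zeros((p_info, 3))
        for j in range(p_info):
            class_means[j, j % 3] = 0.9
        informative = class_means[:, y - 1].T + rng.normal(size=(n, p_info))
        X = np.hstack([informative, rng.normal(size=(n, p_noise))])
        sel = rfe_select(X, y, step=5, folds=5, seed=1, tune=False, n_tree=150, cv_n_tree=80)
        recovered = np.isin(np.arange(p_info), sel.indices).sum()
        assert recovered >= 8

    def test_curve_length_arithmetic(self, rng):
        n, p = 60, 23
        X = rng.normal(size=(n, p))
        y = np.repeat([1, 2], 30)
        X[y == 2, 0] += 3
        sel = rfe_select(X, y, step=5, folds=3, seed=0, tune=False, n_tree=60, cv_n_tree=40)
        p_min = sel.cv_curve[-1][0]
        assert len(sel.cv_curve) == int(np.ceil((p - p_min) / 5)) + 1
        assert sel.cv_curve[0][0] == p

    def test_all_noise_falls_back_to_small_selection(self, rng):
        X = rng.normal(size=(40, 30))
        y = np.repeat([1, 2], 20)
        sel = rfe_select(X, y, step=5, folds=4, seed=2, tune=False, n_tree=60, cv_n_tree=40)
        assert sel.indices.size >= 1
        assert sel.regions is not None

    def test_step_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            rfe_select(rng.normal(size=(20, 4)), np.repeat([1, 2], 10), step=5)

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(45, 20))
        y = np.repeat([1, 2, 3], 15)
        X[:, 3] += y
        s1 = rfe_select(X, y, step=5, folds=3, seed=7, tune=False, n_tree=50, cv_n_tree=30)
        s2 = rfe_select(X, y, step=5, folds=3, seed=7, tune=False, n_tree=50, cv_n_tree=30)
        assert np.array_equal(s1.indices, s2.indices)
        assert s1.cv_curve == s2.cv_curve


class TestBorutaSelect:
    def test_strong_variable_confirmed_quickly(self):
        rng = np.random.default_rng(1)
        n = 80
        y = np.repeat([1, 2], n // 2)
        X = rng.normal(size=(n, 20))
        X[:, 5] += 3.0 * (y == 2)
        sel = boruta_select(X, y, n_tree=100, max_iter=20, seed=1)
        assert 5 in sel.confirmed

    def test_status_partition(self, rng):
        X = rng.normal(size=(50, 15))
        y = np.repeat([1, 2], 25)
        X[:, 0] += 2.0 * (y == 2)
        sel = boruta_select(X, y, n_tree=80, max_iter=15, seed=3)
        merged = np.sort(np.concatenate([sel.confirmed, sel.tentative, sel.rejected]))
        assert np.array_equal(merged, np.arange(15))
        assert np.array_equal(sel.indices,
                              np.sort(np.concatenate([sel.confirmed, sel.tentative])))

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(40, 12))
        y = np.repeat([1, 2], 20)
        X[:, 2] += 1.5 * (y == 2)
        s1 = boruta_select(X, y, n_tree=60, max_iter=12, seed=9)
        s2 = boruta_select(X, y, n_tree=60, max_iter=12, seed=9)
        assert np.array_equal(s1.indices, s2.indices)
        assert np.array_equal(s1.confirmed, s2.confirmed)


class TestVipSelect:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 8))
        y = np.repeat([1, 2, 3], 20)
        X[:, 0] += 2.0 * (y == 2)
        X[:, 1] -= 2.0 * (y == 3)
        return fit_plsda(X, y, A=2)

    def test_threshold_zero_keeps_all(self, model):
        assert vip_select(model, threshold=0.0).indices.size == 8

    def test_strict_inequality_at_max(self, model):
        scores = vip(model)
        sel = vip_select(model, threshold=float(scores.max()))
        assert sel.indices.size == 0

    def test_matches_brute_force_thresholding(self, model):
        scores = vip(model)
        sel = vip_select(model, threshold=1.0)
        assert np.array_equal(sel.indices, np.flatnonzero(scores > 1.0))


class TestSelectionResult:
    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            SelectionResult(method="rfe", indices=np.array([1, 1, 2]))

    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            SelectionResult(method="pcs", eigenvalues=np.array([1.0, 2.0]))
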