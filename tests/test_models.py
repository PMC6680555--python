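import numpy as np
import pytest

from spectrafuse.models import (
    fit_plsda,
    fit_rf,
    one_hot,
    permutation_test,
    plsda_scores,
    quality_metrics,
    tune_rf,
    vip,
    _smooth_region_ntree,
)


def nipals_pls2(X, Y, A, max_iter=500, tol=1e-12):
    """Independent textbook NIPALS PLS2 oracle (deflation on X and Y)."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    W, T, P, Q = [], [], [], []
    for _ in range(A):
        u = Y[:, [np.argmax(Y.var(axis=0))]]
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t.T @ t)
            u_new = Y @ q / (q.T @ q)
            if np.linalg.norm(u_new - u) < tol * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        p = X.T @ t / (t.T @ t)
        X = X - t @ p.T
        Y = Y - t @ q.T
        W.append(w[:, 0]); T.append(t[:, 0]); P.append(p[:, 0]); Q.append(q[:, 0])
    return (np.column_stack(W), np.column_stack(T),
            np.column_stack(P), np.column_stack(Q))


def separable_data(seed=1, n=60, p=10, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.repeat(np.arange(1, k + 1), n // k)
    for i, c in enumerate(np.unique(y)):
        X[y == c, i] += 4.0
    return X, y


class TestPlsda:
    def test_separable_two_class_single_component(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = np.array([1] * 20 + [2] * 20)
        X[y == 2, 0] += 10.0
        m = fit_plsda(X, y, A=1)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_full_rank_exact_fit(self):
        # at A = rank(X), PLS2 reproduces the least-squares fit: R^2 = 1
        # requires Y within the column space of centered X
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 7))
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        m = fit_plsda(X, y, A=7)
        q = quality_metrics(m, X, y)
        assert q.r2 > 1 - 1e-8

    def test_matches_independent_nipals_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
        m = fit_plsda(X, y, A=3)
        Y = one_hot(y, m.classes)
        W, T, P, Q = nipals_pls2(X.copy(), Y.copy(), 3)
        # component signs are arbitrary; compare predictions instead
        Xc = X - X.mean(axis=0)
        B = W @ np.linalg.inv(P.T @ W) @ Q.T
        Y_oracle = Xc @ B + Y.mean(axis=0)
        assert np.allclose(m.predict_y(X), Y_oracle, atol=1e-8)

    def test_auto_selects_reasonable_A(self):
        X, y = separable_data()
        m = fit_plsda(X, y, A="auto")
        assert 1 <= m.A <= 15

    def test_invalid_A_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError):
            fit_plsda(X, y, A=50)


class TestScores:
    def test_rows_sum_to_one_and_near_one_hot(self):
        X, y = separable_data()
        m = fit_plsda(X, y, A=3)
        s = plsda_scores(m, X)
        assert np.allclose(s.sum(axis=1), 1.0, atol=1e-9)
        assert (s >= 0).all()
        assert np.mean(s.max(axis=1) > 0.5) > 0.9

    def test_argmax_matches_raw_prediction_when_positive(self):
        X, y = separable_data(seed=2)
        m = fit_plsda(X, y, A=3)
        Yp = m.predict_y(X)
        pos = (Yp > 0).all(axis=1)
        s = plsda_scores(m, X)
        assert np.array_equal(np.argmax(s[pos], axis=1), np.argmax(Yp[pos], axis=1))


class TestQualityMetrics:
    def test_rmsep_matches_hand_computation(self):
        X, y = separable_data(seed=4)
        Xv, yv = separable_data(seed=7)
        m = fit_plsda(X, y, A=2)
        q = quality_metrics(m, X, y, Xv, yv)
        Y = one_hot(yv, m.classes)
        expected = np.sqrt(np.sum((m.predict_y(Xv) - Y) ** 2) / Y.size)
        assert np.isclose(q.rmsep, expected)

    def test_q2_not_above_r2(self):
        for seed in range(3):
            X, y = separable_data(seed=seed)
            m = fit_plsda(X, y, A=3)
            q = quality_metrics(m, X, y)
            assert q.q2 <= q.r2 + 1e-9


class TestPermutationTest:
    def test_unpermuted_point_at_corr_one(self):
        X, y = separable_data()
        m = fit_plsda(X, y, A=2)
        q = quality_metrics(m, X, y, seed=1)  # same CV stream as the test below
        res = permutation_test(X, y, A=2, n_perm=3, seed=1, classes_to_test=[1])
        corr, r2, q2 = res.points[0]
        assert corr == 1.0
        assert np.isclose(r2, q.r2) and np.isclose(q2, q.q2)

    def test_separated_data_not_flagged(self):
        X, y = separable_data(seed=1, n=60, p=8)
        res = permutation_test(X, y, A=2, n_perm=20, seed=1, classes_to_test=[1])
        assert res.q2_intercept < 0
        assert not res.overfit


class TestVip:
    def test_sum_of_squares_identity(self):
        X, y = separable_data(seed=6, p=7)
        m = fit_plsda(X, y, A=3)
        v = vip(m)
        assert np.isclose((v**2).sum(), 7, atol=1e-8)

    def test_matches_brute_force_formula(self):
        X, y = separable_data(seed=8, p=5)
        m = fit_plsda(X, y, A=2)
        W, T, Q = m.x_weights, m.x_scores, m.y_loadings
        p, A = W.shape
        ssy = [float(T[:, a] @ T[:, a]) * float(Q[:, a] @ Q[:, a]) for a in range(A)]
        expected = np.array([
            np.sqrt(p * sum(ssy[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2
                            for a in range(A)) / sum(ssy))
            for j in range(p)
        ])
        assert np.allclose(vip(m), expected, atol=1e-10)

    def test_single_component_proportional_to_weights(self):
        X, y = separable_data(seed=9, p=6)
        m = fit_plsda(X, y, A=1)
        w = m.x_weights[:, 0]
        expected = np.sqrt(6) * np.abs(w) / np.linalg.norm(w)
        assert np.allclose(vip(m), expected, atol=1e-10)


class TestRandomForest:
    def test_separated_gaussians_low_oob(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = np.array([1] * 30 + [2] * 30)
        X[y == 2] += 4.0
        f = fit_rf(X, y, n_tree=200, seed=1)
        assert f.oob_error_ < 0.05

    def test_single_tree_oob_partial_coverage(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        y = np.where(X[:, 0] > 0, 1, 2)
        f = fit_rf(X, y, n_tree=1, seed=3)
        covered = (f._oob_votes.sum(axis=1) > 0).mean()
        assert 0.25 < covered < 0.5  # ~ (1 - 1/n)^n ~ 36.8% out of bag
        assert 0.0 <= f.oob_error_ <= 1.0

    def test_score_rows_sum_to_one(self):
        X, y = separable_data(seed=3)
        f = fit_rf(X, y, n_tree=50, seed=1)
        s = f.predict_scores(X)
        assert np.allclose(s.sum(axis=1), 1.0)

    def test_same_seed_reproducible(self):
        X, y = separable_data(seed=5)
        f1 = fit_rf(X, y, n_tree=60, seed=9)
        f2 = fit_rf(X, y, n_tree=60, seed=9)
        assert np.array_equal(f1.oob_curve_, f2.oob_curve_)
        assert np.array_equal(f1.predict_scores(X), f2.predict_scores(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_rf(np.zeros((10, 3)), np.ones(10), n_tree=5)


class TestTuneRf:
    def test_smooth_region_flat_curve_picks_earliest(self):
        curve = np.zeros(50)
        assert _smooth_region_ntree(curve, n_cal=60) == 1

    def test_smooth_region_prefers_longest_run(self):
        # min at t=3 inside a short dip, and again inside a long flat tail
        curve = np.array([0.5, 0.4, 0.1, 0.4, 0.4, 0.1, 0.1, 0.1, 0.1])
        assert _smooth_region_ntree(curve, n_cal=1000) == 6

    def test_tuned_within_tolerance_of_minimum(self):
        X, y = separable_data(seed=11, n=45, p=8)
        cfg = tune_rf(X, y, seed=1, n_tree0=120)
        assert cfg.oob_curve[cfg.n_tree - 1] <= cfg.oob_curve.min() + 0.5 / len(y)

    def test_tuned_oob_not_worse_than_default(self, scenario, scenario_split):
        mir, _, _ = scenario
        cal = scenario_split.indices(mir.sample_ids, "calibration")
        X, y = mir.X[cal], mir.labels[cal]
        cfg = tune_rf(X, y, seed=1, n_tree0=300)
        default = fit_rf(X, y, n_tree=300, seed=1)
        assert cfg.oob_error <= default.oob_error_ + 1e-12
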