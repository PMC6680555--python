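"""PLS-DA and random-forest classifiers with the study's fitting protocols.

PLS-DA regresses a one-hot class indicator matrix on the spectra (NIPALS,
via scikit-learn's :class:`~sklearn.cross_decomposition.PLSRegression`) and
assigns each sample to the class with the highest predicted indicator.  The
number of latent variables is chosen by 7-fold stratified cross-validated
Q², adding components while the gain is at least 0.01 (cap 15).  Model
quality is summarized by R², Q², RMSEE (calibration), RMSECV
(cross-validation) and RMSEP (validation), and guarded against overfitting
with a label-permutation test read off as the R²/Q² intercepts at zero
label correlation.

The random forest is bagged CART classification implemented over
scikit-learn decision trees.  Keeping the bagging loop in the package gives
two things the protocol needs that a stock forest does not expose: the
cumulative out-of-bag (OOB) error after each tree (the n_tree tuning
curve), and class-membership scores as hard tree-vote fractions.  Tuning
starts at n_tree = 2000 and m_try = sqrt(p) and picks n_tree from the
"smooth region" of the OOB curve, then scans m_try on a geometric grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

# --------------------------------------------------------------------------
# PLS-DA
# --------------------------------------------------------------------------


def one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for k, c in enumerate(classes):
        Y[labels == c, k] = 1.0
    return Y


@dataclass
class PlsdaModel:
    """Fitted PLS-DA: a PLS2 regression on one-hot class indicators."""

    estimator: PLSRegression
    classes: np.ndarray
    A: int

    @property
    def x_weights(self) -> np.ndarray:
        return self.estimator.x_weights_

    @property
    def x_scores(self) -> np.ndarray:
        return self.estimator.x_scores_

    @property
    def y_loadings(self) -> np.ndarray:
        return self.estimator.y_loadings_

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.predict_y(X), axis=1)]


@dataclass
class ModelQuality:
    """R²/Q² and the three RMS errors of a PLS-DA model."""

    r2: float
    q2: float
    rmsee: float
    rmsecv: float
    rmsep: float = float("nan")
    r2_intercept: float = float("nan")
    q2_intercept: float = float("nan")
    n_permutations: int = 0

    def __post_init__(self) -> None:
        for name in ("rmsee", "rmsecv", "rmsep"):
            v = getattr(self, name)
            if not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")


def _max_components(n: int, p: int, cap: int = 15) -> int:
    return max(1, min(cap, n - 1, p))


def _fit_pls(X: np.ndarray, Y: np.ndarray, A: int) -> PLSRegression:
    # tight inner-loop tolerance: NIPALS components reproducible to ~1e-11
    est = PLSRegression(n_components=A, scale=False, tol=1e-18, max_iter=5000)
    est.fit(X, Y)
    return est


def _cv_press(X: np.ndarray, labels: np.ndarray, classes: np.ndarray, A: int,
              folds: int = 7, seed: int = 0) -> tuple[float, float]:
    """(PRESS, RMSECV) from stratified K-fold refits at A components."""
    Y = one_hot(labels, classes)
    counts = np.bincount(np.searchsorted(classes, labels))
    folds = max(2, min(folds, int(counts.min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    n_total = 0
    for tr, te in skf.split(X, labels):
        a = min(A, _max_components(len(tr), X.shape[1]))
        est = _fit_pls(X[tr], Y[tr], a)
        resid = Y[te] - est.predict(X[te])
        press += float(np.sum(resid**2))
        n_total += resid.size
    return press, float(np.sqrt(press / n_total))


def _ss_tot(Y: np.ndarray) -> float:
    return float(np.sum((Y - Y.mean(axis=0)) ** 2))


def fit_plsda(X_cal: np.ndarray, labels: np.ndarray, A: int | str = "auto",
              folds: int = 7, seed: int = 0, cap: int = 15) -> PlsdaModel:
    """Fit PLS-DA on the calibration set.

    ``A="auto"`` grows the number of latent variables while the 7-fold
    cross-validated Q² improves by at least 0.01, up to ``cap``.
    """
    X_cal = np.asarray(X_cal, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes in calibration")
    Y = one_hot(labels, classes)
    a_max = _max_components(X_cal.shape[0], X_cal.shape[1], cap)
    if A == "auto":
        sst = _ss_tot(Y)
        best_a, best_q2 = 1, -np.inf
        for a in range(1, a_max + 1):
            press, _ = _cv_press(X_cal, labels, classes, a, folds=folds, seed=seed)
            q2 = 1.0 - press / sst
            if q2 > best_q2 + 0.01:
                best_a, best_q2 = a, q2
            elif a > best_a:
                break
        A = best_a
    A = int(A)
    if A < 1 or A > a_max:
        raise ValueError(f"A={A} outside the feasible range [1, {a_max}]")
    return PlsdaModel(estimator=_fit_pls(X_cal, Y, A), classes=classes, A=A)


def plsda_scores(model: PlsdaModel, X: np.ndarray) -> np.ndarray:
    """Class-membership scores: predicted indicators clipped at 0, row-normalized.

    An all-zero clipped row (no class favored) becomes uniform.  Rows sum
    to 1.
    """
    Yp = np.clip(model.predict_y(X), 0.0, None)
    s = Yp.sum(axis=1, keepdims=True)
    flat = s[:, 0] == 0
    if np.any(flat):
        Yp[flat] = 1.0 / Yp.shape[1]
        s = Yp.sum(axis=1, keepdims=True)
    return Yp / s


def quality_metrics(model: PlsdaModel, X_cal: np.ndarray, labels_cal: np.ndarray,
                    X_val: np.ndarray | None = None,
                    labels_val: np.ndarray | None = None,
                    folds: int = 7, seed: int = 0) -> ModelQuality:
    """R², Q², RMSEE, RMSECV (and RMSEP when a validation set is given).

    All RMS errors are root-mean-squares over every entry of the K-column
    indicator matrix; R² = 1 - SS_res/SS_tot on the calibration fit and
    Q² = 1 - PRESS/SS_tot from the cross-validation refits.
    """
    X_cal = np.asarray(X_cal, float)
    Y = one_hot(np.asarray(labels_cal), model.classes)
    resid = Y - model.predict_y(X_cal)
    ss_res = float(np.sum(resid**2))
    sst = _ss_tot(Y)
    rmsee = float(np.sqrt(ss_res / Y.size))
    press, rmsecv = _cv_press(X_cal, labels_cal, model.classes, model.A,
                              folds=folds, seed=seed)
    rmsep = float("nan")
    if X_val is not None and labels_val is not None:
        Yv = one_hot(np.asarray(labels_val), model.classes)
        rv = Yv - model.predict_y(np.asarray(X_val, float))
        rmsep = float(np.sqrt(np.sum(rv**2) / Yv.size))
    return ModelQuality(
        r2=1.0 - ss_res / sst,
        q2=1.0 - press / sst,
        rmsee=rmsee,
        rmsecv=rmsecv,
        rmsep=rmsep,
    )


@dataclass
class PermutationResult:
    """Intercepts of the R² and Q² vs label-correlation regression lines."""

    r2_intercept: float
    q2_intercept: float
    n_permutations: int
    overfit: bool
    points: list[tuple[float, float, float]] = field(repr=False, default_factory=list)


def permutation_test(X_cal: np.ndarray, labels: np.ndarray, A: int | str = "auto",
                     n_perm: int = 200, seed: int = 0, folds: int = 7,
                     classes_to_test=None) -> PermutationResult:
    """Label-permutation overfit test for PLS-DA.

    For every class in turn (or the subset ``classes_to_test``), the sample
    labels are permuted ``n_perm`` times; each refit contributes a point
    (corr, R², Q²) where corr is the correlation between the permuted and
    original indicator column of that class.  The unpermuted model enters at
    corr = 1.  The reported intercepts are the least-squares lines of R² and
    Q² against |corr| evaluated at corr = 0; a Q² intercept >= 0.05 flags
    overfitting.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X_cal = np.asarray(X_cal, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    model = fit_plsda(X_cal, labels, A=A, folds=folds, seed=seed)
    A_fit = model.A
    Y = one_hot(labels, classes)
    sst = _ss_tot(Y)
    q0 = quality_metrics(model, X_cal, labels, folds=folds, seed=seed)
    points: list[tuple[float, float, float]] = [(1.0, q0.r2, q0.q2)]
    rng = np.random.default_rng(seed)
    test_classes = classes if classes_to_test is None else np.asarray(classes_to_test)
    for c in test_classes:
        k = int(np.searchsorted(classes, c))
        y_orig = Y[:, k]
        for _ in range(n_perm):
            perm = rng.permutation(len(labels))
            lab_p = labels[perm]
            Yp = Y[perm]
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(Yp[:, k], y_orig)[0, 1])
            if np.isnan(corr):
                corr = 0.0
            est = _fit_pls(X_cal, Yp, A_fit)
            ss_res = float(np.sum((Yp - est.predict(X_cal)) ** 2))
            press, _ = _cv_press(X_cal, lab_p, classes, A_fit, folds=folds, seed=seed)
            points.append((abs(corr), 1.0 - ss_res / sst, 1.0 - press / sst))
    pts = np.array(points)
    coef_r2 = np.polyfit(pts[:, 0], pts[:, 1], 1)
    coef_q2 = np.polyfit(pts[:, 0], pts[:, 2], 1)
    r2_int, q2_int = float(coef_r2[1]), float(coef_q2[1])
    return PermutationResult(
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        n_permutations=n_perm * len(test_classes),
        overfit=q2_int >= 0.05,
        points=points,
    )


def vip(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt( p * sum_a [ SSY_a * (w_aj / ||w_a||)^2 ] / sum_a SSY_a )``
    where SSY_a is the Y-variance explained by component a.  The scores
    satisfy ``sum_j VIP_j^2 = p``.
    """
    W = model.x_weights          # p x A
    T = model.x_scores           # n x A
    Q = model.y_loadings         # K x A
    p, A = W.shape
    ssy = np.array([
        float((T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a])) for a in range(A)
    ])
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())


# --------------------------------------------------------------------------
# Random forest (bagged CART with OOB bookkeeping)
# --------------------------------------------------------------------------


@dataclass
class RfConfig:
    """Tuned forest parameters and the OOB evidence behind them."""

    n_tree: int
    m_try: int
    oob_curve: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    mtry_grid: list[int] = field(default_factory=list)
    mtry_oob: list[float] = field(default_factory=list)
    oob_error: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")
        if self.m_try < 1:
            raise ValueError("m_try must be >= 1")


class RandomForest:
    """Bagged CART classification forest with per-tree OOB tracking.

    Class-membership scores are hard tree-vote fractions, so every score row
    sums to 1.  The OOB error is the misclassification rate of out-of-bag
    majority votes, computed only over samples that were out of bag at least
    once.
    """

    def __init__(self, n_tree: int = 500, m_try: int | None = None, seed: int = 0):
        self.n_tree = int(n_tree)
        self.m_try = m_try
        self.seed = int(seed)
        self.trees: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.oob_curve_: np.ndarray | None = None
        self.oob_error_: float = float("nan")
        self._oob_votes: np.ndarray | None = None
        self._oob_sets: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, float)
        y = np.asarray(y)
        n, p = X.shape
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("forest needs at least two classes")
        m = self.m_try if self.m_try is not None else max(1, int(np.sqrt(p)))
        m = min(max(1, int(m)), p)
        self.m_try = m
        rng = np.random.default_rng(self.seed)
        K = len(self.classes_)
        class_index = {c: k for k, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        votes = np.zeros((n, K))
        curve = np.empty(self.n_tree)
        self.trees = []
        self._oob_sets = []
        for t in range(self.n_tree):
            boot = rng.integers(0, n, n)
            tree = DecisionTreeClassifier(
                max_features=m, random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            self._oob_sets.append(oob)
            if oob.size:
                pred = tree.predict(X[oob])
                for i, c in zip(oob, pred):
                    votes[i, class_index[c]] += 1
            covered = votes.sum(axis=1) > 0
            if covered.any():
                maj = np.argmax(votes[covered], axis=1)
                curve[t] = float(np.mean(maj != y_idx[covered]))
            else:
                curve[t] = 1.0
        self.oob_curve_ = curve
        self.oob_error_ = float(curve[-1])
        self._oob_votes = votes
        self._X_fit, self._y_fit, self._y_idx = X, y, y_idx
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Tree-vote fractions; rows sum to 1."""
        X = np.asarray(X, float)
        K = len(self.classes_)
        class_index = {c: k for k, c in enumerate(self.classes_)}
        votes = np.zeros((X.shape[0], K))
        for tree in self.trees:
            pred = tree.predict(X)
            for i, c in enumerate(pred):
                votes[i, class_index[c]] += 1
        return votes / len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_scores(X), axis=1)]

    @property
    def feature_importances_(self) -> np.ndarray:
        return np.mean([t.feature_importances_ for t in self.trees], axis=0)

    def permutation_importance(self, seed: int = 0) -> np.ndarray:
        """Mean decrease in OOB accuracy when each feature is permuted.

        The classic forest importance: per tree, the drop in out-of-bag
        accuracy after shuffling one column among the OOB samples, averaged
        over trees.
        """
        X, y = self._X_fit, self._y_fit
        rng = np.random.default_rng(seed)
        p = X.shape[1]
        drops = np.zeros(p)
        for tree, oob in zip(self.trees, self._oob_sets):
            if oob.size < 2:
                continue
            Xo = X[oob]
            base = np.mean(tree.predict(Xo) == y[oob])
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            for j in used:
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                drops[j] += base - np.mean(tree.predict(Xp) == y[oob])
        return drops / len(self.trees)


def fit_rf(X_cal: np.ndarray, labels: np.ndarray, n_tree: int = 500,
           m_try: int | None = None, seed: int = 0) -> RandomForest:
    """Fit a bagged CART forest and record its OOB error curve."""
    return RandomForest(n_tree=n_tree, m_try=m_try, seed=seed).fit(
        np.asarray(X_cal, float), np.asarray(labels)
    )


def _smooth_region_ntree(curve: np.ndarray, n_cal: int) -> int:
    """Pick n_tree from the longest smooth (near-minimum) run of the OOB curve.

    Counts whose OOB error is within half a misclassification
    (``1/(2*n_cal)``) of the global minimum form candidate runs; the chosen
    tree count is the earliest global minimum inside the longest such run.
    """
    m = float(curve.min())
    tol = m + 0.5 / n_cal
    good = curve <= tol
    runs = []  # (length, start, end) inclusive
    start = None
    for t, g in enumerate(good):
        if g and start is None:
            start = t
        elif not g and start is not None:
            runs.append((t - start, start, t - 1))
            start = None
    if start is not None:
        runs.append((len(good) - start, start, len(good) - 1))
    is_min = curve == m
    best_run = max(
        (r for r in runs if is_min[r[1]:r[2] + 1].any()),
        key=lambda r: (r[0], -r[1]),
    )
    inside = np.flatnonzero(is_min[best_run[1]:best_run[2] + 1]) + best_run[1]
    return int(inside[0]) + 1  # tree counts are 1-based


def tune_rf(X_cal: np.ndarray, labels: np.ndarray, seed: int = 0,
            n_tree0: int = 2000) -> RfConfig:
    """Tune (n_tree, m_try) by the OOB protocol.

    Stage 1 fits ``n_tree0`` trees at the default ``m_try = sqrt(p)`` and
    chooses n_tree from the smooth region of the cumulative OOB curve.
    Stage 2 refits at the chosen n_tree for each m_try on a 12-point
    geometric grid spanning ``sqrt(p)/4 .. 4*sqrt(p)`` (deduplicated,
    clipped to [1, p]) and keeps the lowest-OOB point, ties to the smaller
    m_try.
    """
    X_cal = np.asarray(X_cal, float)
    labels = np.asarray(labels)
    n, p = X_cal.shape
    base = fit_rf(X_cal, labels, n_tree=n_tree0, m_try=None, seed=seed)
    n_tree = _smooth_region_ntree(base.oob_curve_, n)
    sq = np.sqrt(p)
    grid = np.geomspace(max(sq / 4, 1.0), min(4 * sq, p), 12)
    mtries = sorted({min(max(1, int(g)), p) for g in grid})
    oobs = []
    for m in mtries:
        f = fit_rf(X_cal, labels, n_tree=n_tree, m_try=m, seed=seed)
        oobs.append(f.oob_error_)
    best = int(np.argmin(oobs))  # argmin keeps the first (smallest m_try) on ties
    return RfConfig(
        n_tree=n_tree,
        m_try=mtries[best],
        oob_curve=base.oob_curve_,
        mtry_grid=mtries,
        mtry_oob=[float(v) for v in oobs],
        oob_error=float(oobs[best]),
    )
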