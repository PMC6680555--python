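"""Variable-selection and feature-extraction routes feeding data fusion.

Three routes reduce each spectral block before mid- or high-level fusion:

* **PCs** -- principal components of the autoscaled (correlation-matrix)
  data, kept by the Kaiser eigenvalue-greater-than-1 rule; the result is a
  projector, not a column subset.
* **RFE** -- recursive feature elimination on a tuned random forest:
  variables are ranked by permutation importance and dropped five at a time
  while a stratified 10-fold cross-validation error curve is recorded; the
  retained-size axis is partitioned into irrelevant / interference /
  important regions and the important region's variable set is returned.
* **Boruta** -- the all-relevant shadow-feature algorithm; confirmed and
  tentative variables are both retained.

VIP selection (threshold 1) applies to a PLS-DA fitted on the low-level
fused matrix and is used by the low-level(VIP) route.

Selection scope matters: for mid-level fusion the study selects on the full
sample set (which leaks validation information into the selection and is
flagged in reports), for high-level fusion on the calibration set only.
Both scopes are supported via the ``rows`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .models import PlsdaModel, fit_rf, tune_rf, vip


@dataclass
class SelectionResult:
    """Retained variables (or PC projector) plus method-specific annotations."""

    method: str  # "pcs" | "rfe" | "boruta" | "vip"
    indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    # PCs route
    loadings: Optional[np.ndarray] = None
    eigenvalues: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None
    kept_columns: Optional[np.ndarray] = None
    # RFE route
    cv_curve: Optional[list[tuple[int, float, float]]] = None  # (size, err, se)
    regions: Optional[dict[str, tuple[int, int]]] = None
    # Boruta route
    confirmed: Optional[np.ndarray] = None
    tentative: Optional[np.ndarray] = None
    rejected: Optional[np.ndarray] = None
    # VIP route
    scores: Optional[np.ndarray] = None
    threshold: Optional[float] = None
    leakage_warning: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("selected indices must be unique")
        if self.eigenvalues is not None:
            ev = np.asarray(self.eigenvalues, float)
            if np.any(np.diff(ev) > 1e-10):
                raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_kept(self) -> int:
        if self.method == "pcs":
            return int(self.loadings.shape[1])
        return int(self.indices.size)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples: PC scores for the PCs route, column subset otherwise."""
        X = np.asarray(X, float)
        if self.method == "pcs":
            Z = (X[:, self.kept_columns] - self.center) / self.scale
            return Z @ self.loadings
        return X[:, self.indices]


def pca_extract(X: np.ndarray, rule: str = "kaiser") -> SelectionResult:
    """Correlation-matrix PCA keeping components with eigenvalue > 1.

    Columns are autoscaled (zero-variance columns dropped with a warning
    before scaling), so the eigenvalue sum equals the number of retained
    columns and the Kaiser rule is calibrated.  The result carries a
    projector for new samples.
    """
    if rule != "kaiser":
        raise ValueError(f"unknown PC retention rule {rule!r}")
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    kept_cols = np.flatnonzero(sd > 0)
    if kept_cols.size < p:
        import warnings

        warnings.warn(f"dropping {p - kept_cols.size} zero-variance column(s) before PCA")
    mu = X[:, kept_cols].mean(axis=0)
    s = sd[kept_cols]
    Z = (X[:, kept_cols] - mu) / s
    # SVD of the autoscaled data == eigendecomposition of the correlation matrix
    U, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = svals**2 / (n - 1)
    n_keep = max(1, int(np.sum(eig > 1.0)))
    return SelectionResult(
        method="pcs",
        loadings=Vt[:n_keep].T,
        eigenvalues=eig,
        center=mu,
        scale=s,
        kept_columns=kept_cols,
    )


def _cv_error(X: np.ndarray, y: np.ndarray, n_tree: int, m_try: int | None,
              folds: int, seed: int) -> tuple[float, float]:
    """Stratified K-fold RF misclassification rate and its standard error."""
    counts = np.bincount(np.searchsorted(np.unique(y), y))
    folds = max(2, min(folds, int(counts.min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        f = fit_rf(X[tr], y[tr], n_tree=n_tree, m_try=m_try, seed=seed)
        errs.append(float(np.mean(f.predict(X[te]) != y[te])))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=1) / np.sqrt(len(errs)))


def rfe_select(X: np.ndarray, labels: np.ndarray, step: int = 5,
               folds: int = 10, seed: int = 0, n_tree0: int = 2000,
               tune: bool = True, n_tree: int | None = None,
               cv_n_tree: int | None = None) -> SelectionResult:
    """RF-based recursive feature elimination with region partitioning.

    Variables are ranked once by permutation importance of a (tuned) forest,
    then dropped ``step`` at a time from the least important end while the
    stratified ``folds``-fold cross-validation error of a refit forest is
    recorded at every retained size.  The size axis is split into three
    regions: the *important* region ends at the smallest size whose error is
    within one standard error of the curve minimum; the *irrelevant* region
    is the plateau of largest sizes whose error stays within one standard
    error of the full-size error; everything between is *interference*.  The
    important region's variable set is returned.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    p = X.shape[1]
    if step >= p:
        raise ValueError(f"step={step} must be smaller than p={p}")
    if tune and n_tree is None:
        cfg = tune_rf(X, labels, seed=seed, n_tree0=n_tree0)
        n_tree_fit, m_try = cfg.n_tree, cfg.m_try
    else:
        n_tree_fit, m_try = n_tree or n_tree0, None
    ranker = fit_rf(X, labels, n_tree=n_tree_fit, m_try=m_try, seed=seed)
    importance = ranker.permutation_importance(seed=seed)
    order = np.argsort(importance)[::-1]  # most important first
    sizes = list(range(p, step - 1, -step))
    curve: list[tuple[int, float, float]] = []
    cv_trees = cv_n_tree if cv_n_tree is not None else max(100, n_tree_fit // 4)
    for size in sizes:
        cols = np.sort(order[:size])
        err, se = _cv_error(X[:, cols], labels, n_tree=cv_trees,
                            m_try=None, folds=folds, seed=seed)
        curve.append((size, err, se))
    errs = np.array([c[1] for c in curve])
    ses = np.array([c[2] for c in curve])
    i_min = int(np.argmin(errs))
    thresh = errs[i_min] + ses[i_min]
    # smallest retained size meeting the 1-SE rule (sizes are descending)
    ok = np.flatnonzero(errs <= thresh)
    i_best = int(ok.max()) if ok.size else i_min
    best_size = curve[i_best][0]
    # plateau at the full-size end: errors within 1 SE of the full-size error
    full_err, full_se = errs[0], max(ses[0], 1e-12)
    i_plateau_end = 0
    while (i_plateau_end + 1 < len(errs)
           and abs(errs[i_plateau_end + 1] - full_err) <= full_se):
        i_plateau_end += 1
    irrelevant_lo = curve[min(i_plateau_end, i_best)][0]
    regions = {
        "important": (step, best_size),
        "interference": (best_size, irrelevant_lo),
        "irrelevant": (irrelevant_lo, p),
    }
    return SelectionResult(
        method="rfe",
        indices=np.sort(order[:best_size]),
        cv_curve=curve,
        regions=regions,
    )


def boruta_select(X: np.ndarray, labels: np.ndarray, n_tree: int = 300,
                  m_try: int | None = None, alpha: float = 0.01,
                  max_iter: int = 100, seed: int = 0) -> SelectionResult:
    """Canonical Boruta all-relevant selection.

    Each iteration appends a permuted shadow copy of every undecided
    variable, fits a forest on the extended matrix, and scores a *hit* for a
    variable whose importance exceeds the maximum shadow importance.  After
    each iteration the hit counts are tested against Binomial(iter, 1/2)
    two-sidedly at ``alpha`` with Holm step-down correction: significantly
    many hits confirms a variable, significantly few rejects it.  Variables
    still undecided at ``max_iter`` are tentative.  Confirmed and tentative
    variables together form the returned selection.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    hits = np.zeros(p, dtype=int)
    n_iter = 0
    for it in range(1, max_iter + 1):
        active = np.flatnonzero(status != -1)
        if not (status == 0).any():
            break
        Xa = X[:, active]
        shadow = Xa.copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = shadow[rng.permutation(X.shape[0]), j]
        Xext = np.hstack([Xa, shadow])
        forest = fit_rf(Xext, labels, n_tree=n_tree, m_try=m_try,
                        seed=int(rng.integers(0, 2**31 - 1)))
        imp = forest.feature_importances_
        real_imp = imp[: Xa.shape[1]]
        max_shadow = imp[Xa.shape[1]:].max()
        hits[active[real_imp > max_shadow]] += 1
        n_iter = it
        # Holm step-down over the still-undecided variables, two-sided
        und = np.flatnonzero(status == 0)
        if und.size == 0:
            break
        pv_hi = np.array([stats.binom.sf(hits[j] - 1, it, 0.5) for j in und])
        pv_lo = np.array([stats.binom.cdf(hits[j], it, 0.5) for j in und])
        pv = 2.0 * np.minimum(np.minimum(pv_hi, pv_lo), 0.5)
        order = np.argsort(pv)
        m = und.size
        for rank, oi in enumerate(order):
            if pv[oi] * (m - rank) >= alpha:
                break
            j = und[oi]
            status[j] = 1 if pv_hi[oi] < pv_lo[oi] else -1
    confirmed = np.flatnonzero(status == 1)
    tentative = np.flatnonzero(status == 0)
    rejected = np.flatnonzero(status == -1)
    selected = np.sort(np.concatenate([confirmed, tentative]))
    return SelectionResult(
        method="boruta",
        indices=selected,
        confirmed=confirmed,
        tentative=tentative,
        rejected=rejected,
    )


def vip_select(model: PlsdaModel, threshold: float = 1.0) -> SelectionResult:
    """Keep variables whose VIP score strictly exceeds the threshold."""
    scores = vip(model)
    return SelectionResult(
        method="vip",
        indices=np.flatnonzero(scores > threshold),
        scores=scores,
        threshold=threshold,
    )
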