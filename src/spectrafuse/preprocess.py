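"""Spectral pretreatment: SNV, Savitzky-Golay derivatives, region exclusion.

The candidate pretreatments are the six the study protocol compares:
raw, SNV, first derivative (FD), second derivative (SD), and the composites
SNV-FD and SNV-SD (SNV applied first, then the derivative, reading the name
left to right).  Derivatives are Savitzky-Golay with window 15 and
polynomial order 2 by default -- a common chemometric choice; it is exposed
in :class:`~spectrafuse.spectra_core.RunConfig` because the value matters
for reproducibility.  Savitzky-Golay output keeps the input shape
(polynomial-fit edge handling), so variable counts stay aligned with the
wavenumber grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_core import PRETREATMENTS, SpectralBlock


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum cannot be SNV-scaled (zero variance)."""


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center to mean 0 and scale to sample sd 1.

    Uses the n-1 denominator.  Inverts multiplicative scatter exactly:
    ``snv(a*x + b) == snv(x)`` for any ``a > 0``.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv expects a 1-D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("zero variance spectrum cannot be SNV-scaled")
    return (x - x.mean()) / sd


def snv_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV of a sample x variable matrix."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = int(np.argwhere(sd[:, 0] == 0)[0][0])
        raise DegenerateSpectrumError(f"zero variance spectrum at row {bad}")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def derivative(X: np.ndarray, order: int, window: int = 15, poly: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative along the wavenumber axis, same shape out.

    Exact for polynomials of degree <= ``poly`` at interior points.
    """
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not (window > poly >= order):
        raise ValueError(f"need window > poly >= order, got window={window}, poly={poly}, order={order}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < window:
        raise ValueError(f"{X.shape[1]} variables < window {window}")
    return savgol_filter(X, window_length=window, polyorder=poly, deriv=order,
                         axis=1, mode="interp")


def apply_pretreatment(block: SpectralBlock, method: str,
                       window: int = 15, poly: int = 2) -> SpectralBlock:
    """Apply one of the six candidate pretreatments to every spectrum.

    Composite methods apply SNV first, then the derivative.  The wavenumber
    grid is unchanged.
    """
    if method not in PRETREATMENTS:
        raise ValueError(f"unknown method {method!r}; expected one of {PRETREATMENTS}")
    X = block.X
    if method == "raw":
        return block.with_matrix(X.copy())
    if method.startswith("SNV"):
        X = snv_matrix(X)
    if method.endswith("FD"):
        X = derivative(X, order=1, window=window, poly=poly)
    elif method.endswith("SD"):
        X = derivative(X, order=2, window=window, poly=poly)
    return block.with_matrix(X)


def exclude_regions(block: SpectralBlock, regions: list[tuple[float, float]]) -> SpectralBlock:
    """Drop grid columns falling inside any ``[lo, hi]`` wavenumber interval.

    Intervals are closed, except that an interval endpoint lying strictly
    inside the grid span is treated as a boundary shared with a retained
    segment and therefore kept (e.g. excluding 4000-3700 and 2620-1800 from a
    full-range mid-IR grid retains the points at exactly 3700, 2620 and
    1800 cm^-1, matching the convention that the retained analysis segments
    are the closed intervals 3700-2620 and 1800-650).  Column order of the
    retained variables is preserved.
    """
    gmin, gmax = block.grid.min(), block.grid.max()
    keep = np.ones(block.n_variables, dtype=bool)
    for lo, hi in regions:
        lo, hi = float(min(lo, hi)), float(max(lo, hi))
        inside = (block.grid >= lo) & (block.grid <= hi)
        shared = np.isin(block.grid, [lo, hi]) & (block.grid > gmin) & (block.grid < gmax)
        keep &= ~(inside & ~shared)
    if not keep.any():
        raise ValueError("region exclusion removed every variable")
    return block.with_matrix(block.X[:, keep], grid=block.grid[keep])


@dataclass
class PretreatmentReport:
    """Model-quality summary of one pretreatment candidate."""

    method: str
    r2: float
    q2: float
    rmsee: float
    rmsecv: float
    accuracy: float

    def __post_init__(self) -> None:
        if self.rmsee < 0 or self.rmsecv < 0:
            raise ValueError("RMSE values must be non-negative")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0,1]")


def rank_pretreatments(block: SpectralBlock, split, methods=PRETREATMENTS,
                       window: int = 15, poly: int = 2,
                       n_components="auto") -> tuple[list[PretreatmentReport], str]:
    """Fit a PLS-DA per candidate pretreatment and rank by the five criteria.

    Better means higher R^2, Q^2 and calibration accuracy, lower RMSEE and
    RMSECV.  Candidates are aggregated by rank-sum over the five criteria
    with calibration accuracy as the tie-breaker.
    """
    from .models import fit_plsda, plsda_scores, quality_metrics

    cal_idx = split.indices(block.sample_ids, "calibration")
    if len(cal_idx) < 8 or len(np.unique(block.labels[cal_idx])) < 2:
        raise ValueError("degenerate calibration set")
    reports: list[PretreatmentReport] = []
    for method in methods:
        pb = apply_pretreatment(block, method, window=window, poly=poly)
        X_cal = pb.X[cal_idx]
        y_cal = pb.labels[cal_idx]
        model = fit_plsda(X_cal, y_cal, A=n_components)
        q = quality_metrics(model, X_cal, y_cal)
        scores = plsda_scores(model, X_cal)
        pred = model.classes[np.argmax(scores, axis=1)]
        acc = float(np.mean(pred == y_cal))
        reports.append(PretreatmentReport(method, q.r2, q.q2, q.rmsee, q.rmsecv, acc))
    # rank-sum: rank 0 is best on each criterion
    def ranks(values, reverse):
        order = sorted(range(len(values)), key=lambda i: values[i], reverse=reverse)
        r = [0] * len(values)
        for rank, i in enumerate(order):
            r[i] = rank
        return r

    r2r = ranks([r.r2 for r in reports], reverse=True)
    q2r = ranks([r.q2 for r in reports], reverse=True)
    accr = ranks([r.accuracy for r in reports], reverse=True)
    eer = ranks([r.rmsee for r in reports], reverse=False)
    cvr = ranks([r.rmsecv for r in reports], reverse=False)
    totals = [r2r[i] + q2r[i] + accr[i] + eer[i] + cvr[i] for i in range(len(reports))]
    best_i = min(range(len(reports)),
                 key=lambda i: (totals[i], -reports[i].accuracy, i))
    return reports, reports[best_i].method
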