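"""Deterministic per-class Kennard-Stone calibration/validation partition.

Each class is split 2:1 (calibration:validation) by the classic
Kennard-Stone max-min procedure, run on the per-variable autoscaled
concatenation of both spectral blocks so that one split serves every
downstream model.  The procedure involves no randomness: repeated runs, and
runs on row-permuted inputs, give the identical assignment by sample id.

The calibration count per class is ``floor(2/3 * n_class)``, which
reproduces the study bookkeeping: class sizes (40, 40, 36, 40, 40) yield
calibration counts (26, 26, 24, 26, 26), 128 in total, and validation
counts (14, 14, 12, 14, 14), 68 in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .spectra_core import SpectralBlock

CAL, VAL = "calibration", "validation"


@dataclass
class SplitAssignment:
    """Per-sample calibration/validation membership, keyed by sample id."""

    roles: dict[str, str]
    feature_space: str = "autoscaled concatenated two-block matrix"
    per_class_counts: dict[int, tuple[int, int]] = field(default_factory=dict)

    def indices(self, sample_ids: list[str], role: str) -> np.ndarray:
        """Row indices of the given role in a block with these sample ids."""
        if role not in (CAL, VAL):
            raise ValueError(f"role must be {CAL!r} or {VAL!r}")
        missing = [s for s in sample_ids if s not in self.roles]
        if missing:
            raise KeyError(f"sample ids not in split: {missing[:5]}")
        return np.array([i for i, s in enumerate(sample_ids) if self.roles[s] == role],
                        dtype=int)

    @property
    def n_calibration(self) -> int:
        return sum(1 for r in self.roles.values() if r == CAL)

    @property
    def n_validation(self) -> int:
        return sum(1 for r in self.roles.values() if r == VAL)


def kennard_stone(X: np.ndarray, k: int) -> list[int]:
    """Classic Kennard-Stone max-min subset selection.

    Starts from the two mutually most distant points (Euclidean), then
    repeatedly adds the point whose minimum distance to the selected set is
    largest.  Ties break to the lowest row index.  Returns ``k`` indices in
    selection order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    D = cdist(X, X)
    # farthest pair; argmax of flattened upper triangle, lowest indices on ties
    iu = np.triu_indices(n, 1)
    best = int(np.argmax(D[iu]))
    i, j = int(iu[0][best]), int(iu[1][best])
    selected = [i, j]
    mind = np.minimum(D[i], D[j])
    mind[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(mind))  # np.argmax takes the first (lowest) index on ties
        selected.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return selected


def _autoscale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def split_by_class(blocks: tuple[SpectralBlock, SpectralBlock] | SpectralBlock,
                   ratio: float = 2.0 / 3.0) -> SplitAssignment:
    """Per-class 2:1 Kennard-Stone split reused by every downstream model.

    Distances are computed on the autoscaled column-wise concatenation of the
    (already pretreated) blocks.  A single block may also be passed.
    """
    if isinstance(blocks, SpectralBlock):
        blocks = (blocks,)
    first = blocks[0]
    for b in blocks[1:]:
        if b.sample_ids != first.sample_ids or not np.array_equal(b.labels, first.labels):
            raise ValueError("blocks are not row-aligned")
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie in (0,1), got {ratio}")
    Z = _autoscale(np.hstack([b.X for b in blocks]))
    labels = first.labels
    # canonical ordering by sample id makes the assignment row-order invariant
    order = sorted(range(len(first.sample_ids)), key=lambda i: first.sample_ids[i])
    roles: dict[str, str] = {}
    counts: dict[int, tuple[int, int]] = {}
    for cls in np.unique(labels):
        rows = [i for i in order if labels[i] == cls]
        n = len(rows)
        if n < 3:
            raise ValueError(f"class {cls} has only {n} samples; need >= 3")
        k_cal = int(math.floor(ratio * n))
        k_cal = min(max(k_cal, 2), n - 1)
        picked = kennard_stone(Z[rows], k_cal)
        cal_ids = {first.sample_ids[rows[p]] for p in picked}
        for i in rows:
            sid = first.sample_ids[i]
            roles[sid] = CAL if sid in cal_ids else VAL
        counts[int(cls)] = (k_cal, n - k_cal)
    return SplitAssignment(roles=roles, per_class_counts=counts)
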