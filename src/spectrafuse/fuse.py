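"""Low-, mid- and high-level fusion of two spectral blocks.

*Low-level* fusion concatenates the raw (pretreated) variable matrices of
the two modalities.  *Mid-level* fusion concatenates per-block selected
features (variable subsets, or PC scores for the PCs route).  *High-level*
fusion combines the two blocks' fitted classifiers at the decision level:
the per-class membership score vectors of each sample are aggregated by
four fuzzy operators (element-wise minimum, maximum, product, average), each
operator votes for its maximal class(es) -- any class within ``eps`` (0.01)
of the maximum counts as maximal -- and the final decision is the plurality
class over the four operator votes, with count ties resolved as the union
of tied classes.  A final set with more than one class is a *multiple
discrimination*: it never hurts accuracy (the sample counts correct if the
true class is in the set) but adds false positives to the spurious classes,
depressing their per-class efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .select import SelectionResult
from .spectra_core import SpectralBlock

OPERATORS = ("min", "max", "product", "average")


@dataclass
class FusionDecision:
    """One sample's operator votes and final fused class set."""

    operator_votes: dict[str, frozenset]
    final: frozenset
    multiple: bool
    true_class: int | None = None

    def __post_init__(self) -> None:
        if not self.final:
            raise ValueError("final class set must be non-empty")
        for op, votes in self.operator_votes.items():
            if not votes:
                raise ValueError(f"operator {op} produced an empty vote set")
        if self.multiple != (len(self.final) > 1):
            raise ValueError("multiple flag inconsistent with final set size")


def low_level_fuse(block_a: SpectralBlock, block_b: SpectralBlock
                   ) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Concatenate two row-aligned blocks column-wise.

    Returns the fused matrix and per-column provenance
    ``(modality, wavenumber)``.
    """
    if block_a.n_samples == 0 or block_b.n_samples == 0:
        raise ValueError("cannot fuse an empty block")
    if block_a.sample_ids != block_b.sample_ids:
        raise ValueError("blocks are not row-aligned (sample ids differ)")
    if not np.array_equal(block_a.labels, block_b.labels):
        raise ValueError("blocks are not row-aligned (labels differ)")
    fused = np.hstack([block_a.X, block_b.X])
    provenance = [(block_a.modality.value, float(w)) for w in block_a.grid]
    provenance += [(block_b.modality.value, float(w)) for w in block_b.grid]
    return fused, provenance


def mid_level_fuse(sel_a: SelectionResult, block_a: SpectralBlock,
                   sel_b: SelectionResult, block_b: SpectralBlock) -> np.ndarray:
    """Concatenate per-block selected features (columns or PC scores)."""
    if block_a.sample_ids != block_b.sample_ids:
        raise ValueError("blocks are not row-aligned (sample ids differ)")
    Fa = sel_a.transform(block_a.X)
    Fb = sel_b.transform(block_b.X)
    if Fa.shape[1] == 0 or Fb.shape[1] == 0:
        raise ValueError("empty selection on one block")
    return np.hstack([Fa, Fb])


def fuzzy_vote(score_a: np.ndarray, score_b: np.ndarray, eps: float = 0.01,
               classes: np.ndarray | None = None,
               true_class: int | None = None) -> FusionDecision:
    """Fuse two class-membership score vectors by fuzzy-operator voting.

    Each of the four operators (min, max, product, average) combines the two
    vectors element-wise; its vote set is every class whose combined score
    exceeds ``max - eps``.  The final set is the plurality class over the
    four vote sets; ties in the vote count yield the union of tied classes
    (multiple discrimination).
    """
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"score vectors must be 1-D and equal length, got {a.shape} vs {b.shape}")
    K = a.size
    classes = np.arange(1, K + 1) if classes is None else np.asarray(classes)
    combined = {
        "min": np.minimum(a, b),
        "max": np.maximum(a, b),
        "product": a * b,
        "average": (a + b) / 2.0,
    }
    votes: dict[str, frozenset] = {}
    counts: dict = {}
    for op in OPERATORS:
        v = combined[op]
        # a gap of exactly eps still counts as a tie; 1e-12 absorbs float error
        vote = frozenset(classes[v >= v.max() - eps - 1e-12].tolist())
        votes[op] = vote
        for c in vote:
            counts[c] = counts.get(c, 0) + 1
    top = max(counts.values())
    final = frozenset(c for c, n in counts.items() if n == top)
    return FusionDecision(
        operator_votes=votes,
        final=final,
        multiple=len(final) > 1,
        true_class=true_class,
    )


def high_level_fuse(scores_a: np.ndarray, scores_b: np.ndarray,
                    eps: float = 0.01, classes: np.ndarray | None = None,
                    true_labels: np.ndarray | None = None) -> list[FusionDecision]:
    """Decision-level fusion: fuzzy-operator voting applied per sample."""
    A = np.asarray(scores_a, float)
    B = np.asarray(scores_b, float)
    if A.shape != B.shape:
        raise ValueError(f"score matrices differ in shape: {A.shape} vs {B.shape}")
    if true_labels is not None and len(true_labels) != A.shape[0]:
        raise ValueError("true_labels length mismatch")
    out = []
    for i in range(A.shape[0]):
        t = int(true_labels[i]) if true_labels is not None else None
        out.append(fuzzy_vote(A[i], B[i], eps=eps, classes=classes, true_class=t))
    return out
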