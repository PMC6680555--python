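"""Core data containers and CSV readers/writers for spectral blocks.

A :class:`SpectralBlock` is one modality's sample x wavenumber absorbance
matrix together with its wavenumber grid, sample identifiers and class
labels.  The canonical on-disk form is a wide CSV: first column
``sample_id``, second column ``class`` (integer 1..K), remaining columns
numeric wavenumbers in cm^-1.  Grids are treated as exact column keys; no
resampling or interpolation happens anywhere in the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml


class Modality(str, enum.Enum):
    """Spectral modality tag."""

    FTMIR = "FTMIR"
    NIR = "NIR"


class LoadError(ValueError):
    """Raised when a spectral CSV violates the block contract."""


@dataclass
class SpectralBlock:
    """One modality's absorbance matrix with grid, sample ids and labels.

    Parameters
    ----------
    modality
        Which instrument the block came from (FT-MIR or NIR).
    grid
        Wavenumbers in cm^-1, strictly monotonic, one per column of ``X``.
    X
        Absorbance matrix, shape ``(n_samples, n_variables)``.
    sample_ids
        Unique sample identifiers aligned with the rows of ``X``.
    labels
        Integer class labels (1..K) aligned with the rows of ``X``.
    """

    modality: Modality
    grid: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.modality = Modality(self.modality)
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        if self.X.ndim != 2:
            raise LoadError(f"X must be 2-D, got ndim={self.X.ndim}")
        n, p = self.X.shape
        if self.grid.shape != (p,):
            raise LoadError(
                f"grid length {self.grid.size} != number of columns {p}"
            )
        d = np.diff(self.grid)
        if p > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise LoadError("grid must be strictly monotonic")
        if len(self.sample_ids) != n:
            raise LoadError(f"{len(self.sample_ids)} sample ids for {n} rows")
        seen: dict[str, int] = {}
        for sid in self.sample_ids:
            seen[sid] = seen.get(sid, 0) + 1
        dups = sorted(s for s, c in seen.items() if c > 1)
        if dups:
            raise LoadError(f"duplicate sample ids: {dups}")
        if self.labels.shape != (n,):
            raise LoadError(f"{self.labels.size} labels for {n} rows")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise LoadError(
                f"non-finite value at row {bad[0]} ({self.sample_ids[bad[0]]}),"
                f" column {bad[1]} ({self.grid[bad[1]]} cm^-1)"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def with_matrix(self, X: np.ndarray, grid: np.ndarray | None = None) -> "SpectralBlock":
        """Return a copy with a new matrix (and optionally a new grid)."""
        return SpectralBlock(
            modality=self.modality,
            grid=self.grid.copy() if grid is None else np.asarray(grid, float),
            X=np.asarray(X, float),
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
        )

    def equals(self, other: "SpectralBlock") -> bool:
        return (
            self.modality == other.modality
            and np.array_equal(self.grid, other.grid)
            and np.array_equal(self.X, other.X)
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.labels, other.labels)
        )


def read_block(path: str | Path, modality: Modality | str) -> SpectralBlock:
    """Load a wide spectral CSV into a validated :class:`SpectralBlock`.

    The header row must contain ``sample_id``, ``class`` and then numeric
    wavenumbers.  Sample row order is preserved exactly as on disk.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "class":
        raise LoadError(
            f"{path}: expected columns 'sample_id', 'class', <wavenumbers...>,"
            f" got {cols[:3]}..."
        )
    try:
        grid = np.array([float(c) for c in cols[2:]])
    except ValueError as exc:
        raise LoadError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    try:
        labels = df["class"].astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise LoadError(f"{path}: non-integer class labels: {exc}") from exc
    body = df[cols[2:]]
    try:
        X = body.astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise LoadError(f"{path}: non-numeric absorbance cell: {exc}") from exc
    return SpectralBlock(
        modality=Modality(modality),
        grid=grid,
        X=X,
        sample_ids=df["sample_id"].tolist(),
        labels=labels,
    )


def write_block(block: SpectralBlock, path: str | Path) -> None:
    """Write a block as wide CSV, exact round-trip at full precision."""
    path = Path(path)
    df = pd.DataFrame(block.X, columns=[repr(float(w)) for w in block.grid])
    df.insert(0, "class", block.labels)
    df.insert(0, "sample_id", block.sample_ids)
    # %.17g is lossless for float64; repr() headers round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


def average_replicates(block: SpectralBlock, replicate_of: dict[str, str]) -> SpectralBlock:
    """Average analytical replicates into one row per biological sample.

    ``replicate_of`` maps each replicate's ``sample_id`` to a parent sample
    id.  Replicates of the same parent must share a class label.  Row order
    follows the first appearance of each parent.  This is an optional helper:
    the pipeline itself assumes one row per sample.
    """
    parents: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(block.sample_ids):
        parent = replicate_of.get(sid, sid)
        if parent not in groups:
            groups[parent] = []
            parents.append(parent)
        groups[parent].append(i)
    rows, labels = [], []
    for parent in parents:
        idx = groups[parent]
        lab = set(block.labels[idx].tolist())
        if len(lab) > 1:
            raise LoadError(f"replicates of {parent} carry different classes {sorted(lab)}")
        rows.append(block.X[idx].mean(axis=0))
        labels.append(lab.pop())
    return SpectralBlock(
        modality=block.modality,
        grid=block.grid.copy(),
        X=np.vstack(rows),
        sample_ids=parents,
        labels=np.array(labels),
    )


PRETREATMENTS = ("raw", "SNV", "FD", "SD", "SNV-FD", "SNV-SD")


@dataclass
class RunConfig:
    """Run-level configuration mirrored by the YAML config file.

    Defaults follow the study protocol: initial forest size 2000 with
    ``m_try = sqrt(p)``, a 2:1 calibration/validation ratio, and a 0.01
    near-tie epsilon in decision voting.
    """

    pretreatment: dict[str, str] = field(default_factory=lambda: {"FTMIR": "auto", "NIR": "auto"})
    excluded_regions: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    split_ratio: float = 2.0 / 3.0
    n_tree0: int = 2000
    mtry_rule: str = "sqrt"
    selection: str = "pcs"
    fusion_level: str = "high"
    tie_eps: float = 0.01
    seed: int = 0
    sg_window: int = 15
    sg_poly: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError(f"split ratio must lie in (0,1), got {self.split_ratio}")
        if self.tie_eps <= 0:
            raise ValueError(f"tie epsilon must be positive, got {self.tie_eps}")
        for mod, regs in self.excluded_regions.items():
            # accept either orientation (spectroscopists write high -> low)
            norm = sorted((min(float(a), float(b)), max(float(a), float(b)))
                          for a, b in regs)
            for (a, b), (c, d) in zip(norm, norm[1:]):
                if c < b:
                    raise ValueError(f"{mod}: regions [{a},{b}] and [{c},{d}] overlap")
            self.excluded_regions[mod] = norm

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "pretreatment": dict(self.pretreatment),
            "excluded_regions": {
                k: [list(map(float, r)) for r in v] for k, v in self.excluded_regions.items()
            },
            "split_ratio": self.split_ratio,
            "n_tree0": self.n_tree0,
            "mtry_rule": self.mtry_rule,
            "selection": self.selection,
            "fusion_level": self.fusion_level,
            "tie_eps": self.tie_eps,
            "seed": self.seed,
            "sg_window": self.sg_window,
            "sg_poly": self.sg_poly,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)
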