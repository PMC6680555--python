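"""Synthetic paired FT-MIR / NIR spectra with class structure.

Real rhizome powders from the five collection regions share nearly identical
spectral fingerprints: the same absorption bands at the same positions, with
only subtle class-dependent differences in band intensity and slight center
shifts.  The generator reproduces that statistical situation: every class
shares one Gaussian-peak backbone per modality, a designated subset of peaks
receives small class-specific height multipliers (a few to ~20 %) and center
shifts (at most a few cm^-1), and each sampled spectrum is corrupted by a
low-order polynomial baseline, per-sample multiplicative scatter
(``y' = a*y + b``), and additive Gaussian noise -- the three nuisance
effects the pretreatment step is designed to remove.

The FT-MIR grid covers the two analysis segments 3700-2620 and
1800-650 cm^-1 (1150 points by default); the NIR grid covers
10,000-4000 cm^-1 (1545 points).  The default class sizes
(40, 40, 36, 40, 40) give the study scale of 196 samples.

All randomness descends from one integer seed through
``numpy.random.SeedSequence.spawn`` so the two modality streams are
independent but jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_core import Modality, SpectralBlock

DEFAULT_CLASS_SIZES = (40, 40, 36, 40, 40)

# Backbone band centers (cm^-1): prominent absorptions of powdered rhizome
# material (O-H/C-H stretches, carbonyl/carboxyl bands, carbohydrate
# fingerprint region; NIR overtone/combination bands).
FTMIR_BACKBONE = (3382.0, 3334.0, 2930.0, 1743.0, 1653.0, 1610.0, 1456.0,
                  1414.0, 1370.0, 1242.0, 1150.0, 1078.0, 1020.0, 922.0)
NIR_BACKBONE = (8347.0, 7256.0, 6950.0, 6324.0, 5686.0, 5169.0, 4750.0, 4300.0)


@dataclass
class ClassProfile:
    """Peak parameters for one class in one or both modalities.

    ``peaks`` maps a modality to an array of ``(center, height, width)``
    rows.  ``height_mult`` / ``center_shift`` give, per modality, the
    class-specific multiplier and shift for each peak (1.0 / 0.0 for
    non-discriminative peaks).
    """

    class_id: int
    peaks: dict[Modality, np.ndarray]
    height_mult: dict[Modality, np.ndarray] = field(default_factory=dict)
    center_shift: dict[Modality, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mod, pk in self.peaks.items():
            pk = np.atleast_2d(np.asarray(pk, float))
            self.peaks[mod] = pk
            if np.any(pk[:, 1] <= 0):
                raise ValueError(f"class {self.class_id} {mod}: non-positive peak height")
            if np.any(pk[:, 2] <= 0):
                raise ValueError(f"class {self.class_id} {mod}: non-positive peak width")
            self.height_mult.setdefault(mod, np.ones(len(pk)))
            self.center_shift.setdefault(mod, np.zeros(len(pk)))
            if len(self.height_mult[mod]) != len(pk) or len(self.center_shift[mod]) != len(pk):
                raise ValueError(f"class {self.class_id} {mod}: modifier length mismatch")


@dataclass
class NoiseModel:
    """Nuisance-effect amplitudes applied to every simulated spectrum.

    additive_sd
        Standard deviation of white absorbance noise.
    baseline_amp
        Amplitude range of the random low-order polynomial baseline
        (coefficients drawn uniformly in ``[-baseline_amp, baseline_amp]``).
    scatter_gain / scatter_offset
        Half-widths of the per-sample multiplicative gain ``a ~ U(1-g, 1+g)``
        and additive offset ``b ~ U(-o, o)``; SNV is the exact inverse of
        this corruption.
    baseline_degree
        Degree of the baseline polynomial.
    """

    additive_sd: float = 0.005
    baseline_amp: float = 0.05
    scatter_gain: float = 0.1
    scatter_offset: float = 0.02
    baseline_degree: int = 2

    def __post_init__(self) -> None:
        for name in ("additive_sd", "baseline_amp", "scatter_gain", "scatter_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_grids(ftmir_n: int = 1150, nir_n: int = 1545) -> tuple[np.ndarray, np.ndarray]:
    """Build the two analysis wavenumber grids, descending (spectroscopic order).

    The FT-MIR grid spans exactly the retained segments 3700-2620 and
    1800-650 cm^-1, splitting ``ftmir_n`` points between them in proportion
    to segment width (1080 and 1150 cm^-1).  The NIR grid spans
    10,000-4000 cm^-1 with ``nir_n`` evenly spaced points.
    """
    if ftmir_n < 2 or nir_n < 2:
        raise ValueError("grids need at least 2 points")
    seg1 = (3700.0, 2620.0)  # width 1080
    seg2 = (1800.0, 650.0)   # width 1150
    w1 = seg1[0] - seg1[1]
    w2 = seg2[0] - seg2[1]
    n1 = int(round(ftmir_n * w1 / (w1 + w2)))
    n1 = min(max(n1, 1), ftmir_n - 1)
    n2 = ftmir_n - n1
    g1 = np.linspace(seg1[0], seg1[1], n1)
    g2 = np.linspace(seg2[0], seg2[1], n2)
    ftmir = np.concatenate([g1, g2])
    nir = np.linspace(10_000.0, 4000.0, nir_n)
    return ftmir, nir


def _gauss(grid: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((grid - center) / width) ** 2)


def class_mean_spectrum(grid: np.ndarray, profile: ClassProfile, modality: Modality) -> np.ndarray:
    """Noise-free class mean: sum of class-adjusted Gaussian peaks."""
    peaks = profile.peaks[modality]
    mult = profile.height_mult[modality]
    shift = profile.center_shift[modality]
    lo, hi = grid.min(), grid.max()
    y = np.zeros_like(grid)
    for (c, h, w), m, s in zip(peaks, mult, shift):
        if not (lo <= c <= hi):
            raise ValueError(f"peak center {c} outside grid span [{lo}, {hi}]")
        y += _gauss(grid, c + s, h * m, w)
    return y


def default_profiles(
    ftmir_grid: np.ndarray,
    nir_grid: np.ndarray,
    n_classes: int = 5,
    effect: float = 0.12,
    rng: np.random.Generator | None = None,
) -> list[ClassProfile]:
    """Five classes sharing the backbone bands, with subtle per-class tweaks.

    Each class perturbs a rotating subset of backbone peaks in both
    modalities: height multipliers ``1 +/- effect`` (default 12 %, inside
    the realistic 5-20 % window) and center shifts up to 4 cm^-1.
    """
    rng = rng or np.random.default_rng(0)
    lo_m, hi_m = ftmir_grid.min(), ftmir_grid.max()
    mir_centers = np.array([c for c in FTMIR_BACKBONE if lo_m <= c <= hi_m])
    nir_centers = np.array([c for c in NIR_BACKBONE if nir_grid.min() <= c <= nir_grid.max()])
    profiles = []
    for k in range(1, n_classes + 1):
        peaks = {
            Modality.FTMIR: np.column_stack([
                mir_centers,
                np.full(len(mir_centers), 0.6),
                np.full(len(mir_centers), 25.0),
            ]),
            Modality.NIR: np.column_stack([
                nir_centers,
                np.full(len(nir_centers), 0.5),
                np.full(len(nir_centers), 120.0),
            ]),
        }
        hm = {Modality.FTMIR: np.ones(len(mir_centers)), Modality.NIR: np.ones(len(nir_centers))}
        cs = {Modality.FTMIR: np.zeros(len(mir_centers)), Modality.NIR: np.zeros(len(nir_centers))}
        for mod, centers in ((Modality.FTMIR, mir_centers), (Modality.NIR, nir_centers)):
            npk = len(centers)
            # rotate which peaks discriminate so classes differ pairwise
            idx = [(k - 1 + 2 * j) % npk for j in range(3)]
            for j, i in enumerate(idx):
                sign = 1 if (k + j) % 2 == 0 else -1
                hm[mod][i] = 1.0 + sign * effect
                cs[mod][i] = sign * min(4.0, 2.0 + j)
        profiles.append(ClassProfile(class_id=k, peaks=peaks, height_mult=hm, center_shift=cs))
    return profiles


def _simulate_modality(
    grid: np.ndarray,
    modality: Modality,
    n_per_class: tuple[int, ...],
    profiles: list[ClassProfile],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    rows = []
    # normalized abscissa keeps baseline polynomial scale grid-independent
    t = np.linspace(-1.0, 1.0, grid.size)
    for prof, n in zip(profiles, n_per_class):
        mean = class_mean_spectrum(grid, prof, modality)
        for _ in range(n):
            y = mean.copy()
            if noise.baseline_amp > 0:
                coef = rng.uniform(-noise.baseline_amp, noise.baseline_amp,
                                   noise.baseline_degree + 1)
                y = y + np.polyval(coef, t)
            a = rng.uniform(1 - noise.scatter_gain, 1 + noise.scatter_gain)
            b = rng.uniform(-noise.scatter_offset, noise.scatter_offset)
            y = a * y + b
            if noise.additive_sd > 0:
                y = y + rng.normal(0.0, noise.additive_sd, grid.size)
            rows.append(y)
    return np.vstack(rows)


def simulate_blocks(
    n_per_class: tuple[int, ...] = DEFAULT_CLASS_SIZES,
    profiles: list[ClassProfile] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    ftmir_n: int = 1150,
    nir_n: int = 1545,
) -> tuple[SpectralBlock, SpectralBlock]:
    """Simulate row-aligned FT-MIR and NIR blocks.

    Returns two blocks with identical ``sample_ids``/``labels``.  The default
    configuration yields the study scale: 196 samples, 1150 FT-MIR and 1545
    NIR variables in five classes.
    """
    ftmir_grid, nir_grid = make_grids(ftmir_n, nir_n)
    if profiles is None:
        profiles = default_profiles(ftmir_grid, nir_grid, n_classes=len(n_per_class))
    if len(profiles) != len(n_per_class):
        raise ValueError("one profile per class required")
    if any(n < 1 for n in n_per_class):
        raise ValueError("every class needs at least one sample")
    noise = noise if noise is not None else NoiseModel()
    ss = np.random.SeedSequence(seed)
    rng_mir, rng_nir = (np.random.default_rng(s) for s in ss.spawn(2))
    X_mir = _simulate_modality(ftmir_grid, Modality.FTMIR, tuple(n_per_class), profiles, noise, rng_mir)
    X_nir = _simulate_modality(nir_grid, Modality.NIR, tuple(n_per_class), profiles, noise, rng_nir)
    labels = np.concatenate([
        np.full(n, prof.class_id) for prof, n in zip(profiles, n_per_class)
    ])
    sample_ids = [f"S{i + 1:03d}" for i in range(labels.size)]
    mir = SpectralBlock(Modality.FTMIR, ftmir_grid, X_mir, sample_ids, labels)
    nir = SpectralBlock(Modality.NIR, nir_grid, X_nir, list(sample_ids), labels.copy())
    return mir, nir


def make_complementary_scenario(
    seed: int = 0,
    ftmir_n: int = 1150,
    nir_n: int = 1545,
    n_per_class: tuple[int, ...] = DEFAULT_CLASS_SIZES,
    effect: float = 0.25,
    noise: NoiseModel | None = None,
) -> tuple[tuple[SpectralBlock, SpectralBlock], dict[str, np.ndarray]]:
    """Scenario where the two modalities carry complementary class information.

    FT-MIR separates classes 1-3 strongly and 4/5 only weakly; NIR does the
    converse.  Neither block alone can resolve all five classes cleanly, so
    any sensible fusion beats each single block -- the property the fusion
    strategies are meant to exploit.

    The scenario's default additive noise (sd 0.03) is deliberately higher
    than the plain generator's: it puts the per-variable signal-to-noise in
    the regime of real powder spectra, where no single wavenumber separates
    the classes and classifiers must pool evidence across whole band
    supports.  That makes the ground-truth masks meaningful for
    selection-recovery checks: an all-relevant or region-level selector must
    retain most of each discriminative band, not just one proxy point.

    Returns the two blocks plus ``{"FTMIR": mask, "NIR": mask}`` boolean
    masks marking the grid points inside the discriminative peak supports
    (within 2 widths of a perturbed peak center).
    """
    ftmir_grid, nir_grid = make_grids(ftmir_n, nir_n)
    profiles = default_profiles(ftmir_grid, nir_grid, n_classes=len(n_per_class), effect=0.0)
    weak, strong = 0.2 * effect, effect
    # Class identity rides on a small pool of backbone bands per modality
    # (four each): every class perturbs three of them with class-specific
    # signs and shifts.  A small pool keeps the truly discriminative
    # variables a minority of the grid, as in real selected-variable counts.
    pool = 4
    disc_idx: dict[Modality, set[int]] = {Modality.FTMIR: set(), Modality.NIR: set()}
    for prof in profiles:
        k = prof.class_id
        for mod in (Modality.FTMIR, Modality.NIR):
            if mod is Modality.FTMIR:
                amp = strong if k in (1, 2, 3) else weak
            else:
                amp = strong if k in (4, 5) else weak
            idx = [(k - 1 + j) % pool for j in range(3)]
            for j, i in enumerate(idx):
                sign = 1 if (k + j) % 2 == 0 else -1
                prof.height_mult[mod][i] = 1.0 + sign * amp
                prof.center_shift[mod][i] = sign * min(4.0, 1.0 + j)
                disc_idx[mod].add(i)
    # ground truth: variables whose noise-free between-class signal spread is
    # a substantial fraction (>= 50%) of the modality's maximum spread --
    # i.e. the core of each strongly perturbed band, not its faint tails
    masks: dict[str, np.ndarray] = {}
    for mod, grid in ((Modality.FTMIR, ftmir_grid), (Modality.NIR, nir_grid)):
        means = np.array([class_mean_spectrum(grid, p, mod) for p in profiles])
        spread = means.max(axis=0) - means.min(axis=0)
        masks[mod.value] = spread >= 0.5 * spread.max()
    if noise is None:
        noise = NoiseModel(additive_sd=0.03)
    blocks = simulate_blocks(
        n_per_class=n_per_class, profiles=profiles, noise=noise, seed=seed,
        ftmir_n=ftmir_n, nir_n=nir_n,
    )
    return blocks, masks
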