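# spectrafuse

Two-block chemometric origin classification for vibrational spectroscopy:
FT-MIR + NIR metabolic fingerprints fused at the data, feature, or decision
level.

## What this is for

Herbal raw materials (here: dried, powdered *Paris polyphylla* var.
*yunnanensis* rhizomes as the motivating system) carry geographic-origin
information in their infrared fingerprints, but a single spectroscopy sees
only part of the chemistry.  `spectrafuse` implements the complete
discrimination workflow for two spectral blocks measured on the same
samples — an FT-MIR block (analysis regions 3700–2620 and 1800–650 cm⁻¹) and
an NIR block (10,000–4000 cm⁻¹) — for analysts who want a tested, scriptable
version of the protocol rather than a chain of GUI tools:

* **Pretreatment**: SNV, Savitzky–Golay first/second derivatives (FD/SD) and
  their SNV composites, ranked per block by R², Q², RMSEE, RMSECV and
  calibration accuracy.
* **Splitting**: deterministic per-class Kennard–Stone partition at 2:1
  (calibration:validation), computed once and reused by every model.
* **Classifiers**: PLS-DA (PLS2 on one-hot class indicators, auto component
  selection by cross-validated Q², VIP scores, permutation overfit test) and
  a bagged CART random forest tuned by its out-of-bag error curve
  (n_tree from the smooth region of the curve, m_try by grid scan).
* **Variable selection**: correlation-PCA with the Kaiser eigenvalue > 1
  rule, random-forest recursive feature elimination (5 variables per step,
  10-fold CV error curve partitioned into irrelevant / interference /
  important regions), and Boruta (confirmed + tentative retained).
* **Fusion**: low-level (concatenate raw blocks), mid-level (concatenate
  selected features per block), and high-level (decision fusion): per-block
  classifier scores combined by four fuzzy aggregation operators — min, max,
  product, average — each voting for its maximal class(es) with a 0.01
  near-tie epsilon, resolved by plurality; ties yield a multi-class
  ("multiple discriminated") decision.
* **Reporting**: per-class efficiency √(SEN·SPE) and overall accuracy for
  calibration and validation sets, plus a reproducibility manifest (seeds,
  per-stage variable counts, output hashes, leakage warnings).

The real 196-sample dataset behind the protocol is not publicly deposited,
so the package ships a synthetic generator that reproduces the structure the
analysis assumes — shared peak backbone across classes, subtle class shifts,
baseline drift, multiplicative scatter, additive noise, and complementary
class information split between the two blocks.  All tests and the worked
examples run on it.  See `docs/methods.md` for the model details and design
decisions.

## Worked example

`examples/01_simulate_and_split.py` simulates the study-scale paired blocks
and builds the Kennard–Stone split:

```
FT-MIR block: 196 samples x 1150 variables (3700-650 cm^-1)
NIR block:    196 samples x 1545 variables (10000-4000 cm^-1)

calibration: 128 samples, validation: 68 samples
  class 1: 26 calibration / 14 validation
  class 2: 26 calibration / 14 validation
  class 3: 24 calibration / 12 validation
  class 4: 26 calibration / 14 validation
  class 5: 26 calibration / 14 validation
```

The 128/68 totals and the per-class counts are fully determined by the class
sizes (40, 40, 36, 40, 40) and the 2:1 rule; the split is deterministic.

`examples/02_pretreatment_ranking.py` corrupts the spectra with scatter and
baseline drift and ranks the six pretreatments:

```
method        R2      Q2   RMSEE  RMSECV    acc
raw        0.006  -0.028  0.3987  0.4055  21.9%
SNV        0.986   0.984  0.0470  0.0506 100.0%
FD         0.982   0.979  0.0537  0.0581 100.0%
SD         0.986   0.984  0.0470  0.0499 100.0%
SNV-FD     0.977   0.973  0.0608  0.0653 100.0%
SNV-SD     0.982   0.979  0.0539  0.0574 100.0%

best pretreatment for this block: SD
```

Raw spectra are unusable under multiplicative scatter and drift (R² ≈ 0);
every correcting pretreatment restores the class signal, and the second
derivative wins the rank-sum over the five criteria.  The remaining examples
cover variable selection with ground-truth recovery
(`03_variable_selection.py`), the fusion levels and decision voting
(`04_fusion_levels.py`), and the full pipeline with its report tables
(`05_full_pipeline.py`).

A thin CLI wraps the two shell-worthy entry points:

```bash
spectrafuse simulate --seed 1 --out data/          # write paired CSVs
spectrafuse run --seed 1 --out results/            # full experiment
```

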