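# Methods

## Problem and scope

`spectrafuse` implements a two-block chemometric workflow for geographic
origin classification of plant material from vibrational spectra: an FT-MIR
block (analysis regions 3700–2620 and 1800–650 cm⁻¹, 1150 variables by
default) and an NIR block (10,000–4000 cm⁻¹, 1545 variables) measured on the
same samples, with five origin classes.  The workflow covers spectral
pretreatment, a per-class Kennard–Stone calibration/validation split, PLS-DA
and random-forest classifiers, three variable-selection routes, and low-,
mid- and high-level fusion of the two blocks.  Because no real dataset ships
with the package, a synthetic generator reproduces the statistical structure
the analysis assumes; everything downstream is exercised against it.

## Synthetic spectra

Each sample spectrum is a sum of Gaussian bands on the modality's wavenumber
grid, plus three nuisance effects applied per sample:

* additive white noise, sd 0.005 absorbance units by default;
* a random low-order polynomial baseline (degree 2, coefficient amplitude
  0.05) on a normalized abscissa;
* multiplicative scatter `y' = a·y + b` with `a ~ U(0.9, 1.1)`,
  `b ~ U(−0.02, 0.02)` — chosen so SNV is its exact inverse, which makes the
  benefit of SNV demonstrable rather than assumed.

The backbone band positions are prominent absorptions of dried, powdered
rhizome material (O–H/C–H stretches near 3382, 3334, 2930 cm⁻¹; carbonyl and
carboxyl bands at 1743, 1653, 1610 cm⁻¹; the carbohydrate fingerprint region
1456–922 cm⁻¹; NIR overtone/combination bands 8347–4300 cm⁻¹).  All classes
share the backbone; class identity enters as small height multipliers
(±12 % by default) and center shifts (≤ 4 cm⁻¹) on a rotating subset of
bands, emulating fingerprints that look nearly identical across origins.
Default class sizes are (40, 40, 36, 40, 40), i.e. 196 samples.  Gaussian
line shapes were chosen over Lorentzian for simplicity: the tests need a
realistic correlation structure, not spectroscopic fidelity.  One integer
seed drives everything through `numpy.random.SeedSequence.spawn`, so the two
modality streams are independent but jointly reproducible.

### Complementary scenario

`make_complementary_scenario` builds the configuration the fusion claims are
tested on: FT-MIR separates classes 1–3 strongly and 4–5 weakly (20 % of the
strong amplitude), NIR the converse.  Class identity rides on a pool of four
backbone bands per modality; each class perturbs three of them with
class-specific signs and shifts.  Two deliberate design choices:

* **Noise level.**  The scenario's additive noise default is 0.03 (six times
  the plain generator's), putting per-variable signal-to-noise in the regime
  of real powder spectra where no single wavenumber separates the classes
  and classifiers must pool evidence across whole band supports.  Without
  this, a handful of variables suffices and selection recovery is
  meaningless.
* **Ground-truth mask.**  The returned mask marks variables whose
  noise-free between-class spread is at least 50 % of the modality's maximum
  spread — the core of each strongly perturbed band.  Band tails carry some
  signal too, but they are redundant with the core; a minimal-optimal
  selector cannot and should not retain them, so they are not counted as
  ground truth.

What the generator does **not** emulate: instrument line-shape physics,
detector response, atmospheric and water-vapor bands, ATR penetration-depth
effects, and batch/session drift.  Tests passing on this generator therefore
show that the pipeline's logic and statistics behave as specified under the
assumed data structure, not that any particular accuracy will be achieved on
real spectra.

## Pretreatment

Candidates are raw, SNV, first and second Savitzky–Golay derivatives (FD,
SD) and the composites SNV-FD / SNV-SD, applied SNV first (reading the name
left to right).  SNV uses the n−1 denominator.  Derivatives use window 15,
polynomial order 2 by default — a common chemometric choice that the
protocol's source software leaves unstated — and are exposed in `RunConfig`
because they matter for reproducibility.  Savitzky–Golay is evaluated with
polynomial-fit edge handling (`mode="interp"`), keeping the output aligned
with the grid.  Candidates are ranked by R², Q², RMSEE, RMSECV and
calibration accuracy of a PLS-DA fit, aggregated by rank-sum with accuracy
as tie-breaker.

Region exclusion treats intervals as closed, except that an interval
endpoint strictly inside the grid span is taken as a boundary shared with a
retained segment and kept: excluding 4000–3700 and 2620–1800 cm⁻¹ from a
full-range mid-IR grid retains the points at exactly 3700, 2620 and
1800 cm⁻¹, because the retained analysis segments are the closed intervals
3700–2620 and 1800–650 cm⁻¹.

## Split

Each class is split 2:1 into calibration and validation by classic
Kennard–Stone max–min selection (farthest pair first, then repeatedly the
point maximizing its minimum distance to the selected set; ties break to the
lowest index in a canonical by-sample-id ordering, making the result
invariant to row order).  The calibration count is `floor(2n/3)` per class —
the convention that reproduces the printed study bookkeeping, 128 = (26, 26,
24, 26, 26) calibration and 68 = (14, 14, 12, 14, 14) validation samples for
class sizes (40, 40, 36, 40, 40); conventional rounding would give 27 for a
class of 40 and break those counts.  Distances are computed on the
per-variable autoscaled concatenation of both blocks so that a single split
serves every downstream model.  The protocol's source does not say which
feature space its split used; the pipeline computes the split on the raw
(region-excluded) blocks to avoid a circular dependence of pretreatment
ranking on the split.

## PLS-DA

PLS-DA is PLS2 regression (NIPALS, via scikit-learn) of a one-hot class
indicator matrix on the mean-centered spectra; a sample's class is the
argmax of the predicted indicator row.  Class-membership scores clip
negative predictions at zero and renormalize rows to sum 1 (an all-zero row
becomes uniform).  The component count is chosen by 7-fold stratified
cross-validated Q², growing while the gain is ≥ 0.01, capped at 15; folds of
7 follow common chemometric software convention.  Quality metrics: RMSEE /
RMSECV / RMSEP are root-mean-squares over all entries of the indicator
matrix on the calibration fit, the cross-validation refits, and the
validation predictions respectively; R² = 1 − SS_res/SS_tot and
Q² = 1 − PRESS/SS_tot.

The permutation overfit guard refits the model under random label
permutations (per tested class, 200 by default), plotting R² and Q² against
the absolute correlation between permuted and original indicator columns and
reading the least-squares intercepts at zero correlation; the unpermuted
model enters at correlation 1.  A Q² intercept ≥ 0.05 flags overfitting.
VIP scores follow the standard formula
`VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` and satisfy
`Σ_j VIP_j² = p`.

## Random forest

The forest is bagged CART over scikit-learn decision trees with bootstrap
samples of size n and `m_try` candidate features per split.  The bagging
loop lives in the package because the tuning protocol needs the cumulative
out-of-bag error after every tree and class scores as hard tree-vote
fractions, neither of which a stock forest exposes.  OOB error counts only
samples that were out of bag at least once.

Tuning starts at `n_tree = 2000`, `m_try = √p`.  The chosen `n_tree` is the
earliest global minimum of the OOB curve lying inside the longest run of
tree counts whose error is within `1/(2·n_cal)` (half a misclassification)
of the minimum — an operationalization of "pick from the smooth region of
the curve", which is otherwise a visual rule.  `m_try` is then scanned on a
12-point geometric grid spanning `√p/4 … 4√p` (deduplicated, clipped to
[1, p]), keeping the lowest-OOB point with ties to the smaller value.

## Variable selection

* **PCs**: PCA of the column-autoscaled matrix (correlation-matrix PCA,
  zero-variance columns dropped with a warning), keeping components with
  eigenvalue > 1.  Autoscaling is required for the Kaiser rule to be
  calibrated (the eigenvalue sum then equals p).  The result is a projector
  applied to new samples.
* **RFE**: variables are ranked once by permutation importance (mean
  decrease in OOB accuracy) of a fitted forest, then dropped five at a time
  while a stratified 10-fold cross-validated RF error is recorded at each
  retained size.  The *important* region ends at the smallest size whose
  error is within one standard error of the curve minimum (1-SE rule); the
  *irrelevant* region is the plateau of largest sizes within one standard
  error of the full-size error; the remainder is *interference*.  The
  important region's variables are returned.  The 1-SE rule replaces a
  by-eye partition of the error curve.
* **Boruta**: canonical all-relevant selection.  Each iteration appends a
  permuted shadow copy of every undecided variable, fits a forest, and
  scores a hit for variables beating the best shadow importance; hit counts
  are tested against Binomial(iter, ½) two-sidedly at α = 0.01 with Holm
  step-down; undecided variables at the iteration cap (100) are tentative.
  Confirmed and tentative sets are both retained, and together with the
  rejected set they partition the variables.
* **VIP**: variables with VIP strictly greater than 1 from a PLS-DA on the
  low-level fused matrix.

Selection scope is switchable and matters: the mid-level fusion protocol
selects on the full sample set, which leaks validation information into the
selection — the pipeline reproduces this faithfully and attaches an explicit
leakage warning to the run manifest — while high-level fusion selects on the
calibration set only.

## Fusion and decision voting

Low-level fusion concatenates the two pretreated matrices (1150 + 1545 =
2695 columns at study scale), retaining per-column provenance.  Mid-level
fusion concatenates per-block selected features (columns, or PC scores for
the PCs route).  High-level fusion combines the two blocks' fitted
classifiers per sample: the two class-score vectors are aggregated by four
fuzzy operators — element-wise minimum, maximum, product and average — and
each operator votes for its maximal class(es).  Any class whose combined
score is within ε = 0.01 of the maximum counts as maximal; a gap of exactly
ε still ties (a 1e−12 slack absorbs floating-point error).  The final
decision is the plurality class across the four operator votes; ties in the
vote count yield the union of the tied classes.  The plurality rule is the
single most consequential reconstruction in the package: the source protocol
shows a worked 3-votes-to-1 example resolved to the majority class but never
states the combination rule in general; ties-to-union is this package's
choice and is surfaced in the report output.

A final set with more than one class is a *multiple discrimination*.  It
never reduces accuracy — a sample counts correct if its true class is in the
set — but each spurious class in the set collects a false positive,
depressing that class's efficiency.  Product-operator scores are not
renormalized (argmax is scale-free), and with pathologically flat vectors
all qualifying classes are kept.

## Metrics and reporting

Per class (one-vs-rest): SEN = TP/(TP+FN), SPE = TN/(TN+FP), efficiency =
√(SEN·SPE).  Overall accuracy is the fraction of samples whose true class is
in the predicted set.  Report tables hold one row per dataset × model with
per-class efficiencies and accuracy for calibration and validation sets;
fractions are stored exactly and rendered as percentages to two decimals.
For non-fused models the predicted set is always the singleton argmax; the
ε tie rule applies only inside high-level fusion voting.  The run manifest
embeds the configuration, the per-stage seeds, stage-by-stage variable
counts, output hashes and warnings, and a rerun from the same configuration
is bit-identical.

## Problem sizes used in tests and the acceptance script

The acceptance script simulates study-scale blocks (196 × 1150 and
196 × 1545) and recomputes the split bookkeeping; it runs in seconds.  The
statistical test suites run on reduced grids — typically 100 variables per
block at the study's n = 196, forests of 150–300 trees, 50 label
permutations — sizes chosen so the full suite completes on a single CPU in
minutes while leaving the tested properties (selection recovery, fusion
benefit, overfit guard) comfortably observable.

## Known limitations

* The synthetic generator's class structure is far simpler than real
  geographic chemotype variation; absolute accuracies on synthetic data say
  nothing about field performance.
* The plurality/union decision rule and the 1-SE RFE regioning are
  reconstructions of visually stated procedures; alternative readings exist.
* Permutation-importance RFE is O(trees × variables) per ranking and is the
  slowest route at full scale.
* PLS-DA assumes the indicator regression's argmax is a good posterior
  surrogate; no probability calibration beyond clipping/renormalization is
  attempted.
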