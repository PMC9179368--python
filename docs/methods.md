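# Methods

This note documents the models, conventions and numerical choices behind
`mrsidh`, including the places where the design was genuinely open and
what the synthetic experiments do and do not demonstrate.

## Chemical-shift geometry

A spectrum acquired with transmitter frequency f₀ (MHz) and spectral
width SW (Hz) spans SW/f₀ ppm.  When f₀ is not supplied it is derived
from the nominal proton gyromagnetic ratio, 42.576 MHz/T (1.5 T →
63.864 MHz; 3.0 T → 127.728 MHz); real magnets deviate slightly, so f₀
is user-overridable.  The axis runs high → low ppm (standard NMR
plotting orientation), has spacing SW/(f₀·n) with *n* points, and its
first point sits at `center_ppm + span/2`; `center_ppm` defaults to
4.7 ppm (water).  The absolute window placement is irrelevant after
choline anchoring, but a fixed convention is needed for simulation,
plotting and window arithmetic.  The two built-in regimes are
3.0 T / 1200 Hz / 1024 pts (reference, spacing ≈ 0.0092 ppm) and
1.5 T / 1000 Hz / 1024 pts (spacing ≈ 0.0153 ppm).

Intensities are real absorption-mode values in vendor arbitrary units;
complex FIDs, phasing and water-reference scaling are out of scope.

## Synthetic cohorts

Each metabolite is a single Lorentzian of unit peak height,
L(x; c, w) = (w/2)² / ((x−c)² + (w/2)²), with linewidth specified in Hz
(default 5 Hz) and converted to ppm by f₀ — so ppm linewidth halves from
1.5 T to 3 T, emulating the better spectral resolution at high field.
Multiplets, J-coupling/TE modulation, macromolecule resonances and
residual water are not modeled.

Default basis (arbitrary units, wild-type means): NAA 1.2 (2.01 ppm),
Cr 0.8 (3.03), Cr2 0.3 (3.93), Cho 1.0 (3.22), M-Ins 0.4 (3.53),
Glx 0.5 (2.35), 2-HG 0.25 (2.24, mutant-only), Lac/Lip 0.5 (1.30).
Group multipliers encode the in-vivo contrasts: M-Ins ×1.75 in mutants,
Lac/Lip ×0.4 in mutants, 2-HG ×0 in wild type.  These amplitudes are
free simulator parameters chosen on a unit scale where the QC
thresholds (Cho > 0.2, Cr > 0.1) are meaningful; they are not measured
effect sizes, which are not available quantitatively.

Per-spectrum nuisance model, with defaults emulating a routine short-TE
clinical acquisition: log-normal amplitude variability with CV 0.25 per
peak; one global frequency jitter per spectrum, N(0, 0.02 ppm) — a rigid
calibration offset, the dominant frequency error in single-voxel MRS; a
smooth random polynomial baseline (order ≤ 3) affinely mapped to
[0, 0.1]; i.i.d. Gaussian noise with SD 0.05 (5% of Cho); and a global
vendor scale drawn uniformly from 0.5–2.0.  The baseline is non-negative
because absorption-mode short-TE baselines (macromolecule/lipid
background) are broad positive humps; a sign-symmetric baseline of the
same size can drive the total window integral negative, which would make
area normalization meaningless.  Cohorts derive per-spectrum RNG streams
from one master seed by index, so contents are reproducible and
independent of generation order.

## Quality control

The amplitude of a metabolite is its baseline-corrected peak maximum:
the maximum intensity within ±0.08 ppm of the nominal position minus the
median intensity over two adjacent 0.08 ppm flanking bands.  This
estimator is invariant under additive offsets, equivariant under
positive scaling, and deliberately simple — vendor software may instead
report fitted amplitudes, so the thresholds (strict inequalities
Cho > 0.2, Cr > 0.1, M-Ins > 0, Cr2 > 0 by default) are fully
configurable and QC always runs on raw, pre-normalization intensities.
Predefined cohort exclusions are applied before the QC gate; a spectrum
failing both is counted once, under its predefined reason, and
`retained + Σ ledger = initial` always holds.

## Harmonization

Anchoring is a rigid ppm shift only (no stretch): the choline maximum is
detected in 3.22 ± 0.15 ppm and moved onto the anchor.  The grid argmax
is refined to sub-grid precision by a three-point parabolic fit;
without refinement the anchor is quantized by up to half a source grid
step (0.0077 ppm at 1.5 T), which dominates the cross-regime residual.
Flat or tied maxima fall back to the grid point nearest 3.22 ppm (ties
then break toward higher ppm).  The anchor itself is snapped to the
nearest reference-grid point, and a spectrum whose axis already equals
the reference window grid passes through unshifted — together these make
harmonization exactly idempotent, since re-detection on harmonized data
would otherwise re-shift by the parabolic vertex bias that
neighboring-peak tails induce (~10⁻⁴ ppm).

Resampling is linear interpolation onto the 3 T reference grid
restricted to the 4.2–0.5 ppm analysis window: the window excludes
residual water (~4.7 ppm) while containing every diagnostic region, and
linear interpolation is monotone and artifact-free when moving from the
coarser-in-ppm 1.5 T grid to the finer 3 T grid.  Normalization divides
by the trapezoidal integral over the window, removing the vendor
arbitrary-unit scale; a non-positive integral raises a
degenerate-spectrum error.  Coverage of the window is required after
shifting, with a 10⁻⁹ ppm tolerance for floating-point noise.
Eddy-current/phase correction, water removal and lineshape matching
across field strengths are out of scope — consequently, spectra
simulated with the same linewidth in Hz at different fields harmonize to
vectors that agree in peak positions and group contrasts but differ in
lineshape width (in ppm), and classification must absorb that mismatch
(it does; see the regime-transfer experiment).

## Classification

"Most differentially expressed" is operationalized as the absolute
Welch two-sample *t* statistic, which tolerates unequal group variances;
zero-variance features get statistic 0 and rank last, ties keep the
lower index.  The feature count is selected from candidates
{1, 2, 3, 5, 10, 20, 50, 100} by stratified 5-fold cross-validation with
a fixed seed, with ranking redone inside every training fold — selection
outside the folds would leak information and inflate fold accuracies.
Ties in mean CV accuracy resolve to the smallest k.  Each class needs at
least 4 members (folds are reduced to ⌊min-class/2⌋ when necessary so
every training part retains ≥ 2 per class).

The final model re-ranks on all training data, standardizes the
selected features with training-set statistics (stored in the model; a
meaningful fixed C requires scaled features), and fits the soft-margin
linear SVM primal with C = 1 via libsvm (the per-sample hinge-sum
convention; duplicating a training point doubles its hinge weight).  The
decision threshold is fixed at 0 and never recalibrated on test data; a
score of exactly 0 is called wild type.  Model files are versioned JSON
documents carrying indices, ppm positions, weights, bias, scaler
statistics and the CV table, so predictions need no retraining and no
access to the training data.

## Diagnostics

With "mut" as the positive class: sensitivity tp/n₁, specificity tn/n₂,
accuracy, PPV, NPV, prevalence, LR⁺ = sens/(1−spec),
LR⁻ = (1−sens)/spec.  Proportion CIs are exact Clopper–Pearson
(beta-quantile form); LR CIs use the log method,
exp(ln LR ± z·SE) with SE(ln LR⁺) = √(1/tp − 1/n₁ + 1/fp − 1/n₂) and
SE(ln LR⁻) = √(1/fn − 1/n₁ + 1/tn − 1/n₂).  PPV/NPV intervals use the
standard logit (Wald on log-odds) method and are tagged accordingly:
no standard method (exact binomial, Wilson, logit) reproduces the
PPV/NPV interval bounds printed in the source clinical literature, so
those two intervals are reported under an explicitly named method
instead of being matched.  Statistics with zero denominators are flagged
undefined rather than raised, so partial reports are always available.
AUC is the trapezoidal area under the empirical ROC curve, equal to the
Mann–Whitney pair statistic with ties counted ½; AUC confidence
intervals are out of scope.

## Synthetic experiments: what they show

The regime-transfer experiment (train 3 T n = 17/17, predict 1.5 T
n = 23/44, 10 seeds) demonstrates that the harmonization + selection +
SVM chain transfers across acquisition regimes under the generator's
group contrasts, with median sensitivity and specificity near 1 and
selected features falling in the 2-HG / M-Ins / Lac-Lip regions.  It
does **not** estimate clinical performance: real spectra carry
overlapping multiplets, macromolecule baselines, voxel-placement and
partial-volume variability, and smaller, less consistent group effects
than the simulator's defaults.  Published in-vivo results with this
type of full-spectrum approach reach sensitivities/specificities in the
0.7–0.95 range, well below the synthetic ceiling.

The feature-count recovery experiment constructs 200 × 100 Gaussian
matrices in which exactly two columns are informative and each is
necessary (the positive group splits into two subgroups, each elevated
by 8 SD in one column only, so one feature caps near 75% accuracy while
two reach ~100%).  Cross-validated selection then returns k\* = 2 in
most seeded runs; occasional k\* ∈ {3, 5} arise when an equally-scoring
larger candidate wins a CV tie by a single held-out sample.  Problem
sizes throughout (10 seeds, 2000 coverage draws, ≤ 20-point SVM oracle
instances) were chosen as the smallest that make the Monte-Carlo
tolerances quoted in the tests meaningful.

## Known limitations

* Single-Lorentzian metabolites: no J-coupling, no TE modulation, no
  2-HG multiplet overlap with Glx — the very overlap that makes in-vivo
  2-HG detection hard at 3 T is absent, which flatters the classifier.
* Total-area normalization assumes the window integral is dominated by
  metabolite signal; gross baseline distortions would bias it.
* Rigid-shift alignment cannot correct field-dependent lineshape
  differences or local frequency errors.
* QC amplitude thresholds are in vendor arbitrary units and do not
  transfer across vendors or processing chains without recalibration.
* The LOH 1p/19q subgroup question is included only as a negative
  control (`scripts/loh_negative_control.py`); the package offers no
  supported codeletion-prediction mode.
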