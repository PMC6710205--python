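# Methods

## Signal model and preprocessing

Resting cerebral hemodynamics are treated as a two-input linear
time-invariant system: arterial blood pressure (ABP) and end-tidal CO2
(ETCO2) drive cerebral blood flow velocity (CBFV) through first-order
kernels k_p and k_c. The linearity assumption is adequate for the small
spontaneous fluctuations seen at rest; nonlinear extensions are a
deliberate non-goal (a config flag reserves the extension point but is
rejected if enabled).

Raw waveforms are reduced to beat-to-beat values before modelling:

- **Beat detection**: systolic upstrokes found by thresholding the
  smoothed ABP derivative (threshold 0.4 × the 95th percentile of
  positive derivative values), refined backwards to the preceding
  diastolic minimum; 0.3-s refractory period. On a flat stretch the
  *last* sample attaining the minimum is taken, so dropouts do not
  produce onsets at the start of the flat segment.
- **Beat reduction**: per-beat means for ABP and CBFV; for CO2 the
  end-tidal value — breath-wise local maxima separated by ≥ 1.5 s —
  assigned to beats by sample-and-hold (end-tidal CO2 is a per-breath
  constant, so interpolation would invent detail). Candidate maxima
  suppressed by the separation rule are counted as suspected missed
  breaths and surfaced as warnings.
- **Artifact cleaning**: a beat is rejected when its ABP or CBFV mean
  lies beyond 4 robust SDs (1.4826 × MAD) of the channel median or its
  inter-beat interval falls outside [0.3, 2.0] s; rejected beats are
  linearly interpolated. The robust scale matters: with heavy
  contamination a plain SD is inflated by the artifacts themselves and
  the unusability rule (> 20% rejected) could never fire. Both
  thresholds are conventions, exposed in the config.
- **Uniformisation**: linear interpolation onto a dt = 1 s grid
  (about one beat at rest), each channel demeaned with the mean stored
  as its baseline.

## Kernel estimation

Kernels are expanded on discrete Laguerre functions with pole α
(0 ≤ α < 1), generated by the stable recursion
b_j(m) = α·b_j(m−1) + b_{j−1}(m−1) − α·b_{j−1}(m),
b_0(m) = √(1−α²)·α^m. The family is orthonormal over m = 0..∞ with
truncation error of order α^M at memory M. Defaults: M = 50 samples
(50 s — long enough for slow vasomotor dynamics), L = 2–4 functions per
branch, α grid {0.2, …, 0.8}.

The regression stacks an intercept and the Laguerre convolutions of
both inputs; the first M−1 rows are burn-in (they reference samples
before the record starts) and are excluded rather than zero-padded,
avoiding biased edge estimates. Ordinary least squares by default; a
ridge penalty (intercept unpenalised) is available and advised by the
error message when the design is rank deficient (e.g. duplicated input
channels). Structure selection is an exhaustive (α, L) grid search per
branch minimising validation NMSE on a temporal 70/30 split — temporal,
not random, because random splits leak autocorrelated samples. Ties go
to smaller total L, then smaller α (prefer the simpler model).

## The DVR index

The fitted model is probed with a rectangular 5-s ETCO2 pulse while the
ABP branch is held at baseline (zero deviation, so it contributes
nothing); the intercept is excluded because the response is a deviation.
DVR is the mean of the response over the 5-s window from pulse onset,
divided by the pulse amplitude. Defaults: amplitude 1 mmHg, window =
pulse duration = 5 s. For a linear model DVR is exactly
amplitude-invariant, making the per-mmHg unit convention safe. An
optional flag reports DVR as % of baseline CBFV per mmHg instead
(default off). For a known system the index has the closed form
(1/K)·Σ_{n<K} Σ_{m≤n} k_c(m), used as the recovery oracle throughout
the tests.

## Statistics

- **Group tests**: Welch's unequal-variance t with Satterthwaite df,
  two-sided. This choice is checkable: the group p-values implied by
  published cohort summaries (16 controls vs 36 patients) are
  reproduced by Welch to the printed precision, and not by the
  pooled-variance test. The summary-statistics interface
  (mean, SD, n per group) exists precisely so such printed tables can
  be recomputed.
- **Categorical demographics**: Pearson chi-square on 2×2 counts,
  df = 1, *no* continuity correction (again the variant that reproduces
  the published medication-use p-values).
- **Covariate separation**: OLS of each marker on age, gender (0/1) and
  education (years), all subjects pooled, intercept included, no
  interactions. The adjusted value is the residual plus the fitted
  value at the *control-group* covariate means, so the control-group
  mean is preserved exactly — the recentring convention consistent with
  published before/after tables whose control columns are identical.
- **Correlations**: Pearson r with the t-transform p (n−2 df),
  pairwise-complete deletion for missing cells, n reported per cell;
  per-cell failures leave NaN without aborting the matrix.
- No multiplicity correction across the 11 markers/scores: raw p-values
  with the conventional 0.05 threshold, matching the analysis this
  package mirrors.

## Voxelwise analysis

Across-subject Pearson correlation of DVR with each masked voxel's
metric value, vectorised; zero-variance voxels are excluded (NaN).
Significance is uncorrected p < 0.05 by default with BH-FDR available by
flag; the choice is recorded in the output provenance because voxelwise
correction conventions differ (permutation/TFCE pipelines are out of
scope — volumes must arrive pre-aligned and skeletonised upstream).
Region tables count significant voxels per atlas label with percentages
and flag regions above 30%, plus a whole-mask totals row. Correlations
use unadjusted DVR by default with a flag for covariate-adjusted values.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions for every test:

- **Hemodynamic systems**: Laguerre ground truth (default α = 0.5,
  L = 3 per branch, dt = 1 s, M = 50) with baselines 90 mmHg ABP,
  40 mmHg ETCO2, 60 cm/s CBFV. Input fluctuations are Gaussian noise
  low-pass filtered below 0.1 Hz (the resting variability band; ABP SD
  3 mmHg, ETCO2 SD 1.5 mmHg) — persistently exciting yet physiological.
  CBFV adds white observation noise of configurable SD.
- **Raw waveforms**: beat onsets at i·60/HR plus small positional
  jitter (so the beat count is exact); fixed intra-beat
  systolic/diastolic contour (40 mmHg / 25 cm/s pulse amplitudes)
  superimposed on the slow beat-level means; capnogram-shaped CO2 with
  a per-breath end-tidal plateau. The CO2 branch of the generating
  system is driven by the *breath-held* end-tidal series, because that
  is the only form of ETCO2 any instrument can observe — this keeps the
  generator consistent with the measurement chain (end-to-end DVR
  recovery from raw waveforms is then ~0.2% at zero noise).
- **Cohorts**: 16 controls vs 36 patients by default, with the
  marker/score means and SDs of the emulated study (DVR 1.1546 (0.6461)
  vs 0.5449 (0.6031); MD/RD on the ×10³ scale) and its 11×11 pairwise
  correlation structure. The correlation targets are *pooled-sample*
  quantities, so the within-group Gaussian-copula correlation is solved
  from the pooled target by removing the between-group component fixed
  by the group moments; for the default targets the resulting matrix is
  positive definite. Covariates: age N(65, 7), gender Bernoulli(0.5),
  education N(16, 2) truncated to [10, 22], independent of the markers.
- **Voxel datasets**: per region, a designated fraction of voxels gets
  metric = intercept + slope·DVR + noise across subjects; the rest are
  pure noise; the ground-truth association mask is returned for
  scoring.

Not emulated: MR physics, TBSS skeleton geometry, nonstationary
physiology (posture changes, breath-holds), measurement drift, and any
dependence of covariates on markers. Passing tests therefore show the
*estimator and statistics machinery* are correct under the stated
model, not that the model captures every property of clinical
recordings.

## Numerical choices and degenerate inputs

- Laguerre recursion is exact and stable for all α ∈ [0, 1); Gram
  matrix within 1e-8 of identity at M = 200, α = 0.5.
- Rank deficiency at λ = 0 raises an error advising ridge rather than
  silently returning a minimum-norm solution.
- Degenerate inputs fail loudly: flatline ABP ("no beats detected"),
  both group variances zero, zero-variance correlation inputs, empty
  masks, non-PSD correlation targets (the offending matrix is named).
- NMSE denominators of zero return 0 for a perfect fit and ∞ otherwise.
- All generators are pure functions of their arguments including the
  seed; waveform/report writers are atomic and embed the config hash.

## Problem sizes

Defaults used by the test suite and the acceptance script: 5-min
(300-sample) records for recovery experiments over 100 seeded subjects;
10,000 replicates for type-I-error calibration; 14×14×5 voxel volumes
over 20 datasets for the null voxel fraction; 10×10×3 three-region
volumes for region recovery; n = 10,000 per group for moment-convergence
checks. These sizes give Monte-Carlo error comfortably below the
asserted tolerances.

## Known limitations

- Beat detection is tuned for clean pressure-like waveforms; heavily
  damped or noisy ABP may need threshold adjustment via the config.
- The end-tidal separation rule (1.5 s) undercounts breaths above
  40/min; suspected misses are warned about, not corrected.
- DVR's absolute scale depends on the unit convention (per-mmHg
  deviation average); comparisons across configs should keep the pulse
  spec fixed.
- The voxelwise screen is mass-univariate with no spatial model; region
  percentages inherit whatever correction was chosen for the mask.
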