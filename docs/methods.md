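# Methods

## The analysis model

The pipeline estimates, for each subject and session, how a seed region's
mean time series couples to every other brain voxel, and then tests at the
group level whether that coupling (or its temporal variability) changed
from the pre- to the post-treatment session and whether the change tracks
clinical improvement.

**Static FC.** For seed series `s` and voxel series `y`, both denoised,
`sFC = atanh(r(s, y))` with `r` the full-length Pearson correlation. The
Fisher transform makes the sampling distribution approximately normal with
variance `1/(T−3)`, which is what the downstream t statistics assume
informally. `|r|` is clipped at `1 − 1e−7` before `atanh` so self- and
near-perfect correlations stay finite.

**Dynamic FC variability.** A window of `W` TRs (default 84, i.e. 67 s at
TR = 0.8 s) slides in steps of 1 TR. Within each window the correlation is
computed with Hamming-taper observation weights: with `p_k = w_k / Σw`,

    r_w = Σ p_k (x_k−μx)(y_k−μy) / sqrt(Σ p_k (x_k−μx)² · Σ p_k (y_k−μy)²).

Applying the taper as weights inside the correlation (rather than
pre-multiplying the signals) keeps `r_w ∈ [−1, 1]` exactly and reduces to
plain Pearson for equal weights, which gives the rectangular-taper oracle
used in the tests. Each windowed `r_w` is Fisher-z transformed and the
voxel's dFCv is the sample standard deviation (denominator N−1) of the
windowed z values. The window must span at least one period of the slowest
retained frequency (`W·TR ≥ 1/f_low`; 67.2 s ≥ 66.7 s at the defaults) —
shorter windows are refused as a configuration error because they admit
spurious slow-fluctuation correlations.

**Denoising.** One linear projection per voxel series: the top
`n_compcor = 5` principal components of the standardized noise-region
series are band-passed and regressed out of the band-passed voxel series.
The band-pass is a hard spectral window (FFT, zero every bin outside
[0.015, 0.1] Hz including DC, inverse FFT): exactly zero-phase,
platform-reproducible, and idempotent. Regressors are filtered before the
regression so the projection cannot reintroduce out-of-band power. The
component count is a convention of anatomical CompCor; it is a parameter,
not a finding.

**Group inference.** Per voxel, OLS t statistics with age and sex as
demeaned covariates of no interest: the intercept of `Δ ~ 1 + age + sex`
for the paired test, the slope of `Δ ~ 1 + PC + age + sex` for the
clinical-change correlations (PC = percent change, `100·(post−pre)/pre`).
The null is Freedman–Lane: residuals from the nuisance-only model are
sign-flipped (paired test; exact under symmetric paired errors) or
permuted across subjects (correlation test), the nuisance fit is added
back, and the statistic is recomputed. Statistic maps are enhanced with
TFCE (`E = 0.5`, `H = 2`, 100 height steps, 26-connectivity — the standard
volumetric defaults of the method), each tail on its own sign. The
per-permutation null maximum is taken over both tails (`max |TFCE|`), so
the corrected p-values

    p_v = (1 + #{null maxima ≥ |TFCE_v|}) / (1 + n_perm)

control the family-wise error rate across the whole map and both
directions jointly; the smallest attainable p is `1/(1 + n_perm)`. Under a
whole-data sign flip the positive and negative tails swap exactly.

TFCE is computed by a union-find pass over descending thresholds
(`h = i·dh`, `dh = max/steps`): identical to labelling the suprathreshold
mask at every step and accumulating `e^E · h^H · dh`, verified against an
independent BFS flood-fill oracle at every distinct threshold to 1e−6
relative tolerance. The kernel is JIT-compiled with numba; the first call
in a process pays the compilation cost.

**Clinical screening.** Percent-change vectors are screened once (single
pass) for values more than 3 sample SDs from the mean; flagged subjects
are dropped from that correlation analysis only, as are subjects with a
missing score. The demographic two-sample t uses pooled variance by
default (`equal_var=False` switches to Welch); the 2×2 χ² is Pearson's
without continuity correction. Remission is a post-treatment HDRS score
≤ 7, boundary inclusive.

## The synthetic cohort generator

The generator emulates a two-session depression cohort at the acquisition
parameters of interest (TR = 0.8 s, default T = 604 volumes ≈ 8 min,
default n = 58 subjects) on a small voxel grid. It is deterministic: every
random stream is derived from `(rng_seed, subject, stream-id)`, so a spec
is a complete description of its cohort.

* **Signals.** The seed signal and every noise source are white Gaussian
  noise band-passed to [0.015, 0.1] Hz and standardized, so the synthetic
  data already live in the analysis band and test outcomes isolate the
  estimators from filter effects.
* **Coupling.** A target voxel is `y_t = a_t·s_t + √(1−a_t²)·ε_t` with
  `a_t = static_r + mod_amplitude·sin(2πt·TR/period)`. This
  variance-preserving mixing makes the planted quantities analytically
  interpretable: the expected full-length correlation is `static_r` (for
  `mod_amplitude = 0`) and windowed correlations oscillate around it with
  amplitude `mod_amplitude`, so dFCv grows monotonically with the planted
  modulation. Admissibility requires `|static_r| + mod_amplitude ≤ 0.99`.
* **Between-subject variation.** Each subject's post-session static
  coupling change gets Gaussian jitter (SD `coupling_change_sd`, default
  0.08, clipped to stay admissible). Without it the planted coupling
  change would be constant across subjects and a clinical-change
  correlation would be statistically undefined; with it, the subject-level
  "planted change" is a well-defined regressor recorded in the clinical
  table (`planted_dcoupling`).
* **Clinical scores.** HDRS percent change is
  `mean + slope·(Δ_i − Δ_spec) + N(0, residual_sd)` with defaults anchored
  to the cohort this emulates (pre 19 (4.76) falling by ~56%); SHAPS uses
  the negated slope and rises with improvement (pre 32.35 (6.79) rising by
  ~24%). The SHAPS orientation simply matches the printed direction of
  change of the instrument in this cohort; no claim is made about its
  scoring convention. Age is truncated-normal on [18, 70] (mean 40.7,
  SD 11.3); sex is Bernoulli 28/58 encoded 0/1.
* **What it does not emulate.** No hemodynamic response, spatial
  autocorrelation, head motion, scanner drift, physiological noise
  spectra, surface geometry, or multi-run phase-encoding structure.
  Passing tests therefore demonstrate the correctness and calibration of
  the estimators and inference under band-limited Gaussian conditions, not
  robustness to real-data artifacts — the denoising stage is exercised
  mechanically (components are planted and removed) rather than
  physiologically.

Volumetric NIfTI stands in for grayordinate files throughout: the
mathematics of every estimator is identical, and the I/O is far simpler.
Voxel indices are 0-based; images are stored float32 (so write/read
round-trips are bit-exact), masks uint8.

## Numerical and design choices

* Zero-variance voxels inside a window contribute `r = 0` with a logged
  count instead of aborting the map; a zero-variance seed is an error.
* The Hamming weights `0.54 − 0.46·cos(2πk/(W−1))` are symmetrized in
  floating point (`(w + reverse(w))/2`) so `w_k = w_{W−1−k}` holds exactly.
* Seconds-to-TRs conversion rounds half up, matching the conventional
  printed mappings at TR = 0.8 s (50 s → 63 TRs, 100 s → 125 TRs).
* Partial correlations return `r = 0, p = 1` when a variable is numerically
  fully explained by the covariates (relative residual tolerance 1e−10),
  rather than correlating rounding noise.
* Outlier screening is deliberately single-pass: the mean and SD are taken
  over all values once, and retention is decided against that one
  threshold (no iterative re-screening).
* Runs are reproducible end to end: one master seed in the configuration
  drives cohort generation and every permutation stream, and two runs with
  identical configuration produce byte-identical TSV summaries.

## Problem sizes used in validation

The stochastic suites run at compact sizes chosen to give stable rates on
a single CPU: FWER calibration uses 200 replicate null cohorts of n = 12
subjects on a 12×12×8 grid with T = 300 and 250 permutations (empirical
rate ≈ 0.04–0.05 at nominal 0.05); dFCv-modulation detection uses 20
replicate 3-subject cohorts (T = 300, W = 84); clinical-slope recovery
uses 20 replicate 20-subject cohorts; window-length monotonicity uses 10
replicates across W ∈ {63, 84, 125}. The acceptance script reports the
same quantities (calibration at 120 replicates) together with the
recomputable cohort-description statistics.

## Known limitations

* Sign-flip inference assumes symmetric paired errors; heavy skew in
  change maps would make the paired test approximate.
* The permutation loops are serial; at 5000 permutations on whole-brain
  grids a run is minutes, not seconds.
* The generator's voxels are spatially independent, so TFCE's sensitivity
  advantage over peak-level correction is demonstrated only qualitatively.
* Seed masks are inputs; segmentation (and per-session mask averaging
  beyond the provided majority-vote utility) is out of scope.
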