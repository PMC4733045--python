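# Methods

## The scientific setting

`remapkit` studies *environment-specific voxel codes*: whether the pattern of
fMRI responses across voxels (particularly in hippocampal subfields)
identifies which of several learned spatial environments a person is
retrieving, and what happens to that code when environments interfere. The
design it models has four virtual cities: Cities 1 and 2 share stores and
geometry except for two swapped store locations ("similar cities"), City 3
re-uses the same stores in a novel layout (the "interference city"), and
City 4 is entirely novel ("distinct city"). Retrieval happens in two blocks
per city (halves A and B) of 20 distance-judgment trials each; stimulus
triads are shared across Cities 1–3 and disjoint for City 4, and the correct
button side for a triad is swapped between the A and B halves so that
within-city pattern comparisons never share a motor response.

Two complementary measurements operationalize "remapping" (the reorganization
of a spatial code between environments):

- **Decoding**: a 4-way classifier trained on single-trial voxel patterns
  from one block half and tested on the other. Above-chance accuracy means
  the local code distinguishes environments; the structure of its confusions
  (e.g., interference-city trials labeled as the similar cities) diagnoses
  *which* code a trial's pattern resembles.
- **Multivariate pattern similarity (MPS)**: the mean correlation of
  voxel patterns across matched trial pairs. The **remapping index** of a
  city is its within-city similarity minus the average of its three
  between-city similarities, on the Fisher-z scale; positive values mean
  context reinstatement within and pattern separation between environments.

## Generative model (module `synthetic`)

No public dataset accompanies this design, so every analysis stage is
exercised against a generator whose statistical structure matches the
analyses' assumptions:

- **Templates.** Each city's code is a unit-norm Gaussian vector over
  `n_voxels` voxels. `separation` dials the expected between-city template
  correlation to `1 − separation` by mixing a common component
  (`separation=1`, the default, gives independent templates — the regime the
  similar cities' orthogonal codes call for). `attraction_mix` (λ) builds
  City 3's template as λ·normalize(mean(T1, T2)) + (1−λ)·U3; with orthogonal
  components its correlation with the similar-city average is
  λ/√(λ² + (1−λ)²).
- **Trials.** A trial's pattern is its city's template plus i.i.d. Gaussian
  voxel noise of standard deviation `noise_sd`. The within-city trial-pair
  correlation is then 1/(1 + noise_sd²·V/‖T‖²), which the tests verify
  against Monte-Carlo simulation.
- **Attraction.** With probability `p_attract` a City 3 stimulus triad's
  memory is captured by City 1 or City 2 (chosen uniformly): its trials are
  generated from the capturing city's template and answered incorrectly.
  The attraction coin is tossed **per triad** by default (`attraction_unit=
  "triad"`): an interfered store-pair relation errs in both retrieval
  blocks, which is how interference behaves at the memory level and which
  keeps the within-City-3 cross-block similarity cell populated at any
  realistic attraction rate. Independent per-trial attraction is available
  (`attraction_unit="trial"`). A consequence of the triad default is that
  City 3 behavioral noise is binomial over 20 triads rather than 40 trials.
- **Instability of the interference-city code.** Correct City 3 trials carry
  a fraction `c3_stability` of their signal energy from the stable City 3
  template; the rest is a fresh random direction per trial. `c3_stability=1`
  (the `simulate_trial_patterns` default) gives City 3 a fully stable code.
  The cohort generator defaults to `c3_stability=0.1`, encoding the premise
  that even *correct* interference-city retrievals reinstate little reliable
  environment-specific signal — this is what makes the interference city
  decode below chance and show a near-zero remapping index while its
  attracted trials resemble the similar cities, the qualitative effect
  pattern the cohort experiments reproduce.
- **Behavior.** A subject's per-city accuracy is the empirical fraction of
  correct trials; for City 3 that is 1 − p_attract up to binomial noise, so
  behavioral accuracy and the neural attraction rate are coupled through a
  single parameter.
- **Cohorts.** `simulate_cohort` draws each of 19 subjects' `p_attract`
  uniformly from (0.15, 0.65) (mean 0.4) with subject-specific templates,
  `n_voxels=200`, `noise_sd=0.35`, and a 5% lapse rate on the stable cities.
- **BOLD forward model.** Voxel time series are sums over trials of the
  trial's amplitude pattern times a boxcar (onset, duration) convolved with
  an HRF kernel on a microtime grid, read out at scan times (TR = 3 s), plus
  white noise. Run length is the last event offset plus 10 scans of padding.
  An optional `baseline_amplitude` adds a task-general evoked response
  shared by all voxels and trials — invisible to pattern correlations and
  decoding (both remove across-voxel means) but necessary for an average
  response shape to dominate the block-FIR profiles the empirical-HRF step
  decomposes, as it does in real data.

### Calibration choices

The design gives no effect-size anchor for voxel-pattern separation, so the
defaults are calibration choices: `noise_sd=0.35` at `n_voxels=200` puts the
within-city trial-pair correlation near 0.04 (Fisher z ≈ 0.04, the order of
magnitude of reported hippocampal pattern-similarity effects) while leaving
whole-ROI decoding of the stable cities well above chance at 40 trials per
city. At this scale the stable cities decode near 0.8 — cleaner than real
hippocampal data — so the cohort experiments are a *qualitative* twin of the
effect pattern, not a quantitative one.

### What the generator does not emulate

Spatial autocorrelation and physiological noise (drift, motion, cardiac),
triad-specific visual structure, learning dynamics within a block,
between-subject registration error, and any geometry of the real
environments. Passing tests therefore certify the analysis machinery and its
calibration under the stated statistical assumptions, not performance on
real BOLD data.

## Single-trial estimation (module `trialbeta`)

Pattern analyses need one maximally orthogonalized estimate per trial:

1. **FIR model**: ten per-scan indicator bins (a 30 s response window at
   TR = 3 s), fit by ordinary least squares with onsets mapped to the
   nearest scan. Two variants exist: a *per-trial* design (ten bins per
   trial) and a *block-level* design (ten bins shared by all of a block's
   trials, estimating one average response shape per voxel per block). With
   a regular SOA shorter than n_bins·TR the per-trial design is exactly
   rank-deficient (neighboring trials' bin columns coincide), so HRF
   extraction in the pipeline uses the block-level design, which stays full
   rank at any SOA; per-trial FIR recovery checks use non-overlapping
   events.
2. **Empirical HRF**: the pooled (profiles × bins) FIR matrix is decomposed
   by logistic-infomax ICA on an SVD-whitened basis (or by its first
   principal component); the component whose back-projection explains the
   most variance is returned, sign-aligned so its peak is positive, with
   that variance fraction reported. The SVD is taken of the *uncentered*
   matrix — the mean response shape is signal here, not a nuisance.
3. **Spline resampling**: cubic-spline upsampling to 16 time bins per scan;
   the interpolant passes through the original samples exactly. Accuracy
   depends on the input resolution: a canonical double-gamma sampled at 1 s
   upsamples to within 2% (max-abs, relative to peak) of its closed form,
   whereas 3 s sampling undersamples the initial rise and no interpolant
   does better than ~15% there — the exact pass-through and
   decimation-recovery properties hold at any resolution.
4. **Per-trial GLM**: one regressor per trial (trial-duration boxcar
   convolved with the HRF at microtime, sampled at scans) plus an intercept,
   fit jointly per run by OLS. When the kernel is an empirical *response*
   shape that already embodies the trial duration (a block-FIR profile),
   the `event_model="impulse"` option places the kernel at each onset
   without re-convolving the boxcar — double-counting the duration would
   misestimate overlapping trials. The forward simulator and the estimator build
   regressors through the same routine, so noise-free simulation followed by
   estimation is self-consistent to machine precision; singular designs
   raise an error naming the collinear trials. No autocorrelation model is
   fit (band-pass filtering is assumed upstream).

## Searchlight decoding (module `searchlight`)

Neighborhoods are ellipsoids with semi-axes (2, 2, 1.5) in voxel units —
exactly 31 voxels for an interior center on an unmasked grid (13 in the
center plane, 9 in each adjacent plane), and near-spherical in scanner
space for 1.6 × 1.6 × 2 mm voxels; edge centers keep whatever members fall
in the mask. Folds follow the block design: train on all correct trials of
one half per city, test every trial of the other half, then swap; confusion
counts pool over both folds. An optional balanced variant subsamples each
city's training trials to the minimum per-city count (seeded). The default
classifier is multinomial logistic regression — deterministic and seedless,
chosen because the decoding claims concern information content, not a
classifier family; a three-hidden-layer MLP is available for comparison.
Score ties resolve to the lowest city index. Misclassification rates report
the fraction of a source city's trials labeled in a target set, with the
denominator defaulting to all tested source trials (an errors-only variant
is provided).

## Group inference (module `inference`)

- **Max-cluster-size permutation** for one-sample accuracy maps: voxelwise
  t against chance, cluster-forming threshold at the two-tailed Student
  quantile (α = 0.05, df = n−1; one-tailed optional), components under
  18-connectivity (configurable 6/18/26). The exchangeable null sign-flips
  each subject's (map − chance); each permutation's maximum cluster size
  forms the null. Clusters get exact permutation p-values
  (1 + #{null ≥ size})/(n_perm + 1) and survive at p ≤ 0.05; tie
  discreteness at n_perm = 200 makes the attained family-wise level ≈ 0.03,
  slightly conservative of the nominal 0.05.
- **Bootstrap max-|t| threshold** for small families of condition-wise
  one-sample tests (ROI × city remapping indices): sign flips are shared
  across conditions within a subject, preserving their dependence; the
  corrected |t| threshold is the 95th percentile of the max-|t|
  distribution. With one condition this reproduces the ordinary Student
  quantile to Monte-Carlo error, and the threshold is monotone in the
  family size.

Zero-variance voxels (including values identical across subjects up to
rounding) are masked out of t-maps rather than propagated.

## Pattern similarity (module `mps`)

Pairwise pattern correlations are computed over an ROI's voxels, Fisher
z-transformed (atanh) *per pair*, then averaged — the standard convention
for averaging correlations; raw-r averaging is a caller-side one-liner on
the per-pair values if needed for sensitivity checks. Pairs with |r| at 1
(possible in noise-free synthetic data) are clipped to 1 − 1e-7 before
atanh, with a count warned; constant patterns make a pair undefined and it
is dropped with a warning.

Pair matching follows the stimulus design: within-city cells pair each
triad's half-A trial with its half-B trial (cross-block only, hence never
the same motor response); between-city cells for the shared-stimulus
Cities 1–3 match triads across opposite halves of the two cities; cells
involving City 4, whose stimuli have no counterpart, use all pairwise
combinations of correct trials. On exchangeable synthetic data the two
between-city schemes agree, which a test asserts. All similarity cells use
correct trials only, except the interference analysis, which contrasts the
similarity of *incorrect* City 3 trials to correct City 1/2 trials
(triad-matched) against that of correct City 3 trials, with City 4 as an
all-pairwise control; group inference is by paired t-tests across subjects.
Per-city remapping indices are tested one-tailed against zero at the
bootstrap-corrected threshold.

The univariate control computes mean betas per ROI × city per subject and a
repeated-measures ANOVA (city and ROI × city terms): multivariate effects
in the absence of per-region activation differences support a
distributed-pattern interpretation.

## Behavior (module `behavior`)

The swapped-store design over-represents conflicting trials: with f of n
trials having different correct responses in the two similar cities, pure
transfer from the other city caps accuracy at (n−f)/n and
answer-shared-plus-guess yields (n−f+f/2)/n — for the design's n = 20,
f = 9: 55% and 77.5%, computed in exact rational arithmetic. Map-drawing
scores are consumed as precomputed proportions (the scoring rubric is
outside this package's scope): per-round OLS learning slopes and
city-transition costs (first map of the new city minus last map of the
previous one).

## Problem sizes in the test and acceptance runs

Cohort experiments use 19 subjects at the full trial design (2 × 20 trials
per city) with 200-voxel ROIs; null-calibration searchlights run 100–200
label-shuffled permutations over 48-voxel grids with every second center;
family-wise-error checks use 200 null replicates with 200 permutations /
2000 bootstrap iterations each; estimation fidelity uses 40 voxels and
8 runs of 20 trials at 9 s SOA. These sizes keep the full suite and the
acceptance script at desk scale while leaving every statistical check
adequately powered.

## Known limitations

- The cohort regime's decoding accuracies are higher than typical
  hippocampal fMRI values; the effect *pattern*, not the effect sizes, is
  the reproduction target.
- The per-triad attraction default changes City 3's behavioral noise scale
  (20 triads, not 40 independent trials).
- The empirical-HRF ICA operates on synthetic FIR profiles whose variance
  structure is simpler than real BOLD; variance-explained figures are not
  comparable to real-data values.
- No spatial smoothing, nonstationarity correction, or TFCE; cluster
  inference assumes aligned maps (warping is out of scope).
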