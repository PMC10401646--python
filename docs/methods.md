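# Methods notes

This note documents the models, numerical choices and limitations behind
`placemem`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Experimental designs emulated

Two event-related designs over 8 runs with TR = 2 s and 20 studied place
stimuli split 10 / 5 / 5 across three visuospatial-context conditions
(image, panorama, street — two image photospheres, one panorama and one
three-photosphere street per each of five cities):

- **Recall**: each stimulus cued once per run (20 trials/run); a 1 s name
  cue plus 1 s dynamic mask precede 10 s of imagery; ISI jittered 4–8 s;
  conditions may repeat at most twice in a row.
- **Recognition**: each familiar stimulus shown once per run as a 2 s
  modeled event, plus novel images pooled into a nuisance regressor and
  excluded from estimates (they are not trial-unique, so their per-trial
  estimates are not analyzable).

Sequence generation is rejection sampling: condition orders are shuffled
until the repetition cap holds, with an explicit infeasibility error after
1e5 attempts and an a-priori pigeonhole check (a condition with n_c of n
trials fits under a cap m only if n_c ≤ m·(n − n_c + 1)). ISI is discrete
uniform over {4,…,8} s; each run starts with 4 s of rest and ends with 16 s
so the final response is sampled. The cue and mask are modeled jointly as
one 2 s nuisance event per trial (they are contiguous and never analyzed
separately); a 1 s cue-only variant is available via `cue_duration`.

## HRF and regressors

The kernel is the classic gamma variate `h(t) = (t/(p·q))^p · e^{p − t/q}`
with defaults p = 8.6, q = 0.547 (the convention of the standard
deconvolution toolchain for this paradigm), peak-normalized, truncated
where it falls below 1e-6 of peak. Regressors are boxcars of the event
duration convolved with the kernel on a 0.1 s grid and evaluated at
t = k·TR; the discrete convolution of a boxcar is computed exactly as a
difference of kernel cumulative sums, so building a regressor is O(T) per
event. No slice-timing offsets are applied.

Task columns are **not** rescaled per event duration. A per-duration peak
rescaling (as some toolchains apply) would break the linearity identity
that one 10 s column equals the sum of two abutting 5 s columns, and since
the simulator and the GLM share the same regressor construction, planted
amplitudes are recovered exactly either way. Consequently a planted
amplitude of 1 "%" produces a peak BOLD excursion of roughly the kernel
integral over the event, not exactly 1%; amplitudes and noise SDs should be
read as being on a common percent-signal-like scale rather than as
calibrated peak percentages.

Drift is modeled by orthonormal polynomial columns (QR of the Vandermonde
basis on [−1, 1]; degrees 0..4 for recall, 0..3 for recognition), which are
exactly mutually orthogonal on the sampling grid. Motion columns are
accepted but optional (synthetic data has none).

The collinearity audit reports the maximum absolute pairwise Pearson r
among selected columns. For the per-trial task regressors of the
beta-series GLM this stays far below the conventional 0.2 warning level
under the design's randomization rules. Note that the three
*condition-level* regressors of the 10/5/5 design are structurally
anti-correlated at |r| ≈ 0.3 — mutually exclusive regressors with these
duty cycles cannot be less correlated, and no detrending changes that — so
the audit's 0.2 criterion is meaningful for the per-trial regressors the
ROI analyses actually fit.

## GLM estimation

Per-run OLS: `β = (XᵀX)⁻¹Xᵀy`, `t = β/SE` with SE from the residual
variance (df = T − rank(X)) and the Gram inverse. Rank-deficient designs
raise, naming the dependent columns (pivoted QR). No autocorrelation
correction is applied: the per-trial t maps come from the standard
deconvolution path, and the simulator's AR(1) noise is deliberately treated
as unmodeled — a documented mismatch that the recovery tests absorb.
Single-trial models fit all 20 trials of a run simultaneously (not
leave-one-trial-out). Percent-signal-change normalization
(100·(x−mean)/mean per voxel) is provided for raw external data; the
simulator emits data already on that scale (see below).

## Synthetic data

Each voxel's series is the linear forward model: per-trial amplitude =
ROI-condition amplitude + rho_id × stimulus pattern, times the same
boxcar⊛HRF regressor the GLM uses, plus a uniform cue response, slow
cosine drift (three low-frequency components with random phases, amplitude
∝ 1/k), and stationary AR(1) Gaussian noise (marginal SD σ_white, lag-1
correlation φ, initialized from the stationary distribution). Identity
patterns are drawn once per stimulus per subject and orthonormalized across
stimuli within each ROI (QR) when the ROI has at least as many voxels as
stimuli; across-run pattern reliability is then monotone in rho_id, which
is the knob the MVPA recovery tests turn. Cohorts draw per-subject
amplitudes normally around a template (SD `between_subject_sd`) and redraw
patterns per subject; all randomness flows from a single seed through
named `SeedSequence` substreams.

What the simulator does *not* emulate: multiecho acquisition and denoising,
motion, spatial autocorrelation between voxels, surface geometry, and
physiological noise. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated noise
model, not robustness to real-scanner artifacts.

Frozen simulation conditions used by the acceptance tests (chosen once as
plausible for post-preprocessing single-trial data and then left alone):
σ_white = 1.0, φ = 0.3, drift amplitude = 0.5, between-subject SD = 0.15,
17-subject cohorts, 8 runs, graded memory-ROI amplitudes 0.5/1.0/1.5
against a flat 1.0 perception ROI, and reduced per-ROI voxel counts (16–20
voxels instead of 300) so a 100-cohort sweep stays cheap; voxel count
affects only averaging noise, not the logic under test.

## ROI definition

Candidates are vertices inside the anatomical constraint with p below the
vertex-wise threshold (default 0.001). `most_selective` keeps the top N
(default 300) by statistic — in the preferred contrast direction when
`signed=True`, by |statistic| otherwise; `center_of_mass` keeps the N
nearest the candidate centroid (Euclidean, on a flat index line or an
optional 3-D grid; the geodesic surface distance is out of scope). Ties at
the boundary break toward the lower vertex index so output is
deterministic. Fewer suprathreshold candidates than N yields the full
candidate set with a warning, not an error.

## Univariate statistics

The repeated-measures ANOVA is the classical balanced within-subject
factorial decomposition: effect arrays are built by inclusion–exclusion
over marginal means (treating subject as a crossed random factor), and each
within-subject effect is tested against its own effect × subject
interaction stratum, F = MS_effect / MS_effect×subject. This is the
standard error model for this design family; it matches the reference
implementation in statsmodels (`AnovaRM`) to 1e-6 on random tables. No
sphericity correction is applied (none is reported in the analyses this
mirrors). Unbalanced tables raise — no imputation.

Post hocs are paired t tests on subject-level cell means (or cell-mean
differences, enabling difference-of-differences contrasts), Bonferroni
corrected as min(1, m·p); Cohen's d is computed on the difference scores.
FDR is Benjamini–Hochberg step-up with the critical-p = 0 convention when
nothing passes. The sample-size calculation inverts noncentral-t power
(noncentrality d·√n, df = n − 1) by scanning n upward.

## Multivariate statistics

All C(n, n/2) ordered half-splits are enumerated lexicographically (70 for
8 runs; both orderings of each complementary pair are listed, which makes
the split-averaged similarity matrix symmetric — numerically identical to
averaging symmetrized matrices over the 35 unordered splits). Spearman ρ
is computed as Pearson correlation of average-ranked patterns (ties get
average ranks), vectorized over stimulus pairs; it matches
`scipy.stats.spearmanr` per entry to 1e-8.

For the identity index, correlations are Fisher-transformed before
averaging and differencing (the symmetric, variance-stabilized choice);
`transform="average_before_z"` offers the other order, and the two agree
closely away from the clipping regime. Correlations are clipped to
|ρ| ≤ 1 − 1e-7 to keep arctanh finite. Only within-condition cells enter
the index; conditions with a single stimulus raise. The matrix is averaged
across splits before the index is computed; a per-split-index-then-average
variant is obtainable by passing single splits.

## Degenerate inputs and tie-breaks

- Constant design columns: collinearity check raises, naming the column.
- Zero-variance cells in the ANOVA: F = 0, p = 1 (rather than 0/0).
- Zero-SD paired differences: t = 0, d = 0, p = 1.
- Empty candidate sets, empty masks, missing labels, and a stimulus missing
  from a run all raise with the offending entity named.
- Sequence infeasibility raises rather than looping.

## Known limitations

- OLS ignores serial correlation, so single-run t values are mildly
  anti-conservative under AR(1) noise; group inference operates on
  subject-level means and is calibrated (the null-cohort rejection rate is
  checked against its nominal level).
- The simulator's voxels are exchangeable within an ROI; no spatial
  structure, so smoothing-related questions are out of scope.
- Surface meshes are represented as flat index sets; center-of-mass
  distances are Euclidean.
- Printed degrees of freedom in published analyses that pool error strata
  differently are not reproduced — the structure (factors, strata) is.
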