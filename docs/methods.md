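# Methods

## Model and procedure

The package estimates directed ("effective") connectivity between a seed
region and every brain voxel from resting-state BOLD series. The working
model is linear bivariate autoregression: the target series is predicted
from its own past, with and without the source's past, and the influence
is Geweke's log variance ratio F = ln(σ²_restricted / σ²_full). Both
residual variances use RSS/(T − p) on the same T − p aligned samples, so
nesting guarantees F ≥ 0 up to round-off and F is invariant to rescaling
either series. All fits are ordinary least squares with an intercept;
since the series have been detrended and band-passed the intercept is
near-neutral, but it is always included so the fits are well defined on
raw inputs too.

Model order is chosen by the Schwarz criterion evaluated on the bivariate
full model over a shared sample (all candidate orders are scored on the
same T − p_max observations, so the criterion values are comparable). For
200-sample resting-state series of this kind the selected and canonical
order is 1, and order 1 is the default everywhere.

Statistical significance of a single influence value uses a permutation
null: the *target* series' time indices are uniformly reshuffled (the
source is untouched), F is recomputed, and the p-value is the add-one
estimator (1 + #{null ≥ observed})/(n_perm + 1) with 500 reshuffles by
default. Full-index reshuffling destroys *all* temporal structure of the
target, including its autocorrelation; for band-limited series this makes
the null anti-conservative (a band-passed but otherwise independent pair
shows a mean F of roughly 2–4× the white-noise value p/(T − p)). This is
a known trade-off of the reshuffling null and is deliberately left as
specified; block or phase-randomized permutations are not implemented.
One practical consequence, visible on the synthetic cohorts: group-level
significance masks derived from this null cover most of the brain, so
the union "analysis mask" barely restricts the between-group contrast.

Group analysis proceeds in the study's canonical order: per-group
voxel-wise mean maps (two groups × two seeds × two directions = eight
maps); per-group significance masks (see below) with Benjamini–Hochberg
FDR at q = 0.05 and a minimum cluster extent of 10 voxels
(26-connectivity by default; 6/18 configurable); a pooled-variance
two-sample t map (patients minus controls, two-tailed, df = n1 + n2 − 2;
Welch available behind a flag) restricted to the union of the two group
masks and FDR-corrected over in-mask voxels; signed clusters extracted
from the surviving voxels; and per-cluster, per-group Pearson
correlations between cluster-mean influence and clinical scores at the
uncorrected α = 0.05, with the number of correlations tested recorded
alongside.

How the original group-level significance was derived from subject-level
permutation nulls is genuinely open; two defensible variants are
implemented and neither claims to be canonical. The default
(`t_vs_null`) tests, per voxel, the subjects' F values against the mean
of the pooled permutation null with a one-sided one-sample t. The
alternative (`fisher`) combines per-subject permutation p-values with
Fisher's method (χ² with 2S df). The pipeline estimates the pooled null
mean per subject from a random subsample of in-mask voxels (64 by
default, 500 reshuffles each); the pooled mean is extremely stable across
voxels and subjects, so the subsample costs nothing statistically.

Behavioral tables use the pooled-variance two-sample t computed directly
from group means/SDs/counts, and a tie-corrected Kruskal–Wallis test on
binary category counts (midranks for the two tied blocks, H divided by
1 − Σ(t³ − t)/(N³ − N), p from χ² with 1 df) for sex composition.

## Preprocessing

Per-voxel cleaning, in order: discard the first 5 volumes (motion rows
dropped in lockstep); optional isotropic Gaussian smoothing
(FWHM 8 mm, σ = FWHM/(2√(2 ln 2)) per axis in voxel units); nuisance
regression of every in-brain voxel on an intercept, the 6 rigid-body
motion parameters, and the white-matter and CSF mean series (extracted
from the unsmoothed post-discard data); zero-phase band-pass
0.01–0.08 Hz; linear detrend. The band-pass is an rFFT magnitude mask
with raised-cosine transition bands of 0.005 Hz, which passes a 0.04 Hz
tone at unit gain, suppresses DC and a 0.2 Hz tone to below 0.1, and is
idempotent in-band to within 1%. Smoothing is off by default for
synthetic runs and restored with `--smooth`. Constant voxels pass
through as zeros and are flagged rather than erroring.

Motion quality control summarizes a 6-parameter trace as the mean
frame-to-frame Euclidean displacement, separately for the three
translations (mm) and three rotation angles (degrees); the exclusion rule
rejects a subject when any translation parameter exceeds 1.5 mm or any
rotation 1.5° in absolute value (strictly greater; a maximum of exactly
the limit is retained). Because SPM-style realignment files store
rotations in radians while the limits are in degrees, motion files can
only be read with an explicit unit declaration (argument or YAML
sidecar); rotations are converted to degrees internally. The exact
algebraic form of the published displacement summary could not be
recovered from the available text, so the implemented form follows the
convention cited for it (mean frame-to-frame displacement); this is
documented rather than claimed verbatim.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale. Regional signals follow a stationary lag-1 vector
autoregression with unit Gaussian innovations; the transition matrix is
diag(self terms) + coupling, validated by its spectral radius, and a
200-sample burn-in precedes every realization. Four network nodes (two
seed regions, a temporal-like "itg" source, a "visual" target) are
embedded as disjoint blocks in a 24 × 24 × 12 grid (the acquisition-scale
64 × 64 × 30 remains configurable) with i.i.d. observation noise
(SD 0.5 on unit-variance signals); WM and CSF compartments carry
independent slow AR(1) nuisance signals; remaining voxels are pure
noise. On top of the phantom each subject receives a per-voxel linear
drift (random amplitude, SD 0.3) and a global component tracking the
first translation parameter (weight 0.2), so nuisance regression,
filtering and detrending have real work to do. Motion traces are
cumulative Gaussian random walks (step SD 0.02 mm / 0.02° — a compliant
subject), with an optional injected spike for testing the exclusion rule.

Cohorts default to 22 patients vs 21 controls, 205 volumes at TR = 2 s.
Patients carry the baseline network (itg→seed_r = 0.25,
seed_l→visual = 0.45, visual→seed_l = 0.20, self terms 0.5); controls add
+0.3 to itg→seed_r and −0.15 to seed_l→visual, so the patient group shows
the *decreased* temporal→amygdala influence and *increased* seed→visual
influence pattern that motivates the analysis. The planted
between-group delta corresponds to a voxel-level population t of roughly
5–6 on the to-seed map at these group sizes — strong enough that the
end-to-end recovery checks validate pipeline correctness rather than
marginal statistical power (at population t ≈ 4 the block's voxels rise
and fall together across subjects, making whole-brain FDR detection
all-or-nothing; that regime is exercised separately in the
two-sample-t-map power test with independent per-voxel subject noise).

Each subject's couplings are jittered around the group mean
(Gaussian, SD 0.10, redrawn toward the mean if stationarity would break),
which is what makes between-subject correlations with clinical scores
definable. The avoidance score is a linear map of the subject's realized
itg→seed_r coupling (score = 40 − 60·c + N(0, 2)); with the F-estimation
noise floor at T = 200 this yields a population correlation of about
−0.6 between region-mean influence and avoidance within the patient
group, matching the regime the recovery checks target. The remaining
scores (fear factor, HAMD, HAMA, STAI, age, education, sex frequencies)
are drawn from per-group normal distributions at the study-scale means
and SDs; the LSAS total is fear + avoidance, so the score structure is
internally consistent.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning (one child per subject), so a cohort
is bit-reproducible and subjects are independent.

What the generator does **not** model: hemodynamic response convolution,
spatial autocorrelation of noise, scanner artifacts, physiological
(cardiac/respiratory) noise, non-white innovation spectra. Passing tests
therefore demonstrate the estimator and inference chain are correct under
the assumed linear VAR regime — not that the method is robust to real
fMRI confounds such as hemodynamic lag variability across regions.

## Numerical choices

* Voxel-wise maps use a vectorized Gram-matrix path (order 1) with
  series standardized per voxel (F is scale-invariant); a relative
  determinant threshold of 1e-10 flags collinear or constant voxels,
  which become NaN in maps, are excluded listwise from group statistics,
  and are counted in QC. The scalar `granger_pair` route uses QR-based
  least squares and is the reference the batched path is tested against.
* Permutations of a standardized series keep its marginal moments, so
  the permutation engine standardizes once and skips re-scaling.
* BH-FDR: cutoff is the largest order statistic with p_(i) ≤ i·q/m;
  zero rejections yield cutoff 0. The implementation is checked against
  both a brute-force "try every cutoff" oracle and statsmodels.
* Nested-fit round-off: RSS_full is clamped to [tiny, RSS_restricted],
  so F is never negative and never −0 log-divergent.
* Disk format is float32 NIfTI-1 (computation in float64); the TR is
  recorded in the header. Motion text files carry a YAML sidecar with
  the rotation unit. Voxel indices are 0-based internally.
* Test problem sizes: recovery checks use 10–20 replicate cohorts at the
  default 24 × 24 × 12 grid, permutation calibration uses 199 reshuffles
  per test over 500–1000 null pairs, and the end-to-end determinism check
  runs the full default cohort twice; these sizes keep the whole suite at
  a few minutes while leaving Monte-Carlo margins far from the asserted
  bounds (except where a bound is intentionally tight, as discussed
  above).

## Known limitations

* Bivariate (pairwise) influence only; no conditional/multivariate or
  spectral Granger causality, and no hemodynamic deconvolution.
* The reshuffling null's anti-conservatism for band-limited data (above)
  means single-subject permutation p-values should be read as liberal.
* The cluster-extent rule is applied in voxel units with no account of
  smoothness-dependent cluster-size distributions.
* The behavioral Kruskal–Wallis helper is specialized to two groups and
  two categories (its use case here); it is not a general K-sample rank
  test.
* Anatomical labeling of clusters is out of scope; reports use voxel
  indices.
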