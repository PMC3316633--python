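# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and what the test suite does and does not establish.

## Behavioural model and estimation

Choices between "\$20 today" and a larger delayed reward are modelled with
hyperbolic discounting, `SV = R / (1 + kD)`, a prime premium on the rate,
`SV* = R / (1 + (k + a·I_A) D)`, and a logistic choice rule
`P(later) = logistic(ω (SV* − 20))`.  Parameter meanings and defaults:

| parameter | units | role | generator default |
|---|---|---|---|
| `k` | 1/day | discount rate; larger = more impulsive | 0.024 (population SD 0.018) |
| `a` | 1/day | additive premium on `k` in the apple condition | 0.06 (population SD 0.31, truncated) |
| `ω` | 1/$ | choice sensitivity (inverse noise) | 0.30 (population SD 0.10) |

The population moments for `k` and `a` are the reported group statistics
of the emulated study; `ω` is not reported there, and 0.30 was chosen once
as a realistic value — at the calibrated amounts it yields roughly 75–85%
model-consistent choices, typical of intertemporal-choice data.  Sampling
is rejection-truncated to `k > 0`, `k + a > 0`, `ω > 0`.

`ω` is implemented as the logistic slope on the value difference (the
standard softmax form).  Describing `1/ω` as the variance of the decision
noise is loose shorthand: the variance of a logistic with scale `1/ω` is
`π²/(3ω²)`.

Estimation is subject-level maximum likelihood: probabilities clipped to
`[1e−12, 1 − 1e−12]`, missed responses and perceptual-control trials
excluded, bounded L-BFGS-B with analytic gradients from eight
deterministic start points on a log-spaced grid (bounds
`k ∈ [1e−6, 2]`, `a ∈ [−0.5, 0.5]`, `ω ∈ [1e−4, 50]`; a soft quadratic
penalty keeps `k + a·I_A ≥ 0`).  Standard errors come from the inverse
observed information (finite-difference Hessian).  A subject whose
later-choice fraction falls outside `[0.05, 0.95]` is declared
non-identifiable, mirroring the exclusion of participants who almost
always chose one option.  BIC uses the number of usable discounting
trials.  The nested baseline/priming comparison is a df-1 likelihood
ratio plus AIC/BIC deltas; `P(later) = 0.5` exactly predicts "now" (tie
broken toward the immediate option, documented here once).

The group-level premium test approximates a non-linear mixed-effects
model by (a) a two-stage one-sample t-test on the per-subject `â` and (b)
a pooled fixed-effects fit — one common `a`, subject-specific `(k_j, ω_j)`
— evaluated by profile likelihood over `a` with an LR test of `a = 0`.
Full random-effects integration is out of scope; the approximation
preserves the direction and strength of the group effect, which is all
that is consumed downstream.

Derived trial variables: premium `Π = SV* − SV` (zero off apple trials),
interaction `Σ = a·SV*` (evaluated as written on every discounting trial,
so on cup trials `Σ = a·SV`; a flag zeroes it on cup trials instead), and
difficulty `Γ = 1 − |2P(Δ) − 1| = 2·min(P, 1−P)` with `Δ = SV − 20`.  The
emulated paradigm constrains `Γ` only to be bounded by 0 and 1, maximal at
`Δ = 0` and decreasing in `|Δ|`; the chosen form satisfies all of that, uses both
fitted parameters, and is an even, strictly unimodal function of `Δ`.
"Hard" trials are those with `Γ` strictly above the subject's median
(ties labelled easy).

## Task design

A session is 6 delays × 6 amounts × 2 primes × 3 repetitions = 216
discounting trials plus 108 perceptual-control trials, packed into 6 runs
of 54 with exact per-run prime balance (each delay-amount-prime cell at
most once per run), 50/50 side counterbalancing per run, and fixed 7000 ms
trial slots (fixation 2417 → mask 84 → blank 16 → prime 16 → blank 16 →
mask 400 → response 4000; the 51 ms shortfall is terminal padding).  Runs
last 378 s; the synthetic scanner acquires 189 volumes at TR 2000 ms.

Amount calibration inverts the hyperbolic model at a pre-test discount
rate: for each delay, six amounts hit later-choice probabilities at the
octiles 0.125…0.875 under a reference `ω` of 0.3, so the expected
later-choice fraction over the grid is one half.  Amounts are clipped to
the dollar envelope \$20.10–\$385.16 and rounded to cents; when the floor
collapses neighbouring grid points (short delays, shallow discounters),
distinctness is restored by cent spacing — the balance property then holds
only approximately at those delays.  The original sequencing used an
external design optimiser; constrained uniform shuffling with per-run
balance is substituted, with a fixed seed.

## Synthetic BOLD

Each subject's 4-D series (default grid 24×24×18 at 4 mm, ellipsoidal
analysis mask, 6 runs × 189 volumes) is baseline 100 plus three parts:

* **Evoked responses.** Every trial adds a response of amplitude 0.8
  (signal units) in every in-mask voxel.  The per-trial response is a
  4.5 s boxcar passed through the canonical double-gamma kernel, sampled
  at volume resolution and supported on the 12 s post-onset window, placed
  at the volume containing the visual onset.  Generating at volume
  resolution keeps the evoked signal inside the span of a volume-locked
  FIR basis, so deconvolution is exact up to noise; real BOLD additionally
  has sub-TR latency jitter and undershoots beyond 12 s that any 6-bin FIR
  truncates.  With a fixed 7 s trial period those truncation residuals are
  class-dependent and nearly balance across runs, which drives
  cross-validated accuracy systematically *below* chance — a property of
  periodic designs, not of this decoder, and the reason the generator is
  volume-locked.
* **Planted effects.**  Parametric regions scale the trial amplitude with
  a standardised model variable (SV, Σ, or Π on apple trials).  Pattern
  regions add a subject-specific spatial pattern, drawn fresh per subject,
  that sums to zero over the region's voxels, with opposite signs for the
  two classes of the dichotomy (apple/cup, now/later, easy/hard).  Group
  univariate contrasts over such patterns are null in expectation — the
  patterns are idiosyncratic across subjects and spatially mean-free —
  while a within-subject linear decoder reads the class reliably: the
  univariate-null / multivariate-decodable dissociation of the emulated
  study.  Effect sizes are free parameters of the generator and default to
  comfortable recovery at desk scale.
* **Noise.**  AR(1) Gaussian noise (ρ = 0.3, SD 1.0) plus slow cosine
  drift with random per-voxel coefficients.  Physiological noise, motion
  and susceptibility artefacts are not modelled; passing tests therefore
  demonstrate correctness of the analysis chain under this noise model,
  not robustness to real-scanner artefacts.

The default grid is deliberately smaller than a scanner matrix
(64×64×32); full-size generation is a configuration change.  Each
synthetic subject receives their own pseudo-randomised schedule — with a
shared schedule, deterministic design-misfit terms are common to all
subjects and can masquerade as consistent group effects.

## Univariate GLMs

Trials are modelled from the visual (mask) onset for 4500 ms, convolved
with the double-gamma kernel (positive lobe peaking at 6 s, undershoot at
16 s, amplitude ratio 6, length 32 s, unit peak).  Each run carries
apple/cup/control condition regressors, a 128 s high-pass discrete-cosine
set, and an intercept.  Parametric modulators are mean-centred and
serially orthogonalised at the regressor level — the interaction model
enters [SV, Σ] (order reversible by flag; shared variance goes to
whichever enters first), the premium model puts SV on all discounting
trials and Π on apple trials only, optionally restricted to correctly
predicted trials.  An all-zero modulator (e.g. Σ when `â = 0`) is
dropped.  Estimation is per-run OLS over mask voxels; rank-deficient
designs raise an error naming a collinear column.

Group inference: subject contrast maps, smoothed at 8 mm FWHM (spatial
normalisation is replaced by the shared synthetic grid), one-sample
t → Z, clusters formed at Z > 1.96 with 6-connectivity, and
family-wise-error control by sign-flip permutation of the maximum cluster
size (the exact 2^n flip set is enumerated whenever it is smaller than
the requested permutation count).  The apple-vs-cup mean contrast is
tested two-sided.

## FIR and searchlight decoding

The FIR model estimates one parameter per condition per 2000 ms bin (six
bins covering 12 s from the volume containing the visual onset; 12
condition regressors per run for prime decoding) after the same 128 s
high-pass.  Trials outside the decoded dichotomy (perceptual control,
missed, the other prime condition in within-condition analyses) are
modelled by a shared nuisance FIR set so their evoked signal cannot alias
into the condition estimates.  A run with fewer than 4 labelled trials of
either class is excluded; a subject with fewer than 3 usable runs is
excluded.

Decoding uses a radius-3 voxel sphere (123 lattice offsets; spheres are
truncated at mask edges, not dropped), one pattern vector per class per
run (built from run-wise condition estimates, never single trials, so
folds are balanced and chance is exactly 50%), leave-one-run-out
cross-validation, and a linear soft-margin SVM with C = 1.  Accuracies of
bins 5 and 6 are averaged into one map by default; a flag concatenates
the bins into a single pattern vector instead.  Features are centred on
the training-fold mean; for an SVM with a bias term this translation
does not change decisions and is retained only for conditioning.

Two implementations coexist and are tested for agreement: a direct path
(explicit feature extraction per sphere, scikit-learn's SVC) and the
default fast path, which precomputes every sphere's linear-kernel Gram
matrix in one pass (a spherical box-sum of voxelwise product maps via
spatial correlation) and solves all spheres' dual problems with a
vectorised SMO.  The dual solver reproduces the reference SVC decisions
exactly on randomised problems and voxel-for-voxel on simulated subjects;
it exists purely because calling a per-sphere estimator tens of thousands
of times is dominated by per-call overhead.

Group accuracy inference smooths accuracy-minus-chance maps at 8 mm FWHM
and reuses the sign-flip cluster machinery.

Small-sample note: leave-one-run-out accuracy with 12 samples is noisy
per sphere (SD ≈ 0.18) and brain-mean accuracy for one subject varies by
one or two percentage points across noise realisations; averaged over
eight subjects at the default grid the null decoder sits within about
half a percentage point of 50%.

## Visibility tests

Detection (image present on half the trials) and identification (one of
four images, scored apple-vs-rest) are scored by the test-specific
hit/false-alarm definitions; `d' = z(hit) − z(fa)` is undefined (NaN,
never an exception or an imputation) when either rate is exactly 0 or 1,
with an optional log-linear correction behind a flag.  Confidence
intervals are percentile bootstrap over 1000 within-class trial resamples
(resampling i.i.d. binary trials within class is realised exactly as
binomial draws of the class counts); undefined resamples are excluded and
counted.  A subject is "aware" only when both tests' 95% intervals
exclude zero.  The simulated observer is equal-variance Gaussian with an
unbiased criterion at `d'/2`.  The default of 96 trials per test is a
configuration choice (the emulated paradigm does not fix it).

## Problem sizes in the test suite

The suite exercises the full session size everywhere the behavioural
model is concerned (216 trials; 200 recovery subjects; 1000 null
simulations for LR-test size).  Imaging tests use the default 24×24×18
grid for the null-calibration check (8 subjects) and 16×16×12 or smaller
grids for recovery, dissociation and error-path tests; cluster-FWE null
calibration runs 100 null experiments with the exact 256-flip
permutation set.  These sizes were chosen as the smallest at which the
assessed properties are stable.

## Known limitations

* The pooled group test is fixed-effects; between-subject heterogeneity
  in `a` widens its true size slightly relative to a mixed model.
* The FIR window truncates the undershoot; with the volume-locked
  generator this is exact, but on real data the periodic-design
  truncation bias discussed above applies.
* Cluster-level permutation assumes sign symmetry of subject maps under
  the null; heavy-tailed subject effects would violate it.
* The amount-calibration scheme is one construction satisfying the stated
  balance property; the original per-subject pre-test procedure is not
  recoverable.
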