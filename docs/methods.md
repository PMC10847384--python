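# Methods

This note documents the models, numerical choices, and known limitations of
`hrvdyn`, in the order the pipeline runs.

## Cardiac preprocessing

Segmented beat-interval records are compiled onto one cumulative task clock;
a lost 30-s segment inserts exactly 30 s of clock as an explicit gap interval
rather than deleting time, so physiology stays aligned with behavior logs.
Artifact filtering applies two rules: a hard physiological range (default
0.2–2 s) and an adaptive rule rejecting a beat whose interval differs by more
than 25% (configurable) from the running median of the last 11 accepted
intervals.  The adaptive rule is this package's own documented criterion —
published toolkits implement comparable running-reference filters but do not
agree on one rule — chosen to be reproducible, tunable, and conservative.
Removal never shifts the clock of surviving beats.

Resampling fits a natural cubic spline through the (beat time, interval)
pairs of each contiguous run and evaluates it at exact multiples of 1/fs
starting at 0 (fs = 1 Hz for the IBI channel, 4 Hz for the spectral stage).
Runs are the complement of the gap set, where gaps are the declared missing
segments plus any span longer than 3 s without an accepted beat (preventing
splines from bridging artifact bursts).  Within a run the spline is evaluated
over the run's full clock span: the margins before the first and after the
last beat of a run are shorter than one beat, and populating them is what
makes the per-second grid complete on gap-free data — the alternative
(dropping sub-second margins) would add a spurious missing second at each
run boundary.  Runs with fewer than 4 beats are left missing.  No
interpolation ever crosses a gap.

## RSA estimation

RSA at second *s* is the natural log of IBI band power in the adult
respiration band (0.12–0.40 Hz), from the 30-s window of the 4 Hz series
covering seconds [s−14, s+16): the window's value represents its 15th
second.  This assignment uniquely reproduces both edge rules: 14 leading and
15 trailing missing seconds on a gap-free task, and missingness from 15 s
before to 14 s after a dropped segment.

Each 120-sample window is demeaned (so DC does not leak into the 0.12 Hz
bin), Hamming-tapered, and Fourier transformed.  The one-sided periodogram is
scaled by 1/(fs·Σw²) and band power is the sum of PSD bins inside the band
(inclusive endpoints) times the bin width fs/N.  With this window-energy
normalization an in-band sinusoid of amplitude A yields band power A²/2
regardless of the taper; the calibration is pinned by a test against
`scipy.signal.periodogram` as an independent oracle.  Band power below
ε = 1e−12 s² is floored before the log and flagged (`floored`), so constant
windows stay finite.  Windows only demean; no detrending beyond the mean is
applied.

## Behavior densities

Coded behavior events carry initiation timestamps.  Second *s* (the interval
[s, s+1)) gets indicator 1 if at least one event of the category initiates in
it; multiple initiations collapse to 1, and durations are not modeled.  Local
density is the count of indicator-1 seconds in the centered 5-s window, an
integer 0–5 — indicator-seconds, not raw event counts, so two utterances in
one second do not inflate it.  Edge windows are truncated to the available
span by default (keeping the first and last 2 s in the model stage); a
missing-at-edges variant is available behind the `edges` flag.

## Penalized-spline smoothing

Each per-second series is approximated by an order-5 B-spline — order in the
functional-data-analysis convention order = degree + 1, i.e. quartic pieces,
consistent with penalizing the integrated squared 3rd derivative — with a
knot at every sample, minimizing RSS + λ·∫(f‴)².  Defaults: λ = 0.5 (IBI,
seconds), 0.1 (RSA, ln-units), 1.0 (behavior densities), applied on the
per-second time scale in native units.  A GCV profile
(n·RSS/(n − edf)²) is available as a diagnostic; the pipeline keeps the fixed
λ values.

Numerics: the coefficient solve uses the augmented least-squares form
[B; √λ·L] with P = LᵀL from an eigendecomposition, whose conditioning is the
square root of the normal equations'; this keeps the λ → ∞ limit (the
least-squares quadratic, the penalty null space) accurate to ~1e-5 on
typical runs.  The penalty integral is exact Gauss–Legendre per inter-knot
interval.  Each contiguous observed run is smoothed independently — no
imputation across gaps — and runs shorter than 31 samples (one spectral
window) are left missing, which also keeps the basis well conditioned.
Derivatives are the analytic derivatives of the fitted spline at sample
times.

## Coupled-ODE multilevel models

For each physiology × behavior pair, two linear mixed models share one
stacked subject-second design:

    dPhys_i(t)/dt = a_i + b (Phys_i(t) − P̄hys_i) + c_i Beh_i(t) + u_i(t)
    dBeh_i(t)/dt  = d_i + e Beh_i(t) + f_i (Phys_i(t) − P̄hys_i) + v_i(t)

Physiology is centered on the person's task average (computed from the
included samples) for both IBI and RSA pairs; behavior's set point is zero
(no centering).  Random effects are estimated for the intercepts (a, d) and
the coupling slopes (c, f) only, independent by default (diagonal
covariance; an unstructured 2×2 option exists) — the covariance structure is
a design choice, as is restricting b and e to fixed effects.  Estimation is
REML via statsmodels MixedLM with variance components; the optimizer runs on
internally standardized columns (native IBI units put variance components
near 1e−7, where quasi-Newton steps stall) and estimates are transformed
back exactly.  p-values are Wald-z; containment-style degrees of freedom are
not used, and at the row counts involved (10⁴–10⁵) the difference is
negligible.  Rows with any missing element are dropped listwise
(missing-at-random treatment).  Residuals u, v are treated as independent
over time; no autoregressive structure is modeled — a known simplification.

Moderator models expand the intercept and coupling coefficient with the
standardized moderator and, as a covariate, the standardized task-total
frequency of the pair's behavior (both as main effects and coupling
interactions), one moderator per model.  Composite scores follow fixed
recipes: sum of the two attribution items, mean of the two parenting-stress
percentiles, mean of the two symptom T-scores, median split of the positive
emotion hit rate, any-nonzero split of anger false alarms; every predictor is
z-standardized on the sample mean/SD.  Simple slopes at moderator levels ±1
SD and 0 use slope = c + level·interaction with delta-method SEs from the
fixed-effect covariance; the slope at level 0 equals the base coupling
exactly.

## Synthetic cohorts

The generator is the model run forward.  Subject coefficients are fixed
effect + moderator effect × Z_i + independent random effect; trajectories are
integrated by Euler–Maruyama at dt = 0.1 s and observed at 1 Hz, with
behavior density clipped to the observable range [0, 5].  At each observed
second the observed derivative is recorded as the drift at the recorded
state plus a unit-variance draw scaled by the per-second residual SD, so the
recorded (state, derivative) pairs satisfy the generating equations exactly
with residuals of SD σ_u / σ_v — the basis of the recovery oracles and the
meaning of the σ parameters.  Parameter sets whose simulated IBI leaves 0.2–2 s for
more than 10% of samples are rejected as non-mean-reverting.

Defaults are the study conditions the package is meant to emulate: 204
subjects, 300-s tasks, person-mean IBI ~ N(0.76 s, 0.12 s), intrinsic rates
b₀ = e₀ = −0.05 /s, couplings c₀ = −0.0015 and f₀ = 0.03, segment-drop rate
0.016 (≈1.6% per-second IBI missingness).  Where the emulated conditions
leave a quantity unstated, values were fixed once at levels realistic for
this kind of task: dynamic-noise SDs 0.015 s/s and 0.3 density-units/s
(stationary within-person SDs ≈ 0.047 s and ≈ 0.95 density units),
random-effect SDs about half the corresponding fixed effects (0.002, 0.0008,
0.03, 0.015 for a, c, d, f), respiratory modulation 0.03 s at 0.25 Hz, and a
behavior-change intercept d₀ = 0.05 (latent density set point 1.0).  Event
logs are sampled per second as Bernoulli with a logistic link on latent
density (timestamps uniform within the second); intercepts can be calibrated
to hit target task totals (5.27 positive, 23.16 negative per 300 s).  The
logistic event link and independent random effects are stand-ins — no
generative model for events or random-effect covariance is implied by the
emulated study — and are flagged as such.

Two fidelity levels serve different tests.  *Latent* cohorts feed the exact
states, derivatives, and generating set points to the model stage: recovery
tests there are clean, and Monte-Carlo calibration shows nominal CI coverage
and type-I error for the coupling estimators.  Handing the model the
generating set point matters: centering physiology on the *observed* task
average instead makes each subject's mean outcome independent of
c_i × (mean behavior) — person-mean centering cancels the between-subject
component of the coupling signal — so any weight the mixed model places on
between-subject contrasts attenuates the coupling estimate when behavior
levels vary between subjects (about 12% under the default heterogeneity).
On real data the set point is unknowable and observed-mean centering is the
standard, slightly conservative choice; the latent route isolates estimator
calibration from that set-point estimation effect.  *Observed* cohorts render beats and sample sparse
events; discretizing a continuous latent density into rare binary events
attenuates coupling estimates toward zero (without sign flips, in
aggregate), so observed-fidelity tests check signs and pipeline integrity,
not point recovery.  Passing latent-cohort tests shows the estimation
machinery is calibrated *when the model is true*; it does not certify
robustness to model violations real data may carry (autocorrelated
residuals, non-Gaussian noise, informative missingness).

With uniform independent segment drops, the default 0.016 rate reproduces
the ≈1.6% per-second IBI missingness condition; the resulting RSA
missingness (~12–13% of seconds, edges included) exceeds the ≈9.9% a cohort
would show if its lost segments clustered at task edges, where the spectral
window is already undefined.  The drop rate is calibrated to the IBI figure.

## Problem sizes used in validation

Monte-Carlo calibration runs 100 replicate latent cohorts of 50 subjects ×
300 s for CI coverage and 200 replicates for null rejection — sizes at which
the binomial error of the estimated rates is a few percentage points, chosen
as the package's own validation budget.  The spline λ → ∞ check uses 60-point
runs, where the finite-λ gap at λ = 1e9 (suppression of the near-null cubic
mode, which scales with run length and noise) is well below the 1e-4
comparison threshold.

## Known limitations

- The two-step approach (smooth, then regress derivatives) inherits
  smoothing bias: derivatives are attenuated near run edges and sharp
  transients, and within-person centering on the observed task mean biases
  the intrinsic-rate estimate b by O(2/T) (the classic dynamic-panel effect;
  ~0.007 /s at T = 300).  Couplings c and f, the quantities of interest, are
  unaffected to first order.
- No autoregressive residual structure; SEs may be optimistic on strongly
  autocorrelated residual processes.
- The behavior-equation random coupling variance is weakly identified when
  the physiology signal is small relative to behavior noise; REML then
  returns boundary or noisy variance estimates, which widens (honestly) the
  coupling SE.
- Random effects are not independent of the regressors they help generate (a
  subject's behavior set-point effect shapes that subject's behavior
  trajectory, and through the coupling, the physiology trajectory), so the
  mixed-model (random-effects) coupling estimates carry a correlated-
  random-effects bias through the between-subject contrast — the
  physiology→behavior coupling f is biased toward zero by roughly half an
  SE under the default generating conditions, while per-subject (fixed-
  effects-style) estimates are unbiased.  Monte-Carlo calibration shows CI
  coverage still at the nominal level because the REML standard errors are
  mildly conservative there.
- RSA from beat series assumes respiratory modulation is the dominant
  in-band power; no respiration channel is modeled (respiration rate can
  enter only as a generic covariate).
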