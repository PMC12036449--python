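# Methods

This note documents the models, the synthetic-data generators, the
statistical procedures, and the numerical and design choices behind them.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task environment

The restless three-armed bandit assigns each arm a hidden reward
probability that starts on the lattice {0.1, 0.3, 0.5, 0.7, 0.9} (seeded
uniformly per arm) and, on every trial and independently per arm, changes
with probability `p_change = 0.1` by a step of `0.2`, bounded in
[0.1, 0.9].  The change probability is read as the *total* probability of
moving; the direction is uniform among the directions that stay in bounds,
and at a bound the single legal direction is taken.  This keeps the change
rate at 10% everywhere, which the acceptance script verifies empirically on
a ≥10,000-trial run.  Updates occur on every simulated trial: simulated
agents always respond, so there is no completed/non-completed distinction.

Outcomes are Bernoulli in the chosen arm's current probability.  Event
times place a selection onset and, 0.5 s later, a feedback onset on each
trial, separated by a 2 s post-feedback period and an inter-trial interval
drawn from a truncated normal with mean 0.626 s and SD 0.072 s.

## Learning models

All learners share the state layout of per-arm value means `m` (initialized
at `m0 = 0.5`, the midpoint of the binary reward scale) and, for the Kalman
family, per-arm posterior variances `w` (initialized at `w0 = 0.5`).

* **RW1/RW2** — delta rule with one learning rate, or separate rates for
  rewarded and unrewarded outcomes.  RW2 with equal rates reproduces RW1
  exactly (tested).
* **KF** — constant process noise `v` and observation noise `σ²`; gain
  `k = (w+v)/(w+v+σ²)`, `w' = (1−k)(w+v)`.
* **VKF** — per-arm volatility `v_t` replaces the constant process noise.
  After the mean/variance update, with lag-one posterior covariance
  `w_cov = (1−k) w`,
  `v' = v + λ ((m'−m)² + w + w' − 2 w_cov − v)`, floored at 1e−8.
  The observation-noise parameter ω plays the role of σ² in the gain.  With
  `λ = 0` the VKF trajectory equals the KF trajectory exactly (tested as an
  exact array identity).  The mean update is the linear form
  `m' = m + k (O − m)`; a sigmoid-transformed binary-observation variant is
  deliberately not used so that the nesting identity holds exactly.

**Free parameters.** RW1: `a, βV`; RW2: `a_pos, a_neg, βV`; KF:
`v, σ², β…`; VKF: `λ, v0, ω(σ²), β…`.  `m0`/`w0` are fixed — freeing them
adds nothing identifiable on 300-trial binary sessions.

**Unchosen arms.** Their means are frozen; for KF/VKF their variances are
inflated by the process noise (or their own volatility) each trial, so
uncertainty grows for unsampled options and relative uncertainty can drive
directed exploration.  The per-arm volatility itself updates only on the
chosen arm.

**Choice rules.** Softmax over value only (`βV`), uncertainty only (`βU`),
or both, computed with max-subtraction.  With `use_relative` the inputs are
the relative vectors `RV_i = m_i/Σm`, `RU_i = w_i/Σw`.  The default
comparison grid is {RW1, RW2} × value plus {KF, VKF} × {V, U, V+U} with
relative inputs — 8 models.

**Per-trial regressors.** The prediction error `PE = O − m_pre(chosen)` and
the post-update `RV`/`RU` of the chosen arm are attached to each trial and
held constant until the next selection, matching how the trial event tables
join behavioral regressors to both the post-feedback and pre-selection
analysis stages.

## Model fitting and comparison

Each model is fitted per subject by MAP in a transformed space: sigmoid
links for unit-range parameters (learning rates, λ), exponential links for
positive ones (variances, inverse temperatures), optional scaled-sigmoid
links for upper-bounded parameters.  The transformed-space Gaussian prior
is N(0, 6.25).  Optimization is multi-start L-BFGS (default 8 starts,
seeded); the Laplace log evidence uses a diagonal finite-difference Hessian
(step 1e−3, floored at 1e−6).  `BIC = 2·NLL + d·log(n_trials)`.

The empirical-Bayes hierarchy iterates (1) per-subject MAP fits under the
current group priors, (2) responsibility updates proportional to
per-subject evidences, (3) responsibility-weighted re-estimation of each
model's group prior mean and variance (posterior variances from the
Laplace Hessians included; group variance clipped to at most the initial
6.25 and at least 1e−3).  Convergence is declared when the largest group-
mean shift falls below `tol`.

Random-effects model comparison follows the variational Dirichlet scheme:
model-frequency parameters are updated from evidence-weighted model
posteriors until convergence, and the exceedance probability is the
Monte-Carlo frequency (default 1e5 seeded Dirichlet draws) with which each
model's frequency exceeds all others.

**Identifiability at small scale.** Model identification requires enough
trials for the extra VKF parameters to pay for themselves; at the smoke
preset's 2 subjects × 50–60 trials the nested KF can win on BIC, which is
expected behavior, not a fitting defect.  Likewise, a learning rate is
unrecoverable from an agent whose softmax weight is near zero (its choices
are random); the recovery harness therefore varies one parameter per study
with the others held at identifiable values.

## Synthetic neural data

Two regions (dmPFC, dlPFC; default 4 and 8 channels per synthetic patient,
the real montage's proportions at desk scale) are sampled at 500 Hz.  Each
channel is 1/f^α Gaussian background noise (spectral shaping, default
α = 1, unit SD).  Injected effects are *additive* oscillations, so their
envelopes are analytically known:

* **Regressor-modulated band power** — per trial, a Tukey-tapered
  oscillation at the band's geometric-center frequency with amplitude
  `base · (1 + clip(slope · z, ±0.95))`, `z` the z-scored regressor.
* **PAC** — within the stage window, a slow wave `cos φ_slow` added to the
  phase region and `a₀ (1 + d cos φ_slow) cos φ_fast` to the amplitude
  region, coupling depth `d ∈ [0, 1]`.  For a clean component with `d = 1`
  and `a₀ = 1` the modulation index is exactly 0.5.
* **AAC** — band oscillations whose envelopes mix a shared slow Gaussian
  process (weight √|r|) with independent ones, achieving an envelope
  correlation near the target `r` (clipping at ±2 SD keeps envelopes
  positive and attenuates the realized correlation only slightly).

Per-channel effect amplitudes are jittered ×U(0.8, 1.2).  What the
generator does **not** emulate: volume conduction, epileptiform artifacts,
line noise, non-stationary background, bipolar-montage geometry.  Passing
tests therefore demonstrate correctness of the estimators on clean additive
effects, not robustness to every pathology of real recordings.

## Spectral analysis

* **Frequency grid** — 50 geometrically spaced bins from 4 to 150 Hz;
  this grid has exactly 18 bins below 15 Hz and 22 above 30 Hz, fixing the
  PAC search grid at 18 × 22.
* **Morlet TFR** — complex Morlet convolution (via `mne`) with cycle counts
  geometrically interpolated from 4 at 4 Hz to 9 at 150 Hz.
* **Gabor HAA** — a band is split into 8 log-spaced sub-bands; each is
  filtered with a complex Gabor kernel
  `g(t) = A exp(−s₀t²) exp(2πi v₀ t)` whose frequency-response FWHM equals
  `fbw · v₀` (`fbw = 0.25`), i.e. `s₀ = π²(fbw·v₀)²/(4 ln 2)`; `A` is set
  for exact discrete unit energy, and the envelope SDs satisfy the Gabor
  limit `σ_t σ_f = 1/(4π)` by construction.  Filtering with the complex
  kernel yields the analytic signal directly; sub-band magnitudes are
  averaged.  Averaging sub-band envelopes gives a stabler broadband
  estimate than one wide filter because band power is non-uniform.
* **Epoching** — windows are half-open `[t_pre, t_post)`: at 500 Hz the
  post-feedback window (−0.5 to 2.0 s) yields exactly 1250 samples per
  trial and the selection-stage window (−1.0 to 1.0 s) exactly 1000;
  trials overlapping the recording edges are dropped with their metadata.

## Coupling measures

The PAC modulation index is `MI = |n⁻¹ Σ a_t e^{iφ_t}|` (the modulus of the
complex mean — a complex number cannot be z-scored, so the modulus is taken
before standardization).  The permutation null circularly shifts the
amplitude series (minimum offset 0.1·n to avoid near-identity shifts) with
the phase fixed; `z = (MI − null mean)/null SD`.

A known property: for a *strictly periodic* phase series the circular-shift
null is degenerate, because MI is invariant to a constant phase offset.
Real (and realistically simulated) oscillations drift in frequency, which
breaks this; synthetic validations must include drift.  In the exploratory
grid, the raw-MI peak localizes the injected frequency pair more stably
than the z peak (whose null-SD normalization adds permutation noise), so
both are exposed.

AAC is the per-trial Pearson correlation of two band envelopes over a stage
window (theta–theta across regions, or dmPFC high-gamma versus dlPFC
theta).  Stage windows: post-feedback [0, 2] s from outcome onset,
pre-selection [−1, 0] s from selection onset.  Coupling is computed per
trial (required by the decision-prediction models); channel-pair values are
averaged within patient before group models.

## Group statistics

The reference model is a linear mixed model with random intercepts for
patient and for channel nested in patient (statsmodels `MixedLM`, REML);
a singular nested fit falls back to the patient-only structure with a
logged downgrade.  Codings: decision stay = 1 / switch = 0 (the *next*
trial's decision), feedback reward = 1 / non-reward = 0, stage
pre-selection = 1 / post-feedback = 0; "previous trial feedback" is trial
t−1's outcome with the same coding.

For pixel-wise maps and permutation refits a fast exact-in-expectation path
is used: demeaning the response and regressors within each
patient × channel stratum absorbs both random intercepts exactly, and the
fixed effects are then a single OLS solve vectorized across all pixels,
with degrees of freedom `n − n_strata − k`.  The full `MixedLM` refit is
available per pixel via `method="lme"`; on synthetic maps the two paths'
t-values agree closely (tested: max |Δt| < 0.7, correlation > 0.99).

The 2D cluster-based permutation test thresholds pixels at two-sided
`p < 0.05 / n_fixed`, forms 4-connected clusters, and drops clusters with
area below 320 Hz·ms, where a pixel's area is Δt(ms) × Δf(Hz) with the
geometric local bin width `Δf_i = f_i (r^{1/2} − r^{−1/2})` — the only
self-consistent Hz measure on a log grid.  Each surviving cluster's
statistic is the sum of squared t.  The null shuffles trial labels *within
each patient × channel stratum* (preserving the hierarchical structure) and
records the per-permutation maximum surviving-cluster statistic; observed
clusters are significant beyond the null's 95th percentile.  Family-wise
error calibration (200 null runs × 500 permutations at 3 patients ×
2 channels × 30 trials, 50 × 40-pixel maps) is part of the test suite.

Band time courses use the same per-timepoint regression with
Benjamini–Hochberg correction across timepoints within one analysis trace
(default q = 0.001).  Coupling-level models: stage contrast
`measure ~ stage + (1|patient)`; decision prediction
`decision ~ measure + (1|patient)` as a linear model (a logistic
mixed variant is available behind a flag); variable correlation
`measure ~ pe + rv + ru + (1|patient)` on all / stay / switch subsets, with
a 25-percentile-bin summary for reporting.

## Pipeline scale presets

* **smoke** — 2 patients, 60 trials, 2+2 channels, 100 permutations; runs
  end to end in well under a minute and is exercised by the test suite.
* **desk** — 6 patients, 300 trials, 4+8 channels, 1000 permutations.
* **full** — 14 patients, 500 trials, paper-scale channel proportions,
  5000 permutations; documents the full-scale parameters.

Time–frequency maps are decimated by a factor of 10 (to 20 ms pixels) for
the statistics stage, recorded in provenance.  One global seed fans out
arithmetically to per-stage seeds, so identical configurations reproduce
identical artifacts; the behavioral environment is seeded by the bandit
config and the agent separately, so environments are reproducible
independent of the agent.

## Known limitations

* The hierarchy is an empirical-Bayes skeleton (MAP + Laplace +
  responsibility-weighted shrinkage), not a full variational hierarchical
  Bayesian inference; evidences use diagonal Hessians.
* The decision-prediction model is linear on a binary response by default
  (matching the t-statistic reporting convention); the logistic variant is
  approximate (variational Bayes).
* Per-trial PAC z-scores on short windows are noisy; stage-level contrasts
  aggregate them across trials and patients.
* The synthetic generator's effects are additive and narrowband; detectors
  tuned to multiplicative or broadband effects are not validated here.
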