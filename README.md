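# neuroadapt

Tools for studying how people decide to **stay with or switch away from** a
choice in a volatile environment, and how such decisions could be read out
from prefrontal field potentials.  The package implements, as a tested and
reusable pipeline:

* a **restless three-armed bandit** environment (drifting reward
  probabilities) and agents that play it;
* a family of trial-by-trial learning models — Rescorla–Wagner (one or two
  learning rates), the **Kalman filter**, and the **volatile Kalman filter
  (VKF)**, whose process-noise variance adapts to recent surprise — with
  softmax choice rules over value and/or uncertainty;
* hierarchical **MAP model fitting**, BIC / Laplace evidence, and
  random-effects model comparison by **exceedance probability (XP)**;
* a **synthetic two-region LFP generator** (dmPFC / dlPFC at 500 Hz) that
  injects known regressor-modulated band power, theta→gamma
  **phase–amplitude coupling (PAC)**, and inter-regional envelope
  correlation (**AAC**), so every downstream statistic can be validated
  against ground truth;
* the neural statistics themselves: Morlet time–frequency maps on a 50-bin
  log grid (4–150 Hz), Gabor-bank Hilbert analytic amplitude, PAC modulation
  index with circular-shift permutation z-scores, envelope correlations, and
  **linear mixed-effects t-maps with 2D cluster-based permutation testing**
  and FDR-corrected band time courses.

Everything runs on synthetic data with known ground truth; no recordings are
required.

## The models in brief

Each arm's value estimate `m` is updated from the binary outcome `O`:

* RW: `m ← m + a (O − m)` with learning rate `a` (RW2 uses `a_pos`/`a_neg`).
* KF: gain `k = (w + v)/(w + v + σ²)`, `m ← m + k (O − m)`,
  posterior variance `w ← (1 − k)(w + v)` with process noise `v` and
  observation noise `σ²`.
* VKF: as the KF with `v` replaced by a per-arm volatility `v_t` that tracks
  squared value changes,
  `v ← v + λ ((Δm)² + w_pre + w_post − 2 w_cov − v)`, so surprising streaks
  raise the effective learning rate.

Choices follow a softmax over per-arm utilities; in the best-fitting
configuration the utilities are the **relative value** `RV_i = m_i / Σ_j m_j`
and **relative uncertainty** `RU_i = w_i / Σ_j w_j`:
`P_i ∝ exp(β_V RV_i + β_U RU_i)`.

PAC is quantified by the modulation index `MI = |n⁻¹ Σ_t a_t e^{iφ_t}|`
standardized against a circular-shift null; cluster statistics sum squared
mixed-model t-values over 4-connected suprathreshold time–frequency pixels,
retain clusters of at least 320 Hz·ms, and compare them to a
label-permutation null of maximum cluster statistics.

## Worked example

```python
from neuroadapt.bandit import BanditConfig, simulate_agent, win_stay, lose_shift
from neuroadapt.models import ModelSpec, ModelParams, session_trajectory
from neuroadapt.fitting import map_fit

spec = ModelSpec("VKF", "value_and_uncertainty", use_relative=True)
truth = ModelParams().with_values(lam=0.2, v0=0.3, sigma2=0.4, betaV=6.0, betaU=2.0)
session = simulate_agent(BanditConfig(n_trials=300, seed=1), spec, truth, seed=2)
print(f"win-stay  = {win_stay(session):.3f}")
print(f"lose-shift = {lose_shift(session):.3f}")

traj = session_trajectory(session, spec, truth)
print(f"mean Kalman gain = {traj.k.mean():.3f}")

fit = map_fit(session, spec, n_starts=4, seed=0)
print("recovered:", {k: round(v, 3) for k, v in fit.params_native.items()})
print(f"BIC = {fit.bic:.1f}")
```

prints

```
win-stay  = 0.973
lose-shift = 0.248
mean Kalman gain = 0.749
recovered: {'lam': 0.218, 'v0': 0.284, 'sigma2': 0.229, 'betaV': 5.095, 'betaU': 0.739}
BIC = 137.1
```

The agent repeats rewarded choices far more often than it abandons
unrewarded ones (win-stay 0.97 vs lose-shift 0.25), the hallmark of
value-guided but exploratory play; MAP fitting recovers the generating
volatility learning rate and initial volatility closely, while the softmax
weights — which trade off against each other on a single 300-trial session —
come back attenuated.

The full synthetic study (behavior → fitting → neural generation → spectral →
coupling → group statistics, with a ground-truth-versus-detected report) runs
from the command line:

```
neuroadapt run-all --preset smoke --seed 1 --out runs/
```

## Layout

```
src/neuroadapt/
  bandit.py     environment, agent play, win-stay / lose-shift
  models.py     RW / KF / VKF updates, softmax rules, trajectories, likelihood
  fitting.py    MAP fits, empirical-Bayes hierarchy, BIC, exceedance probability
  synth.py      synthetic two-region LFP with injected ground truth
  spectral.py   log frequency grid, Morlet TFR, Gabor-bank HAA, epoching
  coupling.py   PAC modulation index + permutation z, PAC grid, AAC
  stats.py      mixed-effects maps, 2D cluster permutation, FDR, coupling models
  pipeline.py   configuration-driven end-to-end orchestration
  cli.py        `neuroadapt` command-line entry point
docs/methods.md   model and statistics documentation
```
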