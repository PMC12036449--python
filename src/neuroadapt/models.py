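"""Learning models for the restless bandit: Rescorla–Wagner, Kalman filter,
and volatile Kalman filter, with softmax choice rules over value and/or
uncertainty.

All learners track a per-arm value estimate ``m``.  The Kalman learners also
track a posterior variance ``w`` (estimation uncertainty) and the volatile
variant additionally tracks a per-arm volatility ``v`` — a time-varying
process-noise variance updated from squared value changes, so that surprising
outcomes speed up subsequent learning.

Choice follows a softmax over per-arm utilities.  Utilities may be the raw
value/uncertainty or the *relative* quantities (each arm's share of the
total), the form found to best describe behavior in this task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelParams",
    "LearnerState",
    "LearnerTrajectory",
    "rw_update",
    "kf_update",
    "vkf_update",
    "relative_quantities",
    "choice_probabilities",
    "session_trajectory",
    "session_nll",
    "init_state",
    "update_state",
    "state_choice_probabilities",
    "MODEL_GRID",
]

_LEARNERS = ("RW1", "RW2", "KF", "VKF")
_RULES = ("value_only", "uncertainty_only", "value_and_uncertainty")
_V_FLOOR = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Which learner and which softmax rule make up a model."""

    learner: str
    choice_rule: str = "value_only"
    use_relative: bool = False

    def __post_init__(self) -> None:
        if self.learner not in _LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.choice_rule not in _RULES:
            raise ValueError(f"unknown choice rule {self.choice_rule!r}")
        if "uncertainty" in self.choice_rule and self.learner in ("RW1", "RW2"):
            raise ValueError(
                "uncertainty-based choice rules require a learner that tracks "
                "uncertainty (KF or VKF)"
            )

    @property
    def name(self) -> str:
        tag = {"value_only": "V", "uncertainty_only": "U", "value_and_uncertainty": "VU"}
        rel = "rel" if self.use_relative else "raw"
        return f"{self.learner}-{tag[self.choice_rule]}-{rel}"

    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters, in canonical order."""
        learner = {
            "RW1": ("a",),
            "RW2": ("a_pos", "a_neg"),
            "KF": ("v", "sigma2"),
            "VKF": ("lam", "v0", "sigma2"),
        }[self.learner]
        rule = {
            "value_only": ("betaV",),
            "uncertainty_only": ("betaU",),
            "value_and_uncertainty": ("betaV", "betaU"),
        }[self.choice_rule]
        return learner + rule


@dataclass(frozen=True)
class ModelParams:
    """Parameters for any member of the model family.

    Only the fields named by ``ModelSpec.free_params()`` (plus the fixed
    initial conditions ``m0``/``w0``) are consulted for a given model.  For
    the VKF, ``sigma2`` plays the role of the binary-observation noise ω.
    """

    a: float = 0.3
    a_pos: float = 0.3
    a_neg: float = 0.3
    v: float = 0.1          # KF process-noise variance
    sigma2: float = 0.5     # observation noise (ω for the VKF)
    lam: float = 0.2        # VKF volatility learning rate
    v0: float = 0.1         # VKF initial volatility
    m0: float = 0.5
    w0: float = 0.5
    betaV: float = 3.0
    betaU: float = 3.0

    def validate(self, spec: ModelSpec) -> None:
        for name in ("a", "a_pos", "a_neg", "lam"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.v < 0:
            raise ValueError("process noise v must be nonnegative")
        if spec.learner == "VKF" and self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.betaV < 0 or self.betaU < 0:
            raise ValueError("inverse temperatures must be nonnegative")

    def with_values(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class LearnerState:
    """Per-arm latent state: value mean, posterior variance, volatility."""

    m: np.ndarray
    w: np.ndarray
    v: np.ndarray | None = None  # VKF only

    def copy(self) -> "LearnerState":
        return LearnerState(
            self.m.copy(), self.w.copy(), None if self.v is None else self.v.copy()
        )


@dataclass
class LearnerTrajectory:
    """Per-trial latents from a forward pass over one session.

    ``pe``, ``rv``, ``ru`` at trial ``t`` are the quantities holding *after*
    that trial's outcome update; they remain constant until the next
    selection.  ``choice_probs[t]`` uses the state *before* trial ``t``'s
    outcome.
    """

    m: np.ndarray             # (n_trials, n_arms)
    w: np.ndarray             # (n_trials, n_arms)
    v: np.ndarray | None      # (n_trials, n_arms) for VKF
    k: np.ndarray             # (n_trials,) Kalman gain / effective lr of chosen arm
    pe: np.ndarray            # (n_trials,)
    rv: np.ndarray            # (n_trials,)
    ru: np.ndarray            # (n_trials,)
    choice_probs: np.ndarray  # (n_trials, n_arms)

    @property
    def n_trials(self) -> int:
        return len(self.pe)


# ---------------------------------------------------------------------------
# elementary updates

def rw_update(m_chosen: float, outcome: int, params: ModelParams, variant: str = "RW1") -> float:
    """Rescorla–Wagner delta-rule value update for the chosen arm."""
    if variant == "RW1":
        a = params.a
    elif variant == "RW2":
        a = params.a_pos if outcome == 1 else params.a_neg
    else:
        raise ValueError(f"unknown RW variant {variant!r}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"learning rate {a} outside [0, 1]")
    return m_chosen + a * (outcome - m_chosen)


def kf_update(m: float, w: float, outcome: float, v: float, sigma2: float):
    """One Kalman-filter update of the chosen arm.

    Returns ``(m', w', k, pe)`` with gain ``k = (w+v)/(w+v+sigma2)``,
    ``m' = m + k (O - m)`` and ``w' = (1-k)(w+v)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if w < 0:
        raise ValueError("posterior variance must be nonnegative")
    total = w + v
    k = total / (total + sigma2)
    pe = outcome - m
    m_new = m + k * pe
    w_new = (1.0 - k) * total
    return m_new, w_new, k, pe


def vkf_update(m: float, w: float, v: float, outcome: float, params: ModelParams):
    """One volatile-Kalman-filter update of the chosen arm.

    As :func:`kf_update` with process noise ``v``, plus a volatility update
    driven by the squared value change:
    ``v' = v + lam * ((m'-m)^2 + w + w' - 2 w_cov - v)`` with
    ``w_cov = (1-k) w`` the lag-one posterior covariance.  ``v'`` is floored
    at a small positive epsilon.
    """
    if not np.all(np.isfinite([m, w, v, outcome])):
        raise ValueError("non-finite input to vkf_update")
    omega = params.sigma2
    total = w + v
    k = total / (total + omega)
    pe = outcome - m
    m_new = m + k * pe
    w_new = (1.0 - k) * total
    w_cov = (1.0 - k) * w
    v_new = v + params.lam * ((m_new - m) ** 2 + w + w_new - 2.0 * w_cov - v)
    v_new = max(v_new, _V_FLOOR)
    return m_new, w_new, v_new, k, w_cov, pe


def relative_quantities(state: LearnerState, chosen: int):
    """Relative value and relative uncertainty of the chosen arm.

    ``RV_i = m_i / sum_j m_j`` and ``RU_i = w_i / sum_j w_j``.  Returns
    ``(rv_chosen, ru_chosen, rv_vector, ru_vector)``.
    """
    m_sum = state.m.sum()
    w_sum = state.w.sum()
    if m_sum <= 0 or w_sum <= 0:
        raise ValueError("relative quantities undefined for non-positive totals")
    rv = state.m / m_sum
    ru = state.w / w_sum
    return float(rv[chosen]), float(ru[chosen]), rv, ru


def choice_probabilities(
    values: np.ndarray,
    uncertainties: np.ndarray | None,
    spec: ModelSpec,
    params: ModelParams,
) -> np.ndarray:
    """Softmax choice probabilities under the model's rule.

    ``P_i ∝ exp(betaV·V_i)``, ``exp(betaU·U_i)`` or
    ``exp(betaV·V_i + betaU·U_i)``; computed with max-subtraction for
    overflow safety.
    """
    values = np.asarray(values, dtype=float)
    if spec.choice_rule == "value_only":
        logits = params.betaV * values
    elif spec.choice_rule == "uncertainty_only":
        logits = params.betaU * np.asarray(uncertainties, dtype=float)
    else:
        logits = params.betaV * values + params.betaU * np.asarray(uncertainties, dtype=float)
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


# ---------------------------------------------------------------------------
# state machinery shared by simulation and likelihood

def init_state(n_arms: int, spec: ModelSpec, params: ModelParams) -> LearnerState:
    params.validate(spec)
    m = np.full(n_arms, params.m0)
    w = np.full(n_arms, params.w0)
    v = np.full(n_arms, params.v0) if spec.learner == "VKF" else None
    return LearnerState(m, w, v)


def state_choice_probabilities(state: LearnerState, spec: ModelSpec, params: ModelParams) -> np.ndarray:
    """Choice probabilities from the current latent state."""
    if spec.use_relative:
        V = state.m / state.m.sum()
        U = state.w / state.w.sum() if state.w.sum() > 0 else np.full_like(state.w, 1.0 / len(state.w))
    else:
        V, U = state.m, state.w
    return choice_probabilities(V, U, spec, params)


def update_state(
    state: LearnerState, chosen: int, outcome: int, spec: ModelSpec, params: ModelParams
) -> LearnerState:
    """Apply one trial's outcome; returns the new state.

    Unchosen arms keep their means; for KF/VKF their variances are inflated
    by the process noise (uncertainty grows for unsampled options).
    """
    s = state.copy()
    if spec.learner == "RW1":
        s.m[chosen] = rw_update(s.m[chosen], outcome, params, "RW1")
    elif spec.learner == "RW2":
        s.m[chosen] = rw_update(s.m[chosen], outcome, params, "RW2")
    elif spec.learner == "KF":
        m, w, _, _ = kf_update(s.m[chosen], s.w[chosen], outcome, params.v, params.sigma2)
        unchosen = np.arange(len(s.m)) != chosen
        s.w[unchosen] += params.v
        s.m[chosen], s.w[chosen] = m, w
    else:  # VKF
        m, w, v, _, _, _ = vkf_update(s.m[chosen], s.w[chosen], s.v[chosen], outcome, params)
        unchosen = np.arange(len(s.m)) != chosen
        s.w[unchosen] += s.v[unchosen]
        s.m[chosen], s.w[chosen], s.v[chosen] = m, w, v
    return s


def _chosen_gain(state: LearnerState, chosen: int, outcome: int, spec: ModelSpec, params: ModelParams) -> tuple[float, float]:
    """(gain, prediction error) for the chosen arm at this trial."""
    pe = outcome - state.m[chosen]
    if spec.learner == "RW1":
        return params.a, pe
    if spec.learner == "RW2":
        return (params.a_pos if outcome == 1 else params.a_neg), pe
    if spec.learner == "KF":
        total = state.w[chosen] + params.v
        return total / (total + params.sigma2), pe
    total = state.w[chosen] + state.v[chosen]
    return total / (total + params.sigma2), pe


def session_trajectory(session, spec: ModelSpec, params: ModelParams) -> LearnerTrajectory:
    """Forward pass over a session producing all per-trial latents."""
    params.validate(spec)
    n, n_arms = session.n_trials, session.n_arms
    state = init_state(n_arms, spec, params)
    m = np.empty((n, n_arms))
    w = np.empty((n, n_arms))
    v = np.empty((n, n_arms)) if spec.learner == "VKF" else None
    k = np.empty(n)
    pe = np.empty(n)
    rv = np.empty(n)
    ru = np.empty(n)
    probs = np.empty((n, n_arms))
    for t in range(n):
        c = int(session.choices[t])
        o = int(session.outcomes[t])
        probs[t] = state_choice_probabilities(state, spec, params)
        k[t], pe[t] = _chosen_gain(state, c, o, spec, params)
        state = update_state(state, c, o, spec, params)
        if not np.all(np.isfinite(state.m)):
            raise FloatingPointError(f"non-finite learner state at trial {t}")
        m[t] = state.m
        w[t] = state.w
        if v is not None:
            v[t] = state.v
        rv[t], ru[t], _, _ = relative_quantities(state, c)
    return LearnerTrajectory(m, w, v, k, pe, rv, ru, probs)


def session_nll(session, spec: ModelSpec, params: ModelParams) -> float:
    """Negative log-likelihood of the observed choices under the model.

    Choice probabilities at trial ``t`` use the state *before* that trial's
    outcome.  Zero probabilities are floored at a machine-safe epsilon.
    """
    traj = session_trajectory(session, spec, params)
    p_chosen = traj.choice_probs[np.arange(session.n_trials), session.choices]
    p_chosen = np.clip(p_chosen, 1e-300, None)
    return float(-np.log(p_chosen).sum())


def _model_grid() -> tuple[ModelSpec, ...]:
    grid = [
        ModelSpec("RW1", "value_only", use_relative=False),
        ModelSpec("RW2", "value_only", use_relative=False),
    ]
    for learner in ("KF", "VKF"):
        for rule in _RULES:
            grid.append(ModelSpec(learner, rule, use_relative=True))
    return tuple(grid)


#: default model-comparison grid: RW variants with value softmax, plus
#: KF/VKF with relative value and/or relative uncertainty softmax inputs
MODEL_GRID: tuple[ModelSpec, ...] = _model_grid()
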