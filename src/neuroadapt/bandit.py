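"""Restless three-armed bandit environment, agent play, and model-free measures.

The task is a restless bandit: each arm carries a hidden reward probability
that performs a bounded random walk over trials.  On every trial there is a
``p_change`` chance (per arm, independently) that the arm's probability moves
by ``step`` up or down, clipped to stay inside ``bounds``.  Agents sample
arms, observe Bernoulli rewards, and must keep re-estimating the drifting
probabilities — the classic explore/exploit pressure that value- and
uncertainty-tracking learners are built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BanditConfig",
    "BanditSession",
    "simulate_probability_walk",
    "simulate_agent",
    "win_stay",
    "lose_shift",
]

#: lattice of admissible starting probabilities
_START_LATTICE = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


@dataclass(frozen=True)
class BanditConfig:
    """Parameters of the restless-bandit reward walk.

    Defaults are the task's generative values: a 10% chance per trial and
    per arm that the reward probability steps by ±0.2, bounded in [0.1, 0.9].
    """

    n_trials: int = 300
    n_arms: int = 3
    p_change: float = 0.1
    step: float = 0.2
    bounds: tuple[float, float] = (0.1, 0.9)
    seed: int = 0
    #: seconds between selection onset and feedback onset
    feedback_delay: float = 0.5
    #: inter-trial interval mean/sd in seconds (truncated positive normal)
    iti_mean: float = 0.626
    iti_sd: float = 0.072

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bounds must satisfy 0 <= lo < hi <= 1, got {self.bounds}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0.0 <= self.p_change <= 1.0:
            raise ValueError("p_change must lie in [0, 1]")
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")
        # the walk lives on the lattice lo, lo+step, ..., hi
        n_steps = (hi - lo) / self.step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"step {self.step} does not tile the interval {self.bounds}"
            )


@dataclass
class BanditSession:
    """One simulated session: choices, outcomes and hidden probabilities.

    ``stay_flags[t]`` indicates whether the choice at trial ``t`` repeated the
    choice at trial ``t-1`` (undefined, -1, at trial 0).  Event times are in
    seconds from recording start and strictly increase within the session.
    """

    choices: np.ndarray          # (n_trials,) int
    outcomes: np.ndarray         # (n_trials,) 0/1
    true_probs: np.ndarray       # (n_trials, n_arms)
    stay_flags: np.ndarray       # (n_trials,) 1 stay / 0 switch / -1 undefined
    selection_times: np.ndarray  # (n_trials,) s
    feedback_times: np.ndarray   # (n_trials,) s

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def n_arms(self) -> int:
        return self.true_probs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """One row per trial; the CSV serialization layout."""
        cols = {
            "trial": np.arange(self.n_trials),
            "choice": self.choices,
            "outcome": self.outcomes,
        }
        for a in range(self.n_arms):
            cols[f"p_arm{a + 1}"] = self.true_probs[:, a]
        cols["stay"] = self.stay_flags
        cols["selection_time_s"] = self.selection_times
        cols["feedback_time_s"] = self.feedback_times
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BanditSession":
        arm_cols = sorted(c for c in df.columns if c.startswith("p_arm"))
        return cls(
            choices=df["choice"].to_numpy(int),
            outcomes=df["outcome"].to_numpy(int),
            true_probs=df[arm_cols].to_numpy(float),
            stay_flags=df["stay"].to_numpy(int),
            selection_times=df["selection_time_s"].to_numpy(float),
            feedback_times=df["feedback_time_s"].to_numpy(float),
        )


def simulate_probability_walk(config: BanditConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the bounded reward-probability random walk.

    Each arm starts at a seeded lattice value.  On every trial, independently
    per arm, the probability changes with probability ``p_change``; the
    direction is uniform among the in-bounds directions (at a bound the single
    legal direction is taken), so the total change rate is ``p_change``
    everywhere.

    Returns
    -------
    (n_trials, n_arms) array of probabilities, all within ``bounds``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    lattice = _START_LATTICE[(_START_LATTICE >= lo) & (_START_LATTICE <= hi)]
    p = rng.choice(lattice, size=config.n_arms)
    out = np.empty((config.n_trials, config.n_arms))
    out[0] = p
    for t in range(1, config.n_trials):
        change = rng.random(config.n_arms) < config.p_change
        direction = np.where(rng.random(config.n_arms) < 0.5, -1.0, 1.0)
        # at a bound the only legal direction is inward
        direction = np.where(p - config.step < lo - 1e-12, 1.0, direction)
        direction = np.where(p + config.step > hi + 1e-12, -1.0, direction)
        p = np.where(change, p + direction * config.step, p)
        out[t] = p
    return np.clip(out, lo, hi)


def _event_times(config: BanditConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Selection / feedback onsets with room for the analysis epochs.

    Trial layout: 1 s lead-in, selection onset, ``feedback_delay``, feedback
    onset, 2 s post-feedback window, then a truncated-normal ITI.
    """
    iti = rng.normal(config.iti_mean, config.iti_sd, size=config.n_trials)
    iti = np.clip(iti, 0.05, None)
    trial_len = 1.0 + config.feedback_delay + 2.0 + iti
    starts = 2.0 + np.concatenate([[0.0], np.cumsum(trial_len[:-1])])
    selection = starts + 1.0
    feedback = selection + config.feedback_delay
    return selection, feedback


def simulate_agent(config: BanditConfig, model, params, seed: int | None = None) -> BanditSession:
    """Play an agent through a restless-bandit session.

    ``model``/``params`` are a :class:`~neuroadapt.models.ModelSpec` and
    :class:`~neuroadapt.models.ModelParams`; the agent samples choices from
    its own running softmax probabilities and observes Bernoulli rewards from
    the hidden walk.  Identical seeds produce identical sessions.
    """
    from . import models  # local import to avoid a cycle

    if seed is None:
        seed = config.seed
    # environment comes from the config seed, agent behavior from `seed`
    probs = simulate_probability_walk(config)
    rng = np.random.default_rng(seed)
    state = models.init_state(config.n_arms, model, params)
    choices = np.empty(config.n_trials, dtype=int)
    outcomes = np.empty(config.n_trials, dtype=int)
    for t in range(config.n_trials):
        p_choice = models.state_choice_probabilities(state, model, params)
        c = rng.choice(config.n_arms, p=p_choice)
        o = int(rng.random() < probs[t, c])
        state = models.update_state(state, c, o, model, params)
        choices[t] = c
        outcomes[t] = o
    stay = np.full(config.n_trials, -1, dtype=int)
    stay[1:] = (choices[1:] == choices[:-1]).astype(int)
    selection, feedback = _event_times(config, rng)
    return BanditSession(choices, outcomes, probs, stay, selection, feedback)


def win_stay(session: BanditSession) -> float:
    """Fraction of post-reward trials on which the previous choice was repeated.

    Returns ``nan`` when no trial follows a reward.
    """
    if session.n_trials < 2:
        raise ValueError("win_stay requires a session with at least 2 trials")
    prev_win = session.outcomes[:-1] == 1
    if not prev_win.any():
        return float("nan")
    stayed = session.choices[1:] == session.choices[:-1]
    return float(stayed[prev_win].mean())


def lose_shift(session: BanditSession) -> float:
    """Fraction of post-non-reward trials on which the choice changed.

    Returns ``nan`` when no trial follows a non-reward.
    """
    if session.n_trials < 2:
        raise ValueError("lose_shift requires a session with at least 2 trials")
    prev_loss = session.outcomes[:-1] == 0
    if not prev_loss.any():
        return float("nan")
    shifted = session.choices[1:] != session.choices[:-1]
    return float(shifted[prev_loss].mean())
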