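import numpy as np
import pytest

from neuroadapt.bandit import BanditConfig, BanditSession, simulate_agent
from neuroadapt.models import ModelParams, ModelSpec


def make_session(choices, outcomes, n_arms=3):
    """Hand-built minimal session for enumeration oracles."""
    choices = np.asarray(choices, int)
    outcomes = np.asarray(outcomes, int)
    n = len(choices)
    probs = np.full((n, n_arms), 0.5)
    stay = np.full(n, -1, int)
    stay[1:] = (choices[1:] == choices[:-1]).astype(int)
    sel = 2.0 + 5.0 * np.arange(n)
    return BanditSession(choices, outcomes, probs, stay, sel, sel + 0.5)


@pytest.fixture(scope="session")
def vkf_spec():
    return ModelSpec("VKF", "value_and_uncertainty", use_relative=True)


@pytest.fixture(scope="session")
def agent_session(vkf_spec):
    """A 200-trial session played by the volatile-Kalman agent."""
    cfg = BanditConfig(n_trials=200, seed=11)
    params = ModelParams().with_values(lam=0.2, v0=0.3, sigma2=0.4, betaV=6.0, betaU=2.0)
    return simulate_agent(cfg, vkf_spec, params, seed=12)
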