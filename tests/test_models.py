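"""Learner update equations, softmax rules, and session likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroadapt.bandit import BanditConfig, simulate_agent
from neuroadapt.models import (
    LearnerState, ModelParams, ModelSpec, choice_probabilities, kf_update,
    relative_quantities, rw_update, session_nll, session_trajectory, vkf_update,
)

from conftest import make_session


class TestRescorlaWagner:
    def test_zero_learning_rate_freezes_value(self):
        p = ModelParams().with_values(a=0.0)
        assert rw_update(0.37, 1, p) == pytest.approx(0.37)
        assert rw_update(0.37, 0, p) == pytest.approx(0.37)

    def test_delta_rule_value(self):
        p = ModelParams().with_values(a=0.3)
        assert rw_update(0.5, 1, p) == pytest.approx(0.65)

    def test_symmetric_rw2_reproduces_rw1(self):
        sess = make_session([0, 1, 0, 2, 0, 1], [1, 0, 0, 1, 1, 0])
        p1 = ModelParams().with_values(a=0.4, betaV=3.0)
        p2 = ModelParams().with_values(a_pos=0.4, a_neg=0.4, betaV=3.0)
        t1 = session_trajectory(sess, ModelSpec("RW1"), p1)
        t2 = session_trajectory(sess, ModelSpec("RW2"), p2)
        np.testing.assert_allclose(t1.m, t2.m)
        np.testing.assert_allclose(t1.choice_probs, t2.choice_probs)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            rw_update(0.5, 1, ModelParams().with_values(a=1.5))


class TestKalmanFilter:
    def test_no_uncertainty_limit(self):
        m, w, k, pe = kf_update(0.4, 0.0, 1, 0.0, 0.2)
        assert k == 0.0 and m == 0.4 and w == 0.0

    def test_frozen_example(self):
        m, w, k, pe = kf_update(0.5, 0.1, 1, 0.01, 0.2)
        assert k == pytest.approx(0.354839, abs=1e-6)
        assert m == pytest.approx(0.677419, abs=1e-6)
        assert w == pytest.approx(0.070968, abs=1e-6)
        assert pe == pytest.approx(0.5)

    def test_noiseless_observation_limit(self):
        m, w, k, _ = kf_update(0.2, 0.5, 1, 0.1, 1e-12)
        assert k == pytest.approx(1.0, abs=1e-9)
        assert m == pytest.approx(1.0, abs=1e-9)

    def test_invalid_sigma2_rejected(self):
        with pytest.raises(ValueError):
            kf_update(0.5, 0.1, 1, 0.01, 0.0)

    @given(w=st.floats(0, 5), v=st.floats(0, 5), s2=st.floats(0.01, 5))
    @settings(max_examples=100, deadline=None)
    def test_posterior_variance_contracts(self, w, v, s2):
        _, w_new, k, _ = kf_update(0.5, w, 1, v, s2)
        assert 0.0 <= k <= 1.0
        assert w_new <= w + v + 1e-12


class TestVolatileKalmanFilter:
    def test_frozen_example(self):
        p = ModelParams().with_values(lam=0.1, sigma2=0.5)
        m, w, v, k, w_cov, pe = vkf_update(0.0, 0.5, 0.5, 1, p)
        assert k == pytest.approx(0.666667, abs=1e-6)
        assert m == pytest.approx(0.666667, abs=1e-6)
        assert w == pytest.approx(0.333333, abs=1e-6)
        assert w_cov == pytest.approx(0.166667, abs=1e-6)
        assert v == pytest.approx(0.544444, abs=1e-6)

    def test_zero_volatility_learning_rate_equals_kf(self, agent_session):
        # lam=0 nests the constant-process-noise Kalman filter exactly,
        # including across a full session trajectory
        p_vkf = ModelParams().with_values(lam=0.0, v0=0.15, sigma2=0.4)
        p_kf = ModelParams().with_values(v=0.15, sigma2=0.4)
        spec_v = ModelSpec("VKF", "value_and_uncertainty", use_relative=True)
        spec_k = ModelSpec("KF", "value_and_uncertainty", use_relative=True)
        tv = session_trajectory(agent_session, spec_v, p_vkf)
        tk = session_trajectory(agent_session, spec_k, p_kf)
        np.testing.assert_allclose(tv.m, tk.m, atol=1e-12)
        np.testing.assert_allclose(tv.w, tk.w, atol=1e-12)
        np.testing.assert_allclose(tv.choice_probs, tk.choice_probs, atol=1e-12)
        np.testing.assert_allclose(tv.v, 0.15, atol=1e-12)

    def test_surprising_outcomes_inflate_volatility(self):
        # alternating outcomes keep prediction errors large; volatility
        # rises monotonically over the early trials
        p = ModelParams().with_values(lam=0.3, sigma2=0.3)
        m, w, v = 0.5, 0.2, 0.05
        vs = []
        for t in range(20):
            m, w, v, *_ = vkf_update(m, w, v, t % 2, p)
            vs.append(v)
        assert vs[0] > 0.05
        assert np.all(np.diff(vs[:10]) > 0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            vkf_update(np.nan, 0.5, 0.5, 1, ModelParams())


class TestRelativeQuantities:
    def test_direct_ratio(self):
        state = LearnerState(np.array([0.6, 0.3, 0.1]), np.array([1.0, 1.0, 2.0]))
        rv, ru, rv_vec, ru_vec = relative_quantities(state, 0)
        assert rv == pytest.approx(0.6)
        assert ru == pytest.approx(0.25)

    def test_symmetric_state(self):
        state = LearnerState(np.full(3, 0.4), np.full(3, 0.2))
        rv, ru, _, _ = relative_quantities(state, 2)
        assert rv == pytest.approx(1 / 3) and ru == pytest.approx(1 / 3)

    @given(st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
           st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_normalization_and_scale_invariance(self, ms, scale):
        m = np.array(ms)
        state = LearnerState(m, m.copy())
        _, _, rv, ru = relative_quantities(state, 0)
        assert rv.sum() == pytest.approx(1.0)
        scaled = LearnerState(scale * m, m.copy())
        _, _, rv2, _ = relative_quantities(scaled, 0)
        np.testing.assert_allclose(rv, rv2)

    def test_degenerate_state_rejected(self):
        with pytest.raises(ValueError):
            relative_quantities(LearnerState(np.zeros(3), np.ones(3)), 0)


class TestSoftmax:
    def test_value_only_example(self):
        spec = ModelSpec("RW1", "value_only")
        p = choice_probabilities(np.array([0.8, 0.5, 0.2]), None, spec,
                                 ModelParams().with_values(betaV=2.0))
        np.testing.assert_allclose(p, [0.5405, 0.2967, 0.1628], atol=2e-4)

    def test_uniform_limit(self):
        spec = ModelSpec("KF", "value_and_uncertainty")
        p = choice_probabilities(np.array([9.0, 1.0, 5.0]), np.array([1.0, 2.0, 3.0]),
                                 spec, ModelParams().with_values(betaV=0.0, betaU=0.0))
        np.testing.assert_allclose(p, 1 / 3)

    @given(st.lists(st.floats(-20, 20), min_size=3, max_size=3),
           st.floats(0, 10), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one_and_shift_invariant(self, vals, beta, shift):
        spec = ModelSpec("RW1", "value_only")
        params = ModelParams().with_values(betaV=beta)
        v = np.array(vals)
        p = choice_probabilities(v, None, spec, params)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        p2 = choice_probabilities(v + shift, None, spec, params)
        np.testing.assert_allclose(p, p2, atol=1e-12)

    def test_overflow_safety(self):
        spec = ModelSpec("RW1", "value_only")
        p = choice_probabilities(np.array([1000.0, 0.0, -1000.0]), None, spec,
                                 ModelParams().with_values(betaV=10.0))
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestSessionTrajectory:
    def test_single_trial(self):
        sess = make_session([1], [1])
        traj = session_trajectory(sess, ModelSpec("RW1"), ModelParams().with_values(a=0.2))
        assert traj.n_trials == 1
        assert traj.pe[0] == pytest.approx(1 - 0.5)

    def test_rw1_matches_closed_form_exponential_average(self):
        # single arm chosen throughout: m_t = (1-a)^t m0 + sum a (1-a)^(t-1-s) O_s
        rng = np.random.default_rng(0)
        outcomes = rng.integers(0, 2, 30)
        sess = make_session(np.zeros(30, int), outcomes)
        a, m0 = 0.35, 0.5
        traj = session_trajectory(sess, ModelSpec("RW1"),
                                  ModelParams().with_values(a=a, m0=m0))
        for t in range(30):
            expect = (1 - a) ** (t + 1) * m0 + sum(
                a * (1 - a) ** (t - s) * outcomes[s] for s in range(t + 1))
            assert traj.m[t, 0] == pytest.approx(expect)

    def test_pe_uses_pre_update_mean(self, agent_session):
        spec = ModelSpec("KF", "value_only", use_relative=True)
        params = ModelParams()
        traj = session_trajectory(agent_session, spec, params)
        c0 = agent_session.choices[0]
        assert traj.pe[0] == pytest.approx(agent_session.outcomes[0] - params.m0)
        # after the update the stored mean differs from the pre-update one
        assert traj.m[0, c0] != params.m0


class TestSessionNLL:
    def test_uniform_model(self):
        sess = make_session([0, 1, 2, 0, 1], [1, 0, 1, 0, 1])
        params = ModelParams().with_values(betaV=0.0)
        nll = session_nll(sess, ModelSpec("RW1"), params)
        assert nll == pytest.approx(5 * np.log(3))

    def test_generating_parameters_beat_wrong_ones(self):
        spec = ModelSpec("RW1", "value_only")
        good = ModelParams().with_values(a=0.3, betaV=5.0)
        bad = ModelParams().with_values(a=0.95, betaV=0.2)
        diffs = []
        for rep in range(20):
            sess = simulate_agent(BanditConfig(n_trials=300, seed=rep), spec, good,
                                  seed=100 + rep)
            diffs.append(session_nll(sess, spec, bad) - session_nll(sess, spec, good))
        assert np.mean(diffs) > 0

    def test_arm_relabeling_invariance(self, agent_session):
        spec = ModelSpec("VKF", "value_and_uncertainty", use_relative=True)
        params = ModelParams()
        base = session_nll(agent_session, spec, params)
        perm = np.array([2, 0, 1])
        sess2 = make_session(perm[agent_session.choices], agent_session.outcomes)
        assert session_nll(sess2, spec, params) == pytest.approx(base)
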