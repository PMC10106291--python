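"""Agent models: update arithmetic, policy structure, likelihood validity,
and agreement between the compiled kernels and an independent pure-Python
replay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from transtep import agents, fitting


class TestIstlUpdate:
    def test_observed_transition_moves_toward_one(self):
        B = np.full((2, 2), 0.5)
        B2 = agents.istl_update(B, action=0, observed=1, gamma=0.5)
        assert B2[0, 1] == pytest.approx(0.75)
        assert B2[0, 0] == pytest.approx(0.25)

    def test_zero_learning_rate_is_identity(self):
        B = np.array([[0.3, 0.7], [0.6, 0.4]])
        assert np.allclose(agents.istl_update(B, 1, 0, gamma=0.0), B)

    def test_gamma_one_fixed_points(self):
        B = np.array([[0.3, 0.7], [0.6, 0.4]])
        B = agents.istl_update(B, 0, 1, gamma=1.0)
        assert B[0, 1] == 1.0 and B[0, 0] == 0.0
        assert np.allclose(B[1], 0.5)  # untaken action decays fully to prior

    def test_multigoal_mode_tracks_binary_outcomes(self):
        B = np.full((2, 2), 0.5)
        B = agents.istl_update(B, 0, (1, 0), gamma=0.4, mode="multigoal")
        assert B[0, 0] == pytest.approx(0.7)
        assert B[0, 1] == pytest.approx(0.3)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            agents.istl_update(np.full((2, 2), 0.5), 0, 1, gamma=1.5)

    @settings(max_examples=50, derandomize=True)
    @given(hst.lists(hst.tuples(hst.integers(0, 1), hst.integers(0, 1),
                                hst.floats(0.0, 1.0)), min_size=1, max_size=40))
    def test_belief_invariants_preserved(self, seq):
        B = np.full((2, 2), 0.5)
        for a, s, g in seq:
            B = agents.istl_update(B, a, s, g)
            assert np.all(B >= 0) and np.all(B <= 1)
            assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)


class TestTypicalInfer:
    def test_zero_counts_give_average_matrix(self):
        assert np.allclose(agents.typical_infer(np.zeros((2, 2))), 0.5)

    def test_single_diagonal_count_selects_t1(self):
        C = np.zeros((2, 2))
        C[0, 0] = 1  # action 0 -> state 0 observed once
        B = agents.typical_infer(C)
        assert B[0, 0] == 0.7 and B[1, 1] == 0.7

    def test_off_diagonal_counts_select_t2(self):
        C = np.array([[0.0, 3.0], [2.0, 0.0]])
        B = agents.typical_infer(C)
        assert B[0, 1] == 0.7 and B[1, 0] == 0.7

    def test_permutation_covariance(self):
        C = np.array([[5.0, 1.0], [2.0, 7.0]])
        B = agents.typical_infer(C)
        # relabel both states and actions: counting matrix flips both axes
        B_swapped = agents.typical_infer(C[::-1, ::-1])
        assert np.allclose(B_swapped, B[::-1, ::-1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            agents.typical_infer(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestMFUpdate:
    def test_full_learning_jumps_to_target(self):
        Q = agents.mf_value_update(np.zeros(2), 0, target=1.0, alpha=1.0, decay=0.0)
        assert Q[0] == 1.0

    @pytest.mark.parametrize("decay,expected", [(0.0, 0.8), (1.0, 0.0), (0.5, 0.4)])
    def test_unchosen_decay_toward_zero(self, decay, expected):
        Q = agents.mf_value_update(np.array([0.2, 0.8]), 0, 0.0, alpha=0.0, decay=decay)
        assert Q[1] == pytest.approx(expected)

    def test_halfway_update_arithmetic(self):
        Q = agents.mf_value_update(np.array([0.4]), 0, target=1.0, alpha=0.5, decay=0.0)
        assert Q[0] == pytest.approx(0.7)

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            agents.mf_value_update(np.zeros(2), 0, 1.0, alpha=-0.1, decay=0.0)


class TestTwoStepPolicy:
    def _params(self, **kw):
        base = dict(gamma=0.3, alpha=0.5, decay=0.4, beta_mb=2.0,
                    beta_mf=0.5, beta2=2.0, pi_stick=0.2)
        base.update(kw)
        return agents.AgentParamsTwoStep(**base)

    def test_uniform_belief_reduces_to_mf_plus_stick(self):
        q2 = np.array([[0.8, 0.2], [0.1, 0.9]])
        out = agents.two_step_choice_values(np.full((2, 2), 0.5), q2, self._params(),
                                            prev_action=None, q_mf=np.array([0.0, 0.0]))
        assert out["q_mb"][0] == pytest.approx(out["q_mb"][1])
        assert out["policy1"] == pytest.approx([0.5, 0.5])

    def test_strong_mb_weight_approaches_argmax(self):
        belief = np.array([[1.0, 0.0], [0.0, 1.0]])
        q2 = np.array([[1.0, 0.0], [0.0, 0.0]])  # state 0 is valuable
        out = agents.two_step_choice_values(belief, q2, self._params(beta_mb=500.0),
                                            prev_action=None)
        assert out["policy1"][0] > 0.999

    def test_policies_are_probabilities(self):
        out = agents.two_step_choice_values(
            np.array([[0.7, 0.3], [0.3, 0.7]]), np.array([[0.4, 0.6], [0.2, 0.1]]),
            self._params(), prev_action=1, q_mf=np.array([0.3, -0.2]))
        assert out["policy1"].sum() == pytest.approx(1.0)
        assert np.allclose(out["policy2"].sum(axis=1), 1.0)

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError):
            agents.two_step_choice_values(np.full((2, 2), np.nan), np.zeros((2, 2)),
                                          self._params(), None)


class TestMultiGoalPolicy:
    def _params(self, **kw):
        base = dict(gamma=0.4, alpha_mf=0.5, beta_mb_reward=0.0, beta_mb_punish=0.0,
                    beta_gp_reward=0.0, beta_gp_punish=0.0, beta_mf=0.0, beta_ap=0.0)
        base.update(kw)
        return agents.AgentParamsMultiGoal(**base)

    def test_avoid_trial_goal_vector_zeroes_reward_value(self):
        B = np.array([[0.6, 0.3], [0.5, 0.5]])
        out = agents.multigoal_action_values(B, goal=1, q_mf=np.zeros(2),
                                             prev_action=None, params=self._params())
        assert out["q_mb_punish"][0] == pytest.approx(-0.3)
        assert out["q_mb_reward"][0] == 0.0

    def test_all_zero_weights_give_uniform_policy(self):
        out = agents.multigoal_action_values(np.random.default_rng(0).random((2, 2)),
                                             0, np.array([1.0, -1.0]), 1, self._params())
        assert out["policy"] == pytest.approx([0.5, 0.5])

    def test_action_perseveration_isolated(self):
        out = agents.multigoal_action_values(np.full((2, 2), 0.5), 0, np.zeros(2),
                                             prev_action=0,
                                             params=self._params(beta_ap=2.0))
        expected = agents.softmax(np.array([2.0, 0.0]))
        assert out["policy"] == pytest.approx(expected)

    def test_unknown_goal_rejected(self):
        with pytest.raises(ValueError):
            agents.multigoal_action_values(np.full((2, 2), 0.5), 2, np.zeros(2),
                                           None, self._params())


# ---------------------------------------------------------------------------
# likelihood cross-validation

def _replay_istl_loglik(df, p):
    """Independent trial-by-trial replay with scalar ops and the module's
    primitive updates."""
    B = np.full((2, 2), 0.5)  # P(state | action)
    q2 = np.zeros((2, 2))
    qmf = np.zeros(2)
    prev = None
    ll = 0.0
    for _, row in df.sort_values("trial").iterrows():
        a1, s2, a2, r = int(row.action), int(row.state), int(row.action2), float(row.reward)
        out = agents.two_step_choice_values(B, q2, p, prev, qmf)
        ll += np.log(out["policy1"][a1])
        ll += np.log(out["policy2"][s2, a2])
        B = agents.istl_update(B, a1, s2, p.gamma)
        q2 = agents.mf_value_update(q2, (s2, a2), r, p.alpha, p.decay)
        qmf = agents.mf_value_update(qmf, a1, r, p.alpha, p.decay)
        prev = a1
    return ll


class TestLikelihoods:
    def test_kernel_matches_pure_python_replay(self, rng):
        theta = fitting.moderate_prior(agents.ISTL).sample(1, rng)
        log = agents.ISTL.simulate(theta, 20, rng)
        p = agents.AgentParamsTwoStep(*theta[0])
        expected = _replay_istl_loglik(log, p)
        got = fitting.subject_loglik(agents.ISTL, theta[0], log)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_kernel_matches_numpy_reference(self, small_twostep_log, rng):
        log, _ = small_twostep_log
        data = agents.ISTL.stack(log)
        theta = fitting.moderate_prior(agents.ISTL).sample(50, rng)
        assert np.allclose(agents.ISTL.loglik(data, theta),
                           agents.ISTL.loglik_reference(data, theta), atol=1e-9)
        theta_t = fitting.moderate_prior(agents.TYPICAL).sample(50, rng)
        assert np.allclose(agents.TYPICAL.loglik(data, theta_t),
                           agents.TYPICAL.loglik_reference(data, theta_t), atol=1e-9)

    def test_indifferent_agent_loglik_is_n_log_half(self, small_twostep_log):
        log, _ = small_twostep_log
        one = log[log.participant_id == 0]
        n = len(one)
        flat = dict(gamma=0.5, alpha=0.5, decay=0.5, beta_mb=0.0,
                    beta_mf=0.0, beta2=0.0, pi_stick=0.0)
        # two binary choices per two-step trial
        assert fitting.subject_loglik(agents.ISTL, flat, one) == pytest.approx(2 * n * np.log(0.5))

    def test_adding_trials_never_increases_loglik(self, small_twostep_log):
        log, theta = small_twostep_log
        one = log[log.participant_id == 0]
        p = theta[0]
        full = fitting.subject_loglik(agents.ISTL, p, one)
        short = fitting.subject_loglik(agents.ISTL, p, one[one.trial < 60])
        assert full <= short

    def test_loglik_finite_across_prior_box(self, small_twostep_log, rng):
        log, _ = small_twostep_log
        data = agents.ISTL.stack(log)
        theta = fitting.GroupPrior.naive(agents.ISTL.param_specs).sample(200, rng)
        assert np.isfinite(agents.ISTL.loglik(data, theta)).all()

    def test_true_gamma_dominates_perturbed(self, rng):
        th = np.array([[0.4, 0.5, 0.4, 4.0, 0.8, 2.5, 0.2]])
        log = agents.ISTL.simulate(th, 2000, rng)
        data = agents.ISTL.stack(log)
        ll_true = agents.ISTL.loglik(data, th)[0, 0]
        for dg in (-0.3, 0.3):
            perturbed = th.copy()
            perturbed[0, 0] += dg
            assert agents.ISTL.loglik(data, perturbed)[0, 0] < ll_true

    def test_multigoal_loglik_matches_primitive_replay(self, small_multigoal_log):
        log, theta = small_multigoal_log
        one = log[log.participant_id == 0].sort_values("trial")
        p = agents.AgentParamsMultiGoal(*theta[0])
        B = np.full((2, 2), 0.5)
        qmf = np.zeros(2)
        prev = None
        ll = 0.0
        for _, row in one.iterrows():
            g = 0 if row.goal == "seek" else 1
            a = int(row.action)
            out = agents.multigoal_action_values(B, g, qmf, prev, p)
            ll += np.log(out["policy"][a])
            B = agents.istl_update(B, a, (row.reached_reward, row.reached_punish),
                                   p.gamma, mode="multigoal")
            qmf[a] += p.alpha_mf * (row.points - qmf[a])
            prev = a
        got = fitting.subject_loglik(agents.MULTIGOAL, theta[0], one)
        assert got == pytest.approx(ll, abs=1e-10)


class TestSimulators:
    def test_reproducible_under_seed(self):
        theta = np.array([[0.4, 0.5, 0.4, 3.0, 0.8, 2.5, 0.2]] * 3)
        a = agents.ISTL.simulate(theta, 50, np.random.default_rng(9))
        b = agents.ISTL.simulate(theta, 50, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_common_transition_rate_in_logs(self, small_twostep_log):
        log, _ = small_twostep_log
        assert abs(log["common"].mean() - 0.7) < 0.03
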