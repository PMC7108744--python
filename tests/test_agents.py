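"""Update rules, their hand-computed values, and the k-ToM belief machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktom import _ktom_core as core
from ktom._ktom_reference import RefKTom, simulate_level
from ktom.agents import (
    InfluenceState,
    KTomState,
    RBSchedule,
    RLState,
    Tom0State,
    WSLSState,
    influence_update,
    ktom_predict,
    ktom_simulate_level,
    ktom_update,
    make_agent,
    rl_update,
    tom0_predict,
    tom0_update,
    wsls_update,
)


class TestRBSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_exact_bias_count(self, seed):
        sched = RBSchedule.generate(60, preferred=1, seed=seed)
        assert sum(sched.sequence) == 39  # round(0.65 * 60)
        assert len(sched.sequence) == 60

    def test_schedule_independent_of_play(self):
        ag = make_agent("RB", role="hider", seed=5)
        seq = [ag.act(None) for _ in range(3)]
        # observing arbitrary outcomes never changes the predetermined order
        ag2 = make_agent("RB", role="hider", seed=5)
        seq2 = []
        for _ in range(3):
            seq2.append(ag2.act(None))
            ag2.observe(a_self=seq2[-1], a_op=1, reward=0)
        assert seq[0] == seq2[0]


class TestTom0:
    def test_hand_computed_update(self):
        s = Tom0State(mu=0.0, sigma2=1.0, volatility=0.5)
        s2 = tom0_update(s, a_op=1)
        assert s2.sigma2 == pytest.approx(1 / (1 / 1.5 + 0.25), abs=1e-6)
        assert s2.mu == pytest.approx(s2.sigma2 * 0.5, abs=1e-6)

    def test_negligible_error_at_saturation(self):
        s = Tom0State(mu=30.0, sigma2=0.5, volatility=0.1)
        s2 = tom0_update(s, a_op=1)
        assert abs(s2.mu - s.mu) < 1e-6

    def test_constant_opponent_drives_belief_up(self):
        s = Tom0State(volatility=0.1)
        for _ in range(60):
            s = tom0_update(s, a_op=1)
        assert 1 / (1 + math.exp(-s.mu)) > 0.9

    def test_predict_symmetry_and_shrinkage(self):
        assert tom0_predict(Tom0State(mu=0.0, sigma2=3.0)) == pytest.approx(0.5)
        sharp = tom0_predict(Tom0State(mu=4.0, sigma2=0.01, volatility=0.01))
        blurred = tom0_predict(Tom0State(mu=4.0, sigma2=25.0, volatility=0.01))
        assert sharp > 0.95
        assert 0.5 < blurred < sharp

    def test_moment_closure_matches_quadrature(self):
        # Gauss-Hermite oracle for E[s(x)], x ~ N(mu, v)
        nodes, weights = np.polynomial.hermite_e.hermegauss(31)
        for mu in (-3.0, -0.7, 0.0, 1.2, 4.0):
            for v in (0.05, 0.5, 2.0, 8.0):
                exact = float(
                    np.sum(weights / np.sqrt(2 * np.pi)
                           / (1 + np.exp(-(mu + math.sqrt(v) * nodes))))
                )
                approx = tom0_predict(
                    Tom0State(mu=mu, sigma2=v / 2, volatility=v / 2)
                )
                assert approx == pytest.approx(exact, abs=0.02)

    def test_one_step_update_close_to_exact_bayes(self):
        # quadrature oracle for a single Bernoulli update from the prior
        for sigma in (0.01, 0.1, 0.5):
            x = np.linspace(-12, 12, 100001)
            w = np.exp(-0.5 * x**2 / (1.0 + sigma))
            post = w / (1 + np.exp(-x))
            exact_mean = float(np.sum(x * post) / post.sum())
            s = tom0_update(Tom0State(volatility=sigma), a_op=1)
            assert abs(s.mu - exact_mean) < 0.05

    def test_small_volatility_limit_tracks_choice_frequency(self):
        # fictitious-play limit: mu approaches the empirical log-odds
        rng = np.random.default_rng(1)
        a = (rng.random(400) < 0.7).astype(int)
        s = Tom0State(volatility=1e-4)
        for ai in a:
            s = tom0_update(s, int(ai))
        assert s.mu == pytest.approx(math.log(a.mean() / (1 - a.mean())), abs=0.25)


class TestInfluence:
    def test_hand_computed_update(self):
        s = InfluenceState(p_op=0.5, eta=0.5, influence_weight=0.2, beta_inf=1.0)
        s2 = influence_update(s, a_op=1, a_self=1)
        assert s2.p_op == pytest.approx(0.70, abs=1e-12)

    def test_reduces_to_exponential_smoothing_without_influence(self):
        s = InfluenceState(p_op=0.4, eta=0.3, influence_weight=0.0, beta_inf=1.0)
        s2 = influence_update(s, a_op=1, a_self=0)
        assert s2.p_op == pytest.approx(0.4 + 0.3 * 0.6)

    def test_pure_influence_term(self):
        s = InfluenceState(p_op=0.5, eta=0.0, influence_weight=0.2, beta_inf=0.0)
        s2 = influence_update(s, a_op=0, a_self=0)
        assert s2.p_op == pytest.approx(0.5 + 0.2 * 0.25)

    @given(
        p=st.floats(0.01, 0.99),
        eta=st.floats(0, 1),
        w=st.floats(0, 1),
        a_op=st.integers(0, 1),
        a_self=st.integers(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_estimate_stays_clipped(self, p, eta, w, a_op, a_self):
        s = InfluenceState(p_op=p, eta=eta, influence_weight=w, beta_inf=2.0)
        s2 = influence_update(s, a_op=a_op, a_self=a_self)
        assert 1e-4 <= s2.p_op <= 1 - 1e-4


class TestRL:
    def test_basic_and_zero_error(self):
        s = RLState(values=(0.0, 0.0), alpha=0.5)
        s2 = rl_update(s, a_self=1, reward=1)
        assert s2.values == (0.0, 0.5)
        s3 = rl_update(RLState(values=(0.0, 0.5), alpha=0.5), 1, 1)
        assert s3.values[1] == pytest.approx(0.75)
        same = rl_update(RLState(values=(0.3, 0.3), alpha=0.9), 0, 0.3)
        assert same.values[0] == pytest.approx(0.3)

    def test_alpha_one_is_wsls_like_on_chosen_arm(self):
        s = rl_update(RLState(values=(0.2, 0.8), alpha=1.0), a_self=0, reward=1)
        assert s.values[0] == 1.0
        assert s.values[1] == 0.8  # unchosen untouched

    def test_values_bounded_under_unit_rewards(self, rng):
        s = RLState(alpha=0.7)
        for _ in range(200):
            s = rl_update(s, int(rng.integers(2)), int(rng.integers(2)))
            assert 0.0 <= min(s.values) and max(s.values) <= 1.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            RLState(alpha=0.0)


class TestWSLS:
    def test_win_stay_lose_switch_values(self):
        win = wsls_update(WSLSState(), a_self=1, reward=1)
        assert win.values == (-1.0, 1.0)  # stay on 1 preferred
        lose = wsls_update(WSLSState(), a_self=1, reward=0)
        assert lose.values == (1.0, -1.0)  # switch preferred
        again = wsls_update(win, a_self=1, reward=1)
        assert again == win  # idempotent on repeated wins


class TestKTomBeliefs:
    def test_level_posterior_point_mass_for_k1(self):
        s = KTomState(k=1, role=1, volatility=1.0)
        for a_op in (1, 0, 1, 1, 0):
            s = ktom_update(s, a_op=a_op, a_self=1 - a_op)
            assert s.level_posterior[0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_level_likelihoods_leave_lambda_unchanged(self):
        # before any observation both levels predict 0.5 exactly
        s = KTomState(k=2, role=1, volatility=1.0)
        s2 = ktom_update(s, a_op=1, a_self=0)
        assert s2.level_posterior == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_initial_prediction_is_half(self):
        for k in (1, 2, 3):
            s = KTomState(k=k, role=1, volatility=1.0)
            assert ktom_predict(s) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_simplex_and_positive_definiteness_random_sequences(self, k, rng):
        # 25 random 60-trial sequences per sophistication level
        for _ in range(25):
            s = KTomState(k=k, role=1, volatility=1.0)
            a_s = rng.integers(0, 2, 60)
            a_o = rng.integers(0, 2, 60)
            for t in range(60):
                s = ktom_update(s, a_op=int(a_o[t]), a_self=int(a_s[t]))
            lam = s.level_posterior
            assert abs(lam.sum() - 1.0) < 1e-10 and np.all(lam >= 0)
            for kappa in range(k):
                cov = s.level_cov(kappa)
                assert np.allclose(cov, cov.T)
                assert np.linalg.eigvalsh(cov).min() > 0

    def test_sophistication_identification_long_run(self):
        # a 2-ToM facing a true 1-ToM favours the level-1 hypothesis
        rng = np.random.default_rng(11)
        two = make_agent("2-ToM", role="seeker", sigma=0.5)
        one = make_agent("1-ToM", role="hider", sigma=0.5)
        lam1 = []
        for t in range(500):
            a_s = two.act(rng)
            a_h = one.act(rng)
            two.observe(a_self=a_s, a_op=a_h, reward=int(a_s == a_h))
            one.observe(a_self=a_h, a_op=a_s, reward=int(a_s != a_h))
            if t >= 400:
                lam1.append(two.state.level_posterior[1])
        assert np.mean(lam1) > 0.5

    def test_mixture_prediction_matches_manual_mixture(self, rng):
        s = KTomState(k=2, role=1, volatility=1.0)
        for _ in range(15):
            s = ktom_update(s, a_op=int(rng.integers(2)), a_self=int(rng.integers(2)))
        lam = s.level_posterior
        p0 = core._level_stats0(s.vec, 2, 4, 8, 1.0, -1.0)[3]
        p1 = core._level_stats1(s.vec, 18, 20, 24, 1.0, -1.0)[3]
        assert ktom_predict(s) == pytest.approx(lam[0] * p0 + lam[1] * p1)


class TestEngineAgainstReference:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_numba_and_recursive_python_trajectories_agree(self, k, rng):
        vec = core.init_state(k)
        ref = RefKTom(k, +1)
        a_s = rng.integers(0, 2, 60)
        a_o = rng.integers(0, 2, 60)
        for t in range(60):
            pn = core.predict_k(vec, k, 0.8, 1.0)
            pr = ref.predict_opponent(0.8)
            assert pn == pytest.approx(pr, abs=1e-8)
            core.update_k(vec, k, 0.8, 1.0, int(a_s[t]), int(a_o[t]))
            ref.update(0.8, a_self=int(a_s[t]), a_op=int(a_o[t]))
            assert np.max(np.abs(ref.lam - vec[:k])) < 1e-8


class TestSimulateLevelReplay:
    def test_flat_prior_gives_half(self):
        p = ktom_simulate_level(0, [0.0, 0.0], [], [], role="seeker")
        assert p == pytest.approx(0.5)

    def test_hider_avoids_a_constant_seeker(self):
        # replaying a 0-ToM hider against a seeker who always played 1
        hist = [1] * 30
        p = ktom_simulate_level(0, [0.0, -1.0], hist, [0] * 30, role="seeker")
        assert p < 0.5

    def test_deterministic_in_inputs(self, rng):
        a_s = rng.integers(0, 2, 20)
        a_o = rng.integers(0, 2, 20)
        x = [0.3, -0.5]
        for kappa in (0, 1, 2):
            p1 = ktom_simulate_level(kappa, x, a_s, a_o, role="seeker")
            p2 = ktom_simulate_level(kappa, x, a_s, a_o, role="seeker")
            assert p1 == p2
            assert 0.0 < p1 < 1.0

    def test_online_bank_converges_to_replay_definition(self):
        """The incrementally maintained replica bank approaches the
        full-history replay value of v^kappa as the parameter posterior
        settles (near-zero volatility, 60 trials)."""
        rng = np.random.default_rng(4)
        a_s = rng.integers(0, 2, 60)
        a_o = rng.integers(0, 2, 60)
        agent = RefKTom(1, +1)
        tiny = 1e-8
        for t in range(60):
            agent.update(tiny, a_self=int(a_s[t]), a_op=int(a_o[t]))
        v_c, _, _ = agent._level_stats(0, tiny)
        p_replay = simulate_level(0, agent.mu[0], a_s, a_o, +1)
        p_online = 1 / (1 + math.exp(-v_c))
        assert p_online == pytest.approx(p_replay, abs=0.01)


class TestAgentFactory:
    def test_unknown_parameters_rejected(self):
        with pytest.raises(ValueError, match="unknown agent parameters"):
            make_agent("RL", role="seeker", learning_rate=0.5)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_agent("4-ToM")

    def test_bn_with_zero_bias_plays_half(self, rng):
        ag = make_agent("BN", role="seeker", bias=0.0)
        acts = [ag.act(rng) for _ in range(2000)]
        assert abs(np.mean(acts) - 0.5) < 0.05

    def test_greedy_limit_is_argmax(self, rng):
        ag = make_agent("WSLS", role="seeker", beta=1e-6)
        ag.observe(a_self=1, a_op=1, reward=1)  # won on 1 -> stay
        assert all(ag.act(rng) == 1 for _ in range(20))
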