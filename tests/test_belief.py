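"""Beta-belief hub, momentum self-belief, sigmoid readout and its exact density."""

import dataclasses
from math import exp, log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

import sociometer as s
from sociometer import config
from sociometer.belief import (
    beta_counts,
    choice_prob_belief,
    decay_group_beliefs,
    expected_se,
    group_pe,
    init_beliefs,
    initial_p_acc,
    inverse_readout,
    se_rating_logdensity,
    se_readout,
    update_group_beliefs,
    update_self_belief,
)
from sociometer.errors import ParameterError


class TestInitialBeliefs:
    def test_total_count_tied_to_decay(self):
        p = s.BeliefParams(lambda_acc=0.5, alpha0_min=1.0, alpha0_max=3.0)
        assert p.n0 == pytest.approx(4.0)
        state = init_beliefs(p, 4)
        assert state.n == pytest.approx([4.0] * 4)

    def test_linear_interpolation_of_group_alphas(self):
        p = s.BeliefParams(lambda_acc=0.5, alpha0_min=1.0, alpha0_max=3.0)
        state = init_beliefs(p, 4)
        assert state.alpha == pytest.approx([1.0, 5 / 3, 7 / 3, 3.0])
        assert state.beta == pytest.approx([3.0, 7 / 3, 5 / 3, 1.0])

    def test_one_in_four_belief_maps_to_counts(self):
        # "1 in 4 people in this group will like me" -> Beta(1, 3)
        assert beta_counts(1, 4) == (1, 3)

    def test_excessive_alpha0_max_rejected(self):
        p = s.BeliefParams(lambda_acc=0.5, alpha0_min=1.0, alpha0_max=3.5)
        with pytest.raises(ParameterError, match="alpha0_max"):
            init_beliefs(p, 4)

    def test_initial_pooled_expectation(self):
        p = s.BeliefParams(lambda_acc=0.5, alpha0_min=1.0, alpha0_max=3.0)
        state = init_beliefs(p, 4)
        assert initial_p_acc(state) == pytest.approx(0.5)  # symmetric design


class TestGroupBeliefDynamics:
    def test_uniform_is_decay_fixed_point(self):
        p = s.BeliefParams(lambda_acc=0.4, alpha0_min=1.0, alpha0_max=1.0)
        state = s.BeliefState([1.0, 1.0], [1.0, 1.0])
        out = decay_group_beliefs(state, p)
        assert out.alpha == [1.0, 1.0] and out.beta == [1.0, 1.0]

    def test_decay_arithmetic_and_limit(self):
        p = s.BeliefParams(lambda_acc=0.5)
        state = s.BeliefState([5.0, 2.0], [2.0, 2.0])
        out = decay_group_beliefs(state, p)
        assert out.alpha[0] == pytest.approx(3.0)
        for _ in range(60):
            state = decay_group_beliefs(state, p)
        assert state.alpha == pytest.approx([1.0, 1.0], abs=1e-12)

    @pytest.mark.parametrize("outcome,expected", [(1, 0.75), (0, -0.25)])
    def test_prediction_error_on_primed_counts(self, outcome, expected):
        state = s.BeliefState([1.0, 1.0], [3.0, 1.0])
        assert group_pe(state, 0, outcome) == pytest.approx(expected)

    def test_certain_approval_gives_zero_error(self):
        state = s.BeliefState([4.0, 1.0], [1e-12, 1.0])
        assert group_pe(state, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_count_update_routes_by_outcome(self):
        state = s.BeliefState([2.0, 2.0], [2.0, 2.0])
        up = update_group_beliefs(state, 0, 1)
        assert (up.alpha[0], up.beta[0]) == (3.0, 2.0)
        down = update_group_beliefs(state, 0, 0)
        assert (down.alpha[0], down.beta[0]) == (2.0, 3.0)
        none = update_group_beliefs(state, 0, None)
        assert none.alpha == state.alpha and none.beta == state.beta
        assert up.alpha[1] == 2.0  # non-encountered group untouched

    @settings(derandomize=True, max_examples=100)
    @given(outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=150),
           lam=st.floats(0.05, 0.95), vs=st.floats(0.05, 1.0),
           w=st.floats(0.0, 5.0))
    def test_counts_never_drop_below_one_and_n_bounded(self, outcomes, lam, vs, w):
        p = s.BeliefParams(lambda_acc=lam, varsigma=vs, w=w,
                           alpha0_min=1.0, alpha0_max=min(2.0, 1.0 + 1.0 / lam))
        state = init_beliefs(p, 2)
        n0 = p.n0
        for o in outcomes:
            state = decay_group_beliefs(state, p)
            delta = group_pe(state, 0, o)
            state = update_group_beliefs(state, 0, o)
            state = update_self_belief(state, delta, p)
            assert all(a >= 1.0 - 1e-12 for a in state.alpha)
            assert all(b >= 1.0 - 1e-12 for b in state.beta)
            assert state.alpha_s >= 1.0 - 1e-12
            assert state.beta_s >= 1.0 - 1e-12
            assert max(state.n) <= n0 + 1e-9


class TestSelfBelief:
    def test_single_step_hand_evaluation(self):
        # varsigma = 1, w = 1, delta = +0.75 from (1, 4): alpha_S -> 1.75
        p = s.BeliefParams(varsigma=1.0, w=1.0)
        state = s.BeliefState([1.0], [1.0], alpha_s=1.0, beta_s=4.0)
        out = update_self_belief(state, 0.75, p)
        assert out.alpha_s == pytest.approx(1.75)
        assert out.beta_s == pytest.approx(4.0)

    def test_zero_error_decays_toward_uniform(self):
        p = s.BeliefParams(varsigma=0.5, w=2.0)
        state = s.BeliefState([1.0], [1.0], alpha_s=3.0, beta_s=5.0)
        out = update_self_belief(state, 0.0, p)
        assert out.alpha_s == pytest.approx(2.0)
        assert out.beta_s == pytest.approx(3.0)

    def test_literal_printed_update_feeds_both_counts(self, monkeypatch):
        monkeypatch.setattr(config, "LITERAL_SELF_UPDATE", True)
        p = s.BeliefParams(varsigma=1.0, w=1.0)
        state = s.BeliefState([1.0], [1.0], alpha_s=1.0, beta_s=1.0)
        out = update_self_belief(state, 0.75, p)
        assert out.alpha_s == out.beta_s == pytest.approx(1.75)

    def test_momentum_symmetry(self, design20):
        """A run of approvals from a low-expectation group shifts alpha_S
        above beta_S; the mirrored disapproval run does the exact opposite
        when initial group beliefs are symmetric."""
        # symmetric initial group beliefs: alpha0 = n0/2 = 2 at lambda = 0.5
        p = s.BeliefParams(lambda_acc=0.5, alpha0_min=2.0, alpha0_max=2.0,
                           w=1.0, varsigma=0.9)

        def run(outcome):
            state = init_beliefs(p, 2)
            for _ in range(6):
                state = decay_group_beliefs(state, p)
                delta = group_pe(state, 0, outcome)
                state = update_group_beliefs(state, 0, outcome)
                state = update_self_belief(state, delta, p)
            return state

        up = run(1)
        down = run(0)
        assert up.alpha_s > up.beta_s
        assert down.beta_s > down.alpha_s
        assert up.alpha_s == pytest.approx(down.beta_s, abs=1e-12)
        assert up.beta_s == pytest.approx(down.alpha_s, abs=1e-12)


class TestChoiceRule:
    def test_indifference_point(self):
        p = s.BeliefParams(B_choice=0.0, T=0.2)
        state = s.BeliefState([2.0], [2.0])
        assert choice_prob_belief(state, 0, p) == pytest.approx(0.5)

    def test_closed_form(self):
        p = s.BeliefParams(B_choice=0.0, T=0.25)
        state = s.BeliefState([3.0], [1.0])  # G_acc = 0.75
        assert choice_prob_belief(state, 0, p) == pytest.approx(1 / (1 + exp(-1.0)))

    def test_monotone_in_expected_approval(self):
        p = s.BeliefParams(B_choice=0.0, T=0.2)
        probs = [choice_prob_belief(s.BeliefState([a], [4.0 - a]), 0, p)
                 for a in (1.0, 2.0, 3.0)]
        assert probs == sorted(probs)
        assert all(0 < q < 1 for q in probs)

    def test_literal_uncentred_rule(self, monkeypatch):
        monkeypatch.setattr(config, "LITERAL_CHOICE_RULE", True)
        p = s.BeliefParams(B_choice=0.0, T=0.25)
        state = s.BeliefState([2.0], [2.0])  # G_acc = 0.5
        assert choice_prob_belief(state, 0, p) == pytest.approx(1 / (1 + exp(-2.0)))


class TestReadout:
    def test_midpoint_condition(self):
        p = s.BeliefParams(B_se=1.0, m_se=3.0)
        assert se_readout(0.5, p) == pytest.approx(0.5)

    def test_identity_when_bias_and_sensitivity_unity(self):
        p = s.BeliefParams(B_se=1.0, m_se=1.0)
        for x in np.linspace(0.01, 0.99, 23):
            assert se_readout(x, p) == pytest.approx(x, abs=1e-12)
            assert inverse_readout(x, p) == pytest.approx(x, abs=1e-12)

    def test_sensitivity_limit_is_step(self):
        p = s.BeliefParams(B_se=1.0, m_se=400.0)
        assert se_readout(0.45, p) == pytest.approx(0.0, abs=1e-6)
        assert se_readout(0.55, p) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_arguments(self):
        base = s.BeliefParams(B_se=1.2, m_se=1.5)
        xs = np.linspace(0.05, 0.95, 15)
        ys = [se_readout(x, base) for x in xs]
        assert np.all(np.diff(ys) > 0)
        more_bias = dataclasses.replace(base, B_se=2.0)
        assert all(se_readout(x, more_bias) > se_readout(x, base) for x in xs)
        # above the midpoint, higher sensitivity pushes the readout up
        p_hi = dataclasses.replace(base, B_se=1.0, m_se=3.0)
        p_lo = dataclasses.replace(base, B_se=1.0, m_se=1.0)
        assert se_readout(0.8, p_hi) > se_readout(0.8, p_lo)


class TestRatingDensity:
    def test_identity_readout_reduces_to_beta_pdf(self):
        p = s.BeliefParams(B_se=1.0, m_se=1.0)
        for r in (0.1, 0.45, 0.9):
            got = se_rating_logdensity(r, 2.5, 4.0, p)
            assert got == pytest.approx(beta_dist.logpdf(r, 2.5, 4.0), abs=1e-10)

    def test_uniform_belief_identity_readout_is_flat(self):
        p = s.BeliefParams(B_se=1.0, m_se=1.0)
        for r in (0.2, 0.5, 0.8):
            assert se_rating_logdensity(r, 1.0, 1.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_density_integrates_to_one(self, rng):
        for _ in range(8):
            p = s.BeliefParams(B_se=rng.uniform(0.3, 3.0),
                               m_se=rng.uniform(0.5, 3.0))
            a = rng.uniform(1.0, 8.0)
            b = rng.uniform(1.0, 8.0)
            total, err = quad(
                lambda r: exp(se_rating_logdensity(r, a, b, p)),
                0.0, 1.0, limit=300, points=[1e-6, 0.5, 1 - 1e-6])
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_expected_se_identity_is_beta_mean(self):
        p = s.BeliefParams(B_se=1.0, m_se=1.0)
        assert expected_se(3.0, 6.0, p) == pytest.approx(1 / 3, abs=1e-9)

    def test_expected_se_symmetric_belief_is_half(self):
        for m in (0.5, 1.0, 4.0):
            p = s.BeliefParams(B_se=1.0, m_se=m)
            assert expected_se(3.5, 3.5, p) == pytest.approx(0.5, abs=1e-9)

    def test_expected_se_matches_monte_carlo(self, rng):
        p = s.BeliefParams(B_se=1.7, m_se=2.2)
        a, b = 2.0, 5.0
        draws = rng.beta(a, b, size=100_000)
        samples = np.array([se_readout(x, p) for x in draws])
        se_mc = samples.mean()
        tol = 3 * samples.std() / np.sqrt(samples.size)
        assert expected_se(a, b, p) == pytest.approx(se_mc, abs=tol)


class TestLikelihoodPaths:
    def test_vectorized_equals_trial_stepped(self, belief_record, rng):
        """The IIR-filter likelihood must agree with the stepped reference."""
        model = s.get_model("belief")
        for _ in range(10):
            p = s.BeliefParams(
                lambda_acc=rng.uniform(0.05, 0.9),
                alpha0_min=1.0, alpha0_max=1.5,
                w=rng.uniform(0.0, 4.0), varsigma=rng.uniform(0.2, 1.0),
                m_se=rng.uniform(0.5, 3.0), B_se=rng.uniform(0.3, 3.0),
                T=rng.uniform(0.05, 1.0), B_choice=rng.uniform(-0.5, 0.5))
            fast = model.loglik(p, belief_record)
            slow = model.loglik_slow(p, belief_record)
            assert fast[0] == pytest.approx(slow[0], abs=1e-9)
            assert fast[1] == pytest.approx(slow[1], abs=1e-9)
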