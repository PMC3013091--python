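"""Odds-ratio -> relative-risk conversion with diseased controls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from gci import (
    ConversionProblem,
    alpha_from_ages,
    estimate_alpha_mle,
    odds_ratios_from_penetrances,
    solve_penetrances,
)
from gci.or2rr import _penetrances_given_x0

from conftest import random_conversion_problem


class TestSolvePenetrances:
    def test_null_odds_ratios_give_flat_penetrance(self):
        sol = solve_penetrances(
            ConversionProblem((1.0, 1.0, 1.0), (0.2, 0.5, 0.3), 0.1, 0.05)
        )
        assert np.allclose(sol.p_d_given_level, 0.1, atol=1e-10)
        assert np.allclose(sol.rel_risks, 1.0, atol=1e-9)

    def test_rare_disease_limit_or_equals_rr(self):
        sol = solve_penetrances(
            ConversionProblem((1.0, 1.5, 2.25), (0.25, 0.5, 0.25), 1e-6, 0.0)
        )
        assert sol.rel_risks[1] == pytest.approx(1.5, rel=1e-3)
        assert sol.rel_risks[2] == pytest.approx(2.25, rel=1e-3)

    def test_matches_brute_force_grid_oracle(self):
        """Independent grid search over the baseline penetrance at step 1e-7."""
        prob = ConversionProblem((1.0, 1.5, 2.5), (0.25, 0.5, 0.25), 0.25, 0.25)
        ors = np.asarray(prob.odds_ratios)
        freqs = np.asarray(prob.freqs)
        grid = np.arange(1e-7, 0.25, 1e-7)
        sums = np.array(
            [freqs @ _penetrances_given_x0(g, ors, 0.25, 0.25) for g in grid[::100]]
        )
        x0_oracle = grid[::100][np.argmin(np.abs(sums - 0.25))]
        sol = solve_penetrances(prob)
        assert sol.p_d_given_level[0] == pytest.approx(x0_oracle, abs=2e-5)
        assert freqs @ sol.p_d_given_level == pytest.approx(0.25, abs=1e-9)

    def test_weighted_mean_penetrance_equals_altr(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            prob = random_conversion_problem(rng)
            sol = solve_penetrances(prob)
            assert np.asarray(prob.freqs) @ sol.p_d_given_level == pytest.approx(
                prob.altr, abs=1e-9
            )

    def test_alpha_zero_matches_classical_prevalence_conversion(self):
        """Closed-form biallelic oracle: OR = [x1/(1-x1)] / [x0/(1-x0)]."""
        or1, f, altr = 2.0, 0.3, 0.2

        def oracle(x0):
            x1 = or1 * x0 / (1 - x0 + or1 * x0)
            return (1 - f) * x0 + f * x1 - altr

        x0 = optimize.brentq(oracle, 1e-12, altr, xtol=1e-14)
        x1 = or1 * x0 / (1 - x0 + or1 * x0)
        sol = solve_penetrances(ConversionProblem((1.0, or1), (1 - f, f), altr, 0.0))
        assert sol.p_d_given_level[0] == pytest.approx(x0, abs=1e-10)
        assert sol.p_d_given_level[1] == pytest.approx(x1, abs=1e-10)

    def test_inconsistent_problem_raises_diagnostic(self):
        # with population controls (alpha = altr) the OR equals the lifetime
        # RR, so OR 10 at lifetime risk 0.9 would need a penetrance above 1
        with pytest.raises(ValueError, match="penetrance|inconsistent"):
            solve_penetrances(
                ConversionProblem((1.0, 10.0), (0.9, 0.1), 0.9, 0.9)
            )

    def test_constraint_function_monotone_on_random_problems(self):
        """The bisection target is strictly increasing in the baseline penetrance."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            prob = random_conversion_problem(rng)
            ors = np.asarray(prob.odds_ratios)
            freqs = np.asarray(prob.freqs)
            xs = np.linspace(prob.altr * 1e-4, prob.altr * 0.9999, 50)
            sums = np.array(
                [
                    freqs @ _penetrances_given_x0(x, ors, prob.altr, prob.alpha_controls)
                    for x in xs
                ]
            )
            assert np.all(np.diff(sums) > 0)


class TestForwardMap:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_or_to_rr_to_or(self, seed):
        rng = np.random.default_rng(seed)
        prob = random_conversion_problem(rng)
        sol = solve_penetrances(prob)
        back = odds_ratios_from_penetrances(
            sol, prob.freqs, prob.altr, prob.alpha_controls
        )
        assert np.allclose(back, prob.odds_ratios, atol=1e-8)

    def test_flat_relative_risks_give_unit_odds_ratios(self):
        sol = solve_penetrances(
            ConversionProblem((1.0, 1.0), (0.5, 0.5), 0.3, 0.1)
        )
        assert np.allclose(
            odds_ratios_from_penetrances(sol, (0.5, 0.5), 0.3, 0.1), 1.0
        )

    def test_contaminated_controls_attenuate_odds_ratios(self):
        """The same penetrances show milder ORs when controls include future cases."""
        prob = ConversionProblem((1.0, 1.5, 2.5), (0.25, 0.5, 0.25), 0.25, 0.25)
        sol = solve_penetrances(prob)
        or_clean = odds_ratios_from_penetrances(sol, prob.freqs, 0.25, 0.0)
        or_contam = odds_ratios_from_penetrances(sol, prob.freqs, 0.25, 0.25)
        for oc, ocont in zip(or_clean[1:], or_contam[1:]):
            assert abs(np.log(oc)) > abs(np.log(ocont))

    def test_rare_disease_convergence_of_rr_to_or(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = rng.integers(2, 5)
            ors = np.concatenate(([1.0], rng.uniform(1.0, 4.0, m - 1)))
            freqs = rng.dirichlet(np.ones(m))
            altr = 10 ** rng.uniform(-6, -3)
            sol = solve_penetrances(
                ConversionProblem(tuple(ors), tuple(freqs), float(altr), 0.0)
            )
            rel_dev = np.abs(np.asarray(sol.rel_risks) / ors - 1.0)
            assert rel_dev.max() < altr * 10


class TestAlphaEstimation:
    def test_mle_recovers_population_control_alpha(self):
        """Population controls (alpha = ALTR): alpha_hat falls in the 95% profile set."""
        rng = np.random.default_rng(7)
        altr, true_alpha = 0.25, 0.25
        freqs = np.array([0.25, 0.5, 0.25])
        x = altr / (freqs @ np.array([1.0, 1.5, 2.5])) * np.array([1.0, 1.5, 2.5])
        q1 = freqs * x / altr
        a, b = true_alpha / altr, (1 - true_alpha) / (1 - altr)
        c = b + (a - b) * x
        q0 = freqs * c / (freqs @ c)
        cases = rng.multinomial(50_000, q1)
        ctrls = rng.multinomial(50_000, q0)
        ahat, info = estimate_alpha_mle(cases, ctrls, freqs, altr)
        assert not info["degenerate"]
        lls = info["loglik"]
        in_ci = info["alphas"][lls >= lls.max() - 1.92]
        assert in_ci.min() - 1e-9 <= true_alpha <= in_ci.max() + 1e-9
        assert abs(ahat - true_alpha) <= in_ci.max() - in_ci.min() + 0.05 * altr

    def test_identical_arms_flagged_degenerate(self):
        ahat, info = estimate_alpha_mle(
            [10, 20, 10], [10, 20, 10], [0.25, 0.5, 0.25], 0.25
        )
        assert info["degenerate"]
        assert 0.0 <= ahat <= 0.25

    def test_estimate_never_leaves_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            prob = random_conversion_problem(rng)
            sol = solve_penetrances(prob)
            x = np.asarray(sol.p_d_given_level)
            f = np.asarray(prob.freqs)
            q1 = f * x / (f @ x)
            a, b = prob.alpha_controls / prob.altr, (1 - prob.alpha_controls) / (
                1 - prob.altr
            )
            c = b + (a - b) * x
            q0 = f * c / (f @ c)
            cases = rng.multinomial(5000, q1) + 1
            ctrls = rng.multinomial(5000, q0) + 1
            ahat, _ = estimate_alpha_mle(cases, ctrls, f, prob.altr)
            assert 0.0 <= ahat <= prob.altr


class TestAlphaFromAges:
    def test_very_old_controls_have_negligible_alpha(self):
        a = alpha_from_ages([100.0] * 50, 50.0, 13.0, 0.25)
        assert a <= 0.25 * 1e-4

    def test_newborn_controls_have_alpha_equal_altr(self):
        a = alpha_from_ages([0.0] * 50, 50.0, 13.0, 0.25)
        assert a == pytest.approx(0.25, rel=1e-3)

    def test_uniform_ages_match_quadrature_oracle(self):
        ages = np.linspace(0.0, 100.0, 200_001)
        a = alpha_from_ages(ages, 50.0, 13.0, 0.25)
        oracle = (
            0.25
            * integrate.quad(
                lambda t: stats.norm.sf(t, 50.0, 13.0) / 100.0, 0.0, 100.0
            )[0]
        )
        assert a == pytest.approx(oracle, abs=1e-5)

    def test_empty_age_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            alpha_from_ages([], 50.0, 13.0, 0.25)
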