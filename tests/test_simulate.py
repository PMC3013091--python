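"""Cohort simulators: genotype draws, status assignment, case-control design."""

import numpy as np
import pytest

from gci import (
    Cohort,
    DiseaseParams,
    Marker,
    alpha_from_ages,
    assign_status_interaction,
    assign_status_multiplicative,
    simulate_age_structured_casecontrol,
    simulate_genotypes,
    solve_interaction_lambdas,
    solve_lambdas_model2,
    solve_penetrances,
    ConversionProblem,
)
from gci.simulate import DEFAULT_BOOSTED_COMBOS


def _marker(mid, rrs, freqs):
    return Marker(mid, "genetic", ("NN", "RN", "RR"), rrs, freqs)


class TestSimulateGenotypes:
    def test_degenerate_frequencies(self):
        m = _marker("m", (1.0, 1.2, 1.4), (0.0, 0.0, 1.0))
        gm = simulate_genotypes([m], 500, seed=0)
        assert np.all(gm.values == 2)

    def test_empirical_frequencies_match_table(self, fixtures):
        markers, _dp = fixtures["crohns_table1"]
        n = 100_000
        gm = simulate_genotypes(markers, n, seed=5)
        for j, m in enumerate(markers):
            counts = np.bincount(gm.values[:, j], minlength=3) / n
            for lv in range(3):
                f = m.freqs[lv]
                se = np.sqrt(max(f * (1 - f), 1e-12) / n)
                assert abs(counts[lv] - f) < max(3 * se, 1e-9)

    def test_markers_sampled_independently(self, ra_markers):
        gm = simulate_genotypes(ra_markers, 100_000, seed=6)
        corr = np.corrcoef(gm.values.T)
        off_diag = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.02)

    def test_reproducible_under_seed(self, ra_markers):
        a = simulate_genotypes(ra_markers, 1000, seed=7)
        b = simulate_genotypes(ra_markers, 1000, seed=7)
        assert np.array_equal(a.values, b.values)


class TestMultiplicativeStatus:
    def test_null_panel_case_fraction(self):
        ms = (_marker("m", (1.0, 1.0, 1.0), (0.25, 0.5, 0.25)),)
        dp = DiseaseParams("x", 0.1, 0.5)
        gm = simulate_genotypes(ms, 100_000, seed=8)
        cohort = assign_status_multiplicative(Cohort(gm, ms), dp, seed=9)
        se = np.sqrt(0.1 * 0.9 / 100_000)
        assert abs(cohort.status.mean() - 0.1) < 3 * se

    def test_crohns_with_smoking_case_fraction(self, fixtures):
        gen, dp = fixtures["crohns_table1"]
        env, _ = fixtures["crohns_env"]
        markers = tuple(gen) + tuple(env)
        gm = simulate_genotypes(markers, 100_000, seed=10)
        cohort = assign_status_multiplicative(Cohort(gm, markers), dp, seed=11)
        se = np.sqrt(dp.altr * (1 - dp.altr) / 100_000)
        assert abs(cohort.status.mean() - dp.altr) < 3 * se

    def test_case_count_linear_in_altr(self, ra_markers):
        ms = tuple(ra_markers)
        gm = simulate_genotypes(ms, 200_000, seed=12)
        n1 = assign_status_multiplicative(
            Cohort(gm, ms), DiseaseParams("x", 0.02, 0.5), seed=13
        ).status.sum()
        n2 = assign_status_multiplicative(
            Cohort(gm, ms), DiseaseParams("x", 0.04, 0.5), seed=13
        ).status.sum()
        se = np.sqrt(2 * n2)
        assert abs(n2 - 2 * n1) < 4 * se


class TestInteractionModel:
    def test_gamma_one_returns_printed_marginals(self, ra_markers):
        dp = DiseaseParams("ra", 0.0154, 0.53)
        x, y = ra_markers[2], ra_markers[3]
        spec = solve_interaction_lambdas(x, y, 1.0, dp)
        assert np.allclose(spec.lambdas_x, x.rel_risks, atol=1e-9)
        assert np.allclose(spec.lambdas_y, y.rel_risks, atol=1e-9)

    @pytest.mark.parametrize("gamma", [2.0, 10.0])
    def test_marginals_match_by_nine_cell_enumeration(self, ra_markers, gamma):
        """Independent 9-cell recomputation of the marginal relative risks."""
        dp = DiseaseParams("ra", 0.0154, 0.53)
        x, y = ra_markers[2], ra_markers[3]
        spec = solve_interaction_lambdas(x, y, gamma, dp)
        fx, fy = np.asarray(x.freqs), np.asarray(y.freqs)
        w = np.zeros((3, 3))
        for gx in range(3):
            for gy in range(3):
                w[gx, gy] = spec.lambdas_x[gx] * spec.lambdas_y[gy]
                if (gx, gy) in spec.boosted_combos:
                    w[gx, gy] *= gamma
        marg_x = w @ fy
        marg_y = fx @ w
        assert np.allclose(marg_x / marg_x[0], x.rel_risks, atol=1e-6)
        assert np.allclose(marg_y / marg_y[0], y.rel_risks, atol=1e-6)

    def test_gamma_one_statuses_identical_to_multiplicative(self, ra_markers):
        ms = tuple(ra_markers)
        dp = DiseaseParams("ra", 0.0154, 0.53)
        spec = solve_interaction_lambdas(ms[2], ms[3], 1.0, dp)
        gm = simulate_genotypes(ms, 50_000, seed=14)
        c1 = assign_status_multiplicative(Cohort(gm, ms), dp, seed=15)
        gm2 = simulate_genotypes(ms, 50_000, seed=14)
        c2 = assign_status_interaction(Cohort(gm2, ms), spec, dp, seed=15)
        assert np.array_equal(c1.status, c2.status)

    def test_case_fraction_calibrated_at_gamma_ten(self, ra_markers):
        ms = tuple(ra_markers)
        dp = DiseaseParams("ra", 0.0154, 0.53)
        spec = solve_interaction_lambdas(ms[2], ms[3], 10.0, dp)
        gm = simulate_genotypes(ms, 100_000, seed=16)
        c = assign_status_interaction(Cohort(gm, ms), spec, dp, seed=17)
        se = np.sqrt(dp.altr * (1 - dp.altr) / 100_000)
        assert abs(c.status.mean() - dp.altr) < 3 * se

    def test_boosted_combos_exceed_multiplicative_prediction(self, t2d_markers):
        """Individuals with boosted genotype pairs are cases more often than
        the independence model predicts for the same genotypes."""
        from gci.riskmodel import cohort_scores

        ms = tuple(t2d_markers)
        dp = DiseaseParams("t2d", 0.25, 0.64)
        order = sorted(range(len(ms)), key=lambda j: ms[j].rel_risks[1], reverse=True)
        jx, jy = order[0], order[1]
        spec = solve_interaction_lambdas(ms[jx], ms[jy], 10.0, dp)
        gm = simulate_genotypes(ms, 100_000, seed=18)
        c = assign_status_interaction(Cohort(gm, ms), spec, dp, seed=19)
        gx = gm.values[:, jx]
        gy = gm.values[:, jy]
        boosted = np.array(
            [(a, b) in DEFAULT_BOOSTED_COMBOS for a, b in zip(gx, gy)]
        )
        mult_pred = cohort_scores(gm.values, ms, dp)
        assert c.status[boosted].mean() > mult_pred[boosted].mean()


@pytest.fixture(scope="module")
def model2():
    dp = DiseaseParams("t2d-like", 0.25, 0.64)
    return dp, solve_lambdas_model2([1.3, 1.15, 1.25], [0.3, 0.5, 0.2], dp)


class TestAgeStructuredCaseControl:

    def test_control_contamination_consistent_with_alpha_from_ages(self, model2):
        dp, spec = model2
        study = simulate_age_structured_casecontrol(spec, 4000, seed=20)
        contamination = study.control_lifetime_status.mean()
        # exact conditional rate: Pr(lifetime & pre-onset | control of age a)
        from scipy import stats as st

        sf = st.norm.sf(study.control_ages, 50.0, 13.0)
        cdf = 1.0 - sf
        expected = np.mean(dp.altr * sf / (1 - dp.altr * cdf))
        se = np.sqrt(expected * (1 - expected) / len(study.control_ages))
        assert abs(contamination - expected) < 3 * se
        # the unconditional approximation used for the OR correction is close
        approx = alpha_from_ages(study.control_ages, 50.0, 13.0, dp.altr)
        assert approx == pytest.approx(expected, rel=0.15)

    def test_everyone_old_means_no_contamination(self, model2):
        _dp, spec = model2
        study = simulate_age_structured_casecontrol(
            spec, 500, seed=22, age_range=(100.0, 100.0)
        )
        assert study.control_lifetime_status.sum() == 0

    def test_controls_matched_on_integer_age(self, model2):
        _dp, spec = model2
        study = simulate_age_structured_casecontrol(spec, 1000, seed=23)
        assert len(study.control_ages) == 1000
        assert np.array_equal(
            np.sort(study.case_ages.astype(int)),
            np.sort(study.control_ages.astype(int)),
        )

    def test_end_to_end_or_conversion_recovers_heterozygote_rr(self, model2):
        """Estimated ORs, corrected with the age-implied alpha, recover the
        model's heterozygote relative risks within sampling error."""
        dp, spec = model2
        targets = [1.3, 1.15, 1.25]
        devs = []
        for seed in (24, 25, 26):
            study = simulate_age_structured_casecontrol(spec, 10_000, seed=seed)
            alpha = alpha_from_ages(study.control_ages, 50.0, 13.0, dp.altr)
            p = np.asarray(spec.allele_freqs)
            for j, t in enumerate(targets):
                freqs = ((1 - p[j]) ** 2, 2 * p[j] * (1 - p[j]), p[j] ** 2)
                sol = solve_penetrances(
                    ConversionProblem(
                        (1.0, study.odds_ratios[j, 1], study.odds_ratios[j, 2]),
                        freqs,
                        dp.altr,
                        alpha,
                    )
                )
                devs.append(sol.rel_risks[1] - t)
        devs = np.asarray(devs)
        # unbiased within sampling noise: each |dev| modest, mean near zero
        assert np.abs(devs).max() < 0.08
        assert abs(devs.mean()) < 0.03
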