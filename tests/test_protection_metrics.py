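"""The protective index, its credible intervals, and ordering probabilities."""

import math

import numpy as np
import pytest
from scipy import stats

from spiroprotect.experiment_data import Treatment, VialOutcome, WaspStrain
from spiroprotect.protection_metrics import (
    FecunditySummary,
    GroupSummary,
    MissingCountsError,
    NoControlError,
    PriorSpec,
    ProtectionComponents,
    UndefinedPIError,
    UndefinedSummaryError,
    build_components,
    components_from_summaries,
    compute_pi,
    percent_change,
    pi_posterior,
    pi_survival_bound,
    posterior_ordering,
    reconstruct_counts,
    reference_components,
    summarize_proportion,
)
from spiroprotect.synthetic_experiment import (
    ExperimentDesign,
    default_params,
    generate_fertility,
    generate_vials,
)

FR, MAD = WaspStrain.LH_FR, WaspStrain.LH_MAD


class TestProportionSummaries:
    def test_clopper_pearson_matches_beta_quantiles_for_all_n_up_to_500(self):
        ks, ns = [], []
        for n in range(1, 501):
            for k in range(0, n + 1):
                ks.append(k)
                ns.append(n)
        k = np.array(ks)
        n = np.array(ns)
        # beta-quantile closed form, boundary cases exact
        with np.errstate(invalid="ignore"):
            low = np.where(k == 0, 0.0, stats.beta.ppf(0.025, k, n - k + 1))
            high = np.where(k == n, 1.0, stats.beta.ppf(0.975, k + 1, n - k))
        # vectorized call through the same statsmodels route the package uses
        from statsmodels.stats.proportion import proportion_confint

        got_low, got_high = proportion_confint(k, n, alpha=0.05, method="beta")
        got_low = np.nan_to_num(np.asarray(got_low, dtype=float), nan=0.0)
        got_high = np.asarray(got_high, dtype=float)
        got_high[np.isnan(got_high)] = 1.0
        assert np.max(np.abs(got_low - low)) < 1e-10
        assert np.max(np.abs(got_high - high)) < 1e-10

    def test_single_summary_matches_beta_oracle(self):
        s = summarize_proportion(25, 45)
        assert s.ci_low == pytest.approx(stats.beta.ppf(0.025, 25, 21), abs=1e-12)
        assert s.ci_high == pytest.approx(stats.beta.ppf(0.975, 26, 20), abs=1e-12)

    @pytest.mark.parametrize(
        "k,n,check",
        [
            (0, 20, lambda s: s.proportion == 0 and s.ci_low == 0),
            (20, 20, lambda s: s.ci_high == 1),
        ],
    )
    def test_boundary_cases(self, k, n, check):
        assert check(summarize_proportion(k, n))

    def test_wilson_alternative(self):
        s = summarize_proportion(25, 45, method="wilson")
        assert s.method == "wilson" and s.ci_low < 25 / 45 < s.ci_high

    def test_empty_group_is_undefined(self):
        with pytest.raises(UndefinedSummaryError):
            summarize_proportion(0, 0)


class TestComputePI:
    @pytest.mark.parametrize(
        "exposed,unexposed,percent",
        [
            ((0.42, 0.56, 10.9), (0.81, 0.97, 15.6), 21),
            ((0.40, 0.40, 5.45), (0.75, 0.95, 13.7), 9),
            ((0.33, 0.34, 9.98), (0.80, 1.00, 19.2), 7),
            ((0.33, 0.60, 6.38), (0.80, 0.95, 14.2), 12),
        ],
    )
    def test_worked_examples_to_nearest_percent(self, exposed, unexposed, percent):
        pi = compute_pi(components_from_summaries(exposed, unexposed))
        assert round(100 * pi) == percent

    def test_identical_sides_give_unity(self):
        c = components_from_summaries((0.5, 0.6, 12.0), (0.5, 0.6, 12.0))
        assert compute_pi(c) == pytest.approx(1.0)

    def test_scale_invariance_in_fecundity(self):
        for c_scale in (0.1, 3.0, 17.0):
            a = components_from_summaries((0.4, 0.5, 10.0), (0.8, 0.9, 15.0))
            b = components_from_summaries(
                (0.4, 0.5, 10.0 * c_scale), (0.8, 0.9, 15.0 * c_scale)
            )
            assert compute_pi(a) == pytest.approx(compute_pi(b))

    def test_monotone_in_each_component(self):
        base = compute_pi(components_from_summaries((0.4, 0.5, 10.0), (0.8, 0.9, 15.0)))
        up = compute_pi(components_from_summaries((0.45, 0.5, 10.0), (0.8, 0.9, 15.0)))
        down = compute_pi(components_from_summaries((0.4, 0.5, 10.0), (0.85, 0.9, 15.0)))
        assert up > base > down

    def test_zero_denominator_names_component(self):
        c = components_from_summaries((0.4, 0.5, 10.0), (0.8, 0.0, 15.0))
        with pytest.raises(UndefinedPIError, match="unexposed_fertile"):
            compute_pi(c)


class TestSurvivalBound:
    def test_ratio_convention(self):
        c = components_from_summaries((0.05, None, None), (0.72, None, None))
        b = pi_survival_bound(c)
        assert b.is_bound and b.value == pytest.approx(0.05 / 0.72)

    def test_product_convention_available(self):
        c = components_from_summaries((0.05, None, None), (0.72, None, None))
        assert pi_survival_bound(c, convention="product").value == pytest.approx(0.036)

    def test_zero_exposed_gives_zero_bound(self):
        c = components_from_summaries((0.0, None, None), (0.72, None, None))
        assert pi_survival_bound(c).value == 0.0

    def test_equal_survival_gives_unit_bound(self):
        c = components_from_summaries((0.72, None, None), (0.72, None, None))
        assert pi_survival_bound(c).value == pytest.approx(1.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,cmp,expected", [(17.5, 10.6, 39), (14.0, 8.35, 40), (3.3, 3.3, 0)]
    )
    def test_reductions(self, ref, cmp, expected):
        assert round(percent_change(ref, cmp)) == expected

    def test_zero_reference_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


def big_components(factor=1_000_000):
    return ProtectionComponents(
        exposed_survival=summarize_proportion(42 * factor, 100 * factor),
        unexposed_survival=summarize_proportion(81 * factor, 100 * factor),
        exposed_fertile=summarize_proportion(56 * factor, 100 * factor),
        unexposed_fertile=summarize_proportion(97 * factor, 100 * factor),
        exposed_fecundity=FecunditySummary(45, 10.9, 0.0),
        unexposed_fecundity=FecunditySummary(37, 15.6, 0.0),
    )


class TestPIPosterior:
    def test_degenerate_posterior_collapses_onto_point(self):
        res = pi_posterior(big_components(), n_draws=20_000, seed=0)
        assert res.ci_high - res.ci_low < 1e-3
        assert res.ci_low < res.point < res.ci_high

    def test_same_seed_bit_reproducible(self):
        c = reference_components(FR, 0)
        a = pi_posterior(c, n_draws=5000, seed=42)
        b = pi_posterior(c, n_draws=5000, seed=42)
        assert np.array_equal(a.draws, b.draws)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_across_seeds_endpoints_vary_at_monte_carlo_rate(self):
        c = reference_components(FR, 0)
        los = [pi_posterior(c, n_draws=40_000, seed=s).ci_low for s in range(5)]
        assert np.std(los) < 0.01  # O(1/sqrt(n_draws))

    def test_interval_agrees_with_log_delta_method_at_large_counts(self):
        c = big_components(factor=100)  # n = 10^4 larvae, fecundity se ~ 0
        c = ProtectionComponents(
            exposed_survival=c.exposed_survival,
            unexposed_survival=c.unexposed_survival,
            exposed_fertile=c.exposed_fertile,
            unexposed_fertile=c.unexposed_fertile,
            exposed_fecundity=FecunditySummary(4500, 10.9, 0.05),
            unexposed_fecundity=FecunditySummary(3700, 15.6, 0.04),
        )
        res = pi_posterior(c, n_draws=100_000, seed=3)
        var_log = 0.0
        for g in (c.exposed_survival, c.unexposed_survival,
                  c.exposed_fertile, c.unexposed_fertile):
            var_log += (1 - g.proportion) / (g.proportion * g.n_total)
        for f in (c.exposed_fecundity, c.unexposed_fecundity):
            var_log += (f.se / f.mean) ** 2
        point = compute_pi(c)
        lo = point * math.exp(-1.96 * math.sqrt(var_log))
        hi = point * math.exp(1.96 * math.sqrt(var_log))
        width = hi - lo
        assert abs(res.ci_low - lo) < 0.2 * width
        assert abs(res.ci_high - hi) < 0.2 * width

    def test_small_draw_count_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            pi_posterior(big_components(), n_draws=500, seed=0)

    def test_missing_fertility_requires_bound_mode(self):
        c = components_from_summaries((0.05, None, None), (0.72, None, None))
        with pytest.raises(MissingCountsError, match="pi_survival_bound"):
            pi_posterior(c)


class TestPosteriorOrdering:
    def _result(self, draws, seed=0):
        from spiroprotect.protection_metrics import ProtectionIndexResult

        return ProtectionIndexResult(
            point=float(np.mean(draws)), ci_low=0, ci_high=1,
            n_draws=len(draws), seed=seed, priors=PriorSpec(),
            draws=np.asarray(draws, dtype=float),
        )

    def test_identical_draws_tie_to_half(self):
        d = np.linspace(0.1, 0.9, 1000)
        assert posterior_ordering(self._result(d), self._result(d)).p_greater == 0.5

    def test_disjoint_draws_give_unity(self):
        a = self._result(np.full(100, 2.0))
        b = self._result(np.full(100, 1.0))
        assert posterior_ordering(a, b).p_greater == 1.0

    def test_complementarity_is_exact(self):
        rng = np.random.default_rng(1)
        a = self._result(rng.normal(1.0, 0.1, 5000))
        b = self._result(rng.normal(0.95, 0.1, 5000))
        assert (
            posterior_ordering(a, b).p_greater + posterior_ordering(b, a).p_greater
            == 1.0
        )

    def test_matches_closed_form_normal_ordering(self):
        rng = np.random.default_rng(7)
        n = 200_000
        a = self._result(rng.normal(1.0, 0.1, n))
        b = self._result(rng.normal(0.8, 0.1, n))
        expected = stats.norm.cdf(0.2 / math.sqrt(0.02))  # ~0.921
        got = posterior_ordering(a, b).p_greater
        assert abs(got - expected) < 3 * math.sqrt(expected * (1 - expected) / n)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            posterior_ordering(self._result(np.ones(10)), self._result(np.ones(11)))


class TestBuildComponents:
    def test_single_vial_arithmetic(self):
        t_exp = Treatment(FR, True, 0)
        t_un = Treatment(WaspStrain.NONE, True, 0)
        vials = [
            VialOutcome("v1", t_exp, 30, 20, 12, 0),
            VialOutcome("c1", t_un, 30, 28, 24, 0, block="LH_FR"),
        ]
        c = build_components(vials, [], FR, 0)
        assert c.exposed_survival.proportion == pytest.approx(0.40)
        assert not c.complete  # no fertility table -> bound mode

    def test_no_control_rows_is_an_error(self):
        t_exp = Treatment(FR, True, 0)
        with pytest.raises(NoControlError):
            build_components([VialOutcome("v1", t_exp, 30, 20, 12, 0)], [], FR, 0)

    def test_generator_round_trip_recovers_configured_truth(self, params):
        d = ExperimentDesign(n_vials_per_treatment=400, n_females_fertility=800, seed=5)
        vials = generate_vials(d, params)
        fert = generate_fertility(d, params)
        c = build_components(vials, fert, FR, 0)
        n = c.exposed_survival.n_total
        assert abs(c.exposed_survival.proportion - 0.42) < 3 * math.sqrt(0.42 * 0.58 / n)
        nf = c.exposed_fertile.n_total
        assert abs(c.exposed_fertile.proportion - 0.56) < 3 * math.sqrt(0.56 * 0.44 / nf)
        assert abs(c.exposed_fecundity.mean - 10.9) < 3 * c.exposed_fecundity.se + 0.2


class TestReconstruction:
    def test_reconstructed_fraction_matches_printed_proportion(self):
        k, n = reconstruct_counts(0.42, 450)
        assert k / n == pytest.approx(0.42, abs=1e-9)
        k, n = reconstruct_counts(0.97, 45)
        assert abs(k / n - 0.97) < 0.005

    def test_reference_interval_near_published_for_default_priors(self):
        res = pi_posterior(reference_components(FR, 0), n_draws=100_000, seed=1)
        assert abs(res.ci_low - 0.12) <= 0.04
        assert abs(res.ci_high - 0.33) <= 0.04

    def test_ordering_exceeds_point_nine_across_sensitivity_grid(self):
        # robustness of the strain ordering to prior and reconstructed-n choices
        for prior in (PriorSpec(1, 1), PriorSpec.jeffreys()):
            for n_larvae in (300, 500):
                for n_females in (35, 50):
                    a = pi_posterior(
                        reference_components(FR, 0, n_larvae, n_females),
                        priors=prior, n_draws=20_000, seed=11,
                    )
                    b = pi_posterior(
                        reference_components(MAD, 0, n_larvae, n_females),
                        priors=prior, n_draws=20_000, seed=12,
                    )
                    assert posterior_ordering(a, b).p_greater > 0.9
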