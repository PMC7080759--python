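"""GLM term tests, stepwise simplification, separation-robust logistic, Box-Cox."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from spiroprotect.inferential_models import (
    ModelSpec,
    boxcox_lambda,
    fit_glm,
    fit_penalized_logistic,
    parse_formula,
    stepwise_simplify,
    term_tests,
)


def binom_frame(groups, rng=None):
    """Vial-level binomial data: groups = {label cols -> (n_vials, n, p)}."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for labels, (n_vials, n, p) in groups.items():
        k = rng.binomial(n, p, size=n_vials)
        for ki in k:
            rows.append({**dict(labels), "succ": int(ki), "tot": n})
    return pd.DataFrame(rows)


class TestFitGlm:
    def test_null_effect_coefficient_near_zero(self):
        df = pd.DataFrame(
            {"g": ["a"] * 5 + ["b"] * 5, "succ": [12] * 10, "tot": [30] * 10}
        )
        fit = fit_glm(df, ModelSpec(("succ", "tot"), "binomial", ("g",)))
        assert fit.converged
        assert abs(fit.coefficients["C(g)[T.b]"]) < 1e-8

    def test_saturated_2x2_lrt_equals_g_statistic(self):
        # one vial per cell: the single-factor model vs intercept is the G-test
        df = pd.DataFrame(
            {"g": ["a", "b"], "succ": [20, 9], "tot": [30, 30]}
        )
        (test,) = term_tests(df, ModelSpec(("succ", "tot"), "binomial", ("g",)))
        # closed-form G = 2 sum O ln(O/E) over the 2x2 success/failure table
        obs = np.array([[20, 10], [9, 21]], dtype=float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row * col / obs.sum()
        g = 2 * np.sum(obs * np.log(obs / exp))
        assert test.statistic == pytest.approx(g, abs=1e-8)
        assert test.df == 1

    def test_poisson_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        spec = ModelSpec("y", "poisson", ("strain",))
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "strain": np.repeat(["a", "b", "c"], 50),
                    "y": rng.poisson(1.4, 150),
                }
            )
            pvals.append(term_tests(df, spec)[0].p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_gaussian_single_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b"], 25),
                "y": np.concatenate([rng.normal(0, 1, 25), rng.normal(0.7, 1, 25)]),
            }
        )
        (test,) = term_tests(df, ModelSpec("y", "gaussian", ("g",)))
        t = stats.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"], equal_var=True)
        assert test.statistic_kind == "F"
        assert test.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert test.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_lrt_invariant_to_level_relabelling(self):
        rng = np.random.default_rng(4)
        df = binom_frame(
            {
                (("g", "a"),): (8, 30, 0.3),
                (("g", "b"),): (8, 30, 0.6),
            },
            rng,
        )
        (t1,) = term_tests(df, ModelSpec(("succ", "tot"), "binomial", ("g",)))
        df2 = df.assign(g=df.g.map({"a": "zzz", "b": "aaa"}))
        (t2,) = term_tests(df2, ModelSpec(("succ", "tot"), "binomial", ("g",)))
        assert t1.statistic == pytest.approx(t2.statistic, abs=1e-8)


class TestFormulaParsing:
    def test_star_expands_to_all_subterms(self):
        spec = parse_formula("succ/tot ~ a * b", "binomial")
        assert set(spec.terms) == {("a",), ("b",), ("a", "b")}

    def test_explicit_interaction_and_main(self):
        spec = parse_formula("y ~ a + b + a:b", "gaussian")
        assert set(spec.terms) == {("a",), ("b",), ("a", "b")}

    def test_undeclared_interaction_factor_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            ModelSpec("y", "gaussian", ("a",), (("a", "b"),))


class TestStepwise:
    def test_main_effects_only_truth_drops_interactions(self):
        spec = ModelSpec(
            ("succ", "tot"), "binomial", ("a", "b"), (("a", "b"),)
        )
        clean = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            groups = {}
            for a, pa in (("x", 0.0), ("y", 1.0)):
                for b, pb in (("u", 0.0), ("v", 0.8)):
                    p = 1 / (1 + math.exp(-(-1.2 + pa + pb)))
                    groups[(("a", a), ("b", b))] = (15, 30, p)
            df = binom_frame(groups, rng)
            minimal, dropped = stepwise_simplify(df, spec)
            if set(minimal.terms) == {("a",), ("b",)}:
                clean += 1
        assert clean >= 9  # main effects retained, interaction dropped

    def test_all_null_reaches_intercept_only_in_most_replicates(self):
        spec = ModelSpec(("succ", "tot"), "binomial", ("a", "b"), (("a", "b"),))
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            groups = {
                (("a", a), ("b", b)): (10, 30, 0.4)
                for a in "xy" for b in "uv"
            }
            minimal, _ = stepwise_simplify(binom_frame(groups, rng), spec)
            if not minimal.terms:
                empty += 1
        assert empty >= 12  # ~0.95^3 of replicates expected

    def test_significant_three_way_interaction_blocks_all_removal(self):
        rng = np.random.default_rng(5)
        groups = {}
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    p = 0.8 if (a ^ b ^ c) else 0.2  # pure three-way structure
                    groups[(("a", f"a{a}"), ("b", f"b{b}"), ("c", f"c{c}"))] = (12, 30, p)
        df = binom_frame(groups, rng)
        spec = parse_formula("succ/tot ~ a * b * c", "binomial")
        minimal, dropped = stepwise_simplify(df, spec)
        assert minimal.terms == spec.terms and dropped == []

    def test_marginality_never_tests_main_under_its_interaction(self):
        # the comparison for a main effect must exclude interactions that
        # contain it from both fitted models, so the test statistic for 'a'
        # is identical whether or not a:b is declared
        rng = np.random.default_rng(6)
        groups = {
            (("a", a), ("b", b)): (10, 30, 0.3 + 0.3 * (a == "y"))
            for a in "xy" for b in "uv"
        }
        df = binom_frame(groups, rng)
        with_int = term_tests(df, parse_formula("succ/tot ~ a * b", "binomial"))
        without = term_tests(df, parse_formula("succ/tot ~ a + b", "binomial"))
        stat_a_with = next(t for t in with_int if t.term == "a").statistic
        stat_a_without = next(t for t in without if t.term == "a").statistic
        assert stat_a_with == pytest.approx(stat_a_without, abs=1e-8)


def separated_frame():
    """Complete separation: symbiont-positive vials have zero wasp emergence."""
    rng = np.random.default_rng(7)
    rows = []
    for spiro in (False, True):
        for _ in range(20):
            k = 0 if spiro else int(rng.binomial(30, 0.6))
            rows.append({"spiro": spiro, "succ": k, "tot": 30})
    return pd.DataFrame(rows)


class TestPenalizedLogistic:
    spec = ModelSpec(("succ", "tot"), "binomial", ("spiro",))

    def test_separation_gives_finite_map_while_mle_diverges(self):
        df = separated_frame()
        pen = fit_penalized_logistic(df, self.spec)
        coef = pen.coefficients["C(spiro)[T.True]"]
        assert np.isfinite(coef) and abs(coef) < 15
        mle_lo = fit_glm(df, self.spec, maxiter=8)
        mle_hi = fit_glm(df, self.spec, maxiter=20)
        c_lo = abs(mle_lo.coefficients["C(spiro)[T.True]"])
        c_hi = abs(mle_hi.coefficients["C(spiro)[T.True]"])
        assert c_hi > c_lo > abs(coef)  # grows with the iteration cap

    def test_map_matches_profile_grid_oracle(self):
        df = separated_frame()
        pen = fit_penalized_logistic(df, self.spec)
        theta = pen.diagnostics["coefficients_standardized"]
        x = df.spiro.to_numpy(float)
        xc = x - x.mean()
        y = (df.succ / df.tot).to_numpy()
        w = df.tot.to_numpy(float)

        def neg_log_post(a, b):
            eta = a + b * xc
            ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
            lp = stats.cauchy.logpdf(a, scale=10) + stats.cauchy.logpdf(b, scale=2.5)
            return -(ll + lp)

        # 1-D grid over the slope, profiling the intercept per grid point
        grid = np.arange(-15.0, 0.0, 0.01)
        profile = [
            optimize.minimize_scalar(
                lambda a, bb=b: neg_log_post(a, bb), bounds=(-10, 10), method="bounded"
            ).fun
            for b in grid
        ]
        b_hat = grid[int(np.argmin(profile))]
        assert theta["C(spiro)[T.True]"] == pytest.approx(b_hat, abs=0.02)

    def test_start_independent_to_1e6(self):
        df = separated_frame()
        a = fit_penalized_logistic(df, self.spec, n_starts=5, seed=1)
        b = fit_penalized_logistic(df, self.spec, n_starts=5, seed=2)
        assert a.diagnostics["start_spread"] < 1e-6
        for k in a.coefficients:
            assert a.coefficients[k] == pytest.approx(b.coefficients[k], abs=1e-6)

    def test_shrinks_toward_zero_without_effect(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "spiro": [False] * 10 + [True] * 10,
                "succ": rng.binomial(30, 0.5, 20),
                "tot": 30,
            }
        )
        pen = fit_penalized_logistic(df, self.spec)
        mle = fit_glm(df, self.spec)
        assert abs(pen.coefficients["C(spiro)[T.True]"]) <= abs(
            mle.coefficients["C(spiro)[T.True]"]
        )

    def test_prior_washes_out_at_large_n(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "spiro": [False] * 50 + [True] * 50,
                "succ": np.concatenate(
                    [rng.binomial(200, 0.4, 50), rng.binomial(200, 0.6, 50)]
                ),
                "tot": 200,
            }
        )
        pen = fit_penalized_logistic(df, self.spec)
        mle = fit_glm(df, self.spec)
        c_pen = pen.coefficients["C(spiro)[T.True]"]
        c_mle = mle.coefficients["C(spiro)[T.True]"]
        assert abs(c_pen - c_mle) / abs(c_mle) < 0.02

    def test_requires_binomial_family(self):
        with pytest.raises(ValueError):
            fit_penalized_logistic(pd.DataFrame(), ModelSpec("y", "gaussian", ("a",)))


class TestBoxCox:
    def test_normal_sample_estimates_identity(self):
        rng = np.random.default_rng(10)
        lam, _ = boxcox_lambda(rng.normal(20, 2, 10_000))
        assert abs(lam - 1.0) < 0.25

    def test_lognormal_sample_estimates_log(self):
        rng = np.random.default_rng(11)
        lam, y = boxcox_lambda(np.exp(rng.normal(0, 0.6, 10_000)))
        assert abs(lam) < 0.05

    def test_lambda_one_is_shift_by_one(self):
        x = np.array([1.0, 2.5, 7.0])
        _, y = boxcox_lambda(x, grid=(1.0, 1.0, 1.0))
        assert np.allclose(y, x - 1.0)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            boxcox_lambda(np.array([1.0, 0.0, 2.0]))
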