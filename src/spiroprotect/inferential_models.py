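"""Factorial GLMs, analysis of deviance, stepwise simplification, and
separation-robust logistic regression.

Responses from the assay tables are modelled with the families a field
ecologist would pick: vial-level binomial for fly or wasp survival
(successes/totals, likelihood-identical to per-larva rows), Poisson for
oviposition counts, Gaussian linear models for daughter numbers and
(Box-Cox transformed) wing areas.

Term tests are marginality-respecting (Type II) likelihood-ratio tests: a
term is tested by comparing the model holding every term that does not
contain it, with and without the term, so a main effect is never removed
while its interaction remains in the fitted pair.  Gaussian models use F
tests with the full model's residual mean deviance in the denominator;
binomial/Poisson models use chi-square on the deviance difference.

Stepwise simplification repeatedly deletes the least-significant removable
term above the alpha threshold (highest-order terms become removable first
through the marginality rule), with an alphabetical tie-break so the path
is deterministic.

Complete separation (e.g. zero wasp emergence in every symbiont-positive
cell) makes unpenalized logistic maximum-likelihood estimates infinite;
``fit_penalized_logistic`` returns the maximum a-posteriori fit under
independent Cauchy priors on standardized coefficients (scale 2.5, 10 on
the intercept), which is finite under any separation pattern.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.genmod.families import Binomial, Gaussian, Poisson
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "ModelTermTest",
    "FitResult",
    "parse_formula",
    "fit_glm",
    "term_tests",
    "stepwise_simplify",
    "fit_penalized_logistic",
    "boxcox_lambda",
]

Family = Literal["binomial", "poisson", "gaussian"]

_FAMILIES = {"binomial": Binomial, "poisson": Poisson, "gaussian": Gaussian}


@dataclass(frozen=True)
class ModelSpec:
    """A factorial model: response, family, factors and interactions.

    ``response`` is a column name, or a ``(successes, totals)`` column pair
    for the binomial family.  ``factors`` are categorical predictors;
    ``interactions`` are tuples of declared factors.
    """

    response: str | tuple[str, str]
    family: Family
    factors: tuple[str, ...]
    interactions: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not (
            isinstance(self.response, tuple) and len(self.response) == 2
        ):
            raise ValueError("binomial response must be a (successes, totals) pair")
        object.__setattr__(self, "factors", tuple(self.factors))
        inter = tuple(tuple(i) for i in self.interactions)
        for term in inter:
            unknown = set(term) - set(self.factors)
            if unknown:
                raise ValueError(f"interaction {term} uses undeclared factor(s) {unknown}")
            if len(term) < 2 or len(set(term)) != len(term):
                raise ValueError(f"malformed interaction {term}")
        object.__setattr__(self, "interactions", inter)

    @property
    def terms(self) -> list[tuple[str, ...]]:
        """All model terms: main effects then interactions, canonical order."""
        mains = [(f,) for f in sorted(self.factors)]
        inters = sorted(self.interactions, key=lambda t: (len(t), t))
        return mains + [tuple(sorted(t)) for t in inters]

    def with_terms(self, terms: Sequence[tuple[str, ...]]) -> "ModelSpec":
        factors = tuple(sorted({f for t in terms for f in t}))
        interactions = tuple(t for t in terms if len(t) > 1)
        return replace(self, factors=factors, interactions=interactions)


def term_label(term: tuple[str, ...]) -> str:
    return ":".join(term)


def parse_formula(formula: str, family: Family) -> ModelSpec:
    """Parse a minimal model formula such as ``"n_flies/n_larvae ~ a * b + c"``.

    ``*`` expands to all sub-terms (``a*b`` gives ``a``, ``b`` and ``a:b``);
    ``:`` names a single interaction; ``+`` separates chunks.  A binomial
    response is written ``successes/totals``.
    """
    lhs, _, rhs = formula.partition("~")
    if not rhs:
        raise ValueError(f"formula {formula!r} lacks '~'")
    lhs = lhs.strip()
    response: str | tuple[str, str]
    if family == "binomial":
        num, _, den = lhs.partition("/")
        if not den:
            raise ValueError("binomial formula response must be 'successes/totals'")
        response = (num.strip(), den.strip())
    else:
        response = lhs
    terms: set[tuple[str, ...]] = set()
    for chunk in rhs.split("+"):
        chunk = chunk.strip()
        if not chunk or chunk == "1":
            continue
        if "*" in chunk:
            factors = [f.strip() for f in chunk.split("*")]
            for r in range(1, len(factors) + 1):
                for combo in itertools.combinations(factors, r):
                    terms.add(tuple(sorted(combo)))
        elif ":" in chunk:
            terms.add(tuple(sorted(f.strip() for f in chunk.split(":"))))
        else:
            terms.add((chunk,))
    factors = tuple(sorted({f for t in terms for f in t}))
    interactions = tuple(sorted((t for t in terms if len(t) > 1), key=lambda t: (len(t), t)))
    return ModelSpec(response=response, family=family, factors=factors, interactions=interactions)


@dataclass(frozen=True)
class ModelTermTest:
    """One term's analysis-of-deviance test.

    ``df`` is the numerator df for chi-square tests, or a (numerator,
    denominator) pair for F tests.  ``testable`` is False for aliased terms
    (zero df), whose statistic and p-value are NaN.
    """

    term: str
    statistic_kind: Literal["chi_square", "F"]
    statistic: float
    df: int | tuple[int, int]
    p_value: float
    testable: bool = True


@dataclass(frozen=True)
class FitResult:
    """A fitted model: coefficients, deviance and convergence status."""

    coefficients: dict[str, float]
    deviance: float
    df_residual: int
    converged: bool
    penalized: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)
    _sm_result: object = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# model construction


def _rhs(terms: Sequence[tuple[str, ...]]) -> str:
    if not terms:
        return "1"
    return " + ".join(":".join(f"C({f})" for f in t) for t in terms)


def _prepare(data: pd.DataFrame, spec: ModelSpec):
    df = data.copy()
    if spec.family == "binomial":
        succ, tot = spec.response
        if (df[tot] <= 0).any():
            raise ValueError(f"column {tot!r} must be positive")
        df["_prop"] = df[succ] / df[tot]
        return df, "_prop", np.asarray(df[tot], dtype=float)
    return df, str(spec.response), None


def _fit_terms(
    data: pd.DataFrame, spec: ModelSpec, terms: Sequence[tuple[str, ...]],
    maxiter: int = 100,
):
    df, response, weights = _prepare(data, spec)
    formula = f"{response} ~ {_rhs(terms)}"
    family = _FAMILIES[spec.family]()
    kwargs = {} if weights is None else {"var_weights": weights}
    model = smf.glm(formula, data=df, family=family, **kwargs)
    return model.fit(maxiter=maxiter)


def fit_glm(data: pd.DataFrame, spec: ModelSpec, maxiter: int = 100) -> FitResult:
    """Maximum-likelihood GLM fit (IRLS) of the full model in ``spec``.

    Binomial responses are modelled at vial level as proportions with the
    vial totals as variance weights, which matches the counts likelihood.
    Non-convergence is reported through ``converged``, never silently.
    ``maxiter`` caps the IRLS iterations; under complete separation the
    estimates grow without bound as the cap is raised.
    """
    try:
        res = _fit_terms(data, spec, spec.terms, maxiter=maxiter)
    except Exception as exc:  # e.g. perfect separation detected by statsmodels
        return FitResult(
            coefficients={},
            deviance=math.nan,
            df_residual=0,
            converged=False,
            diagnostics={"error": str(exc)},
        )
    return FitResult(
        coefficients={k: float(v) for k, v in res.params.items()},
        deviance=float(res.deviance),
        df_residual=int(res.df_resid),
        converged=bool(getattr(res, "converged", True)),
        _sm_result=res,
    )


# ---------------------------------------------------------------------------
# analysis of deviance


def _contains(outer: tuple[str, ...], inner: tuple[str, ...]) -> bool:
    return set(inner) < set(outer)


def _one_term_test(
    data: pd.DataFrame,
    spec: ModelSpec,
    term: tuple[str, ...],
    context: Sequence[tuple[str, ...]],
    scale: float | None,
    df_denom: int | None,
) -> ModelTermTest:
    """LRT of ``term`` against the model holding ``context`` terms."""
    base = [t for t in context if t != term and not _contains(t, term)]
    with_term = base + [term]
    res0 = _fit_terms(data, spec, base)
    res1 = _fit_terms(data, spec, with_term)
    d_dev = float(res0.deviance - res1.deviance)
    d_df = int(res0.df_resid - res1.df_resid)
    label = term_label(term)
    if d_df <= 0:
        return ModelTermTest(label, "chi_square", math.nan, 0, math.nan, testable=False)
    if spec.family == "gaussian":
        f_stat = (d_dev / d_df) / scale
        p = float(stats.f.sf(f_stat, d_df, df_denom))
        return ModelTermTest(label, "F", max(f_stat, 0.0), (d_df, df_denom), p)
    chi2 = max(d_dev, 0.0)
    p = float(stats.chi2.sf(chi2, d_df))
    return ModelTermTest(label, "chi_square", chi2, d_df, p)


def _gaussian_scale(data: pd.DataFrame, spec: ModelSpec, terms) -> tuple[float, int]:
    res = _fit_terms(data, spec, terms)
    return float(res.deviance / res.df_resid), int(res.df_resid)


def term_tests(data: pd.DataFrame, spec: ModelSpec) -> list[ModelTermTest]:
    """Marginality-respecting (Type II) analysis-of-deviance tests, one per term."""
    scale = df_denom = None
    if spec.family == "gaussian":
        scale, df_denom = _gaussian_scale(data, spec, spec.terms)
    return [
        _one_term_test(data, spec, term, spec.terms, scale, df_denom)
        for term in spec.terms
    ]


def stepwise_simplify(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> tuple[ModelSpec, list[ModelTermTest]]:
    """Reduce a saturated model to a minimum adequate model.

    Repeatedly tests every removable term (one not contained in a retained
    interaction) and deletes the least significant whose p-value exceeds
    ``alpha``; ties break alphabetically on the term label.  Returns the
    minimal spec and the dropped-term report in deletion order.  A model
    whose every removable term is significant is returned unchanged.
    """
    current = list(spec.terms)
    dropped: list[ModelTermTest] = []
    while current:
        scale = df_denom = None
        if spec.family == "gaussian":
            scale, df_denom = _gaussian_scale(data, spec, current)
        removable = [
            t for t in current if not any(_contains(u, t) for u in current)
        ]
        tests = [
            _one_term_test(data, spec, t, current, scale, df_denom) for t in removable
        ]
        candidates = [
            (t, test) for t, test in zip(removable, tests)
            if test.testable and test.p_value > alpha
        ]
        if not candidates:
            break
        t, test = min(candidates, key=lambda pair: (-pair[1].p_value, pair[1].term))
        dropped.append(test)
        current.remove(t)
    return spec.with_terms(current), dropped


# ---------------------------------------------------------------------------
# separation-robust logistic regression


def fit_penalized_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    prior_scale: float = 2.5,
    intercept_scale: float = 10.0,
    n_starts: int = 4,
    seed: int = 0,
) -> FitResult:
    """MAP logistic regression with independent Cauchy priors.

    Predictors are standardized internally (binary design columns centered,
    continuous columns scaled to sd 0.5); coefficients get Cauchy(0, 2.5)
    priors on that scale and the intercept Cauchy(0, 10).  The posterior
    mode is located by quasi-Newton optimization from several starts, which
    yields finite, start-independent estimates even under complete
    separation.  Returned coefficients are back-transformed to the original
    predictor scale; the standardized-scale estimates are in
    ``diagnostics["coefficients_standardized"]``.
    """
    if spec.family != "binomial":
        raise ValueError("penalized logistic requires a binomial spec")
    df, response, weights = _prepare(data, spec)
    model = smf.glm(
        f"{response} ~ {_rhs(spec.terms)}", data=df, family=Binomial(),
        var_weights=weights,
    )
    X = np.asarray(model.exog, dtype=float)
    names = list(model.exog_names)
    y = np.asarray(model.endog, dtype=float)
    w = np.asarray(weights, dtype=float)

    # standardize non-intercept columns
    centers = np.zeros(X.shape[1])
    scales = np.ones(X.shape[1])
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        col = X[:, j]
        centers[j] = col.mean()
        uniq = np.unique(col)
        if len(uniq) > 2:
            sd = col.std()
            scales[j] = 2.0 * sd if sd > 0 else 1.0
    Xs = (X - centers) / scales
    Xs[:, names.index("Intercept")] = 1.0
    prior = np.full(X.shape[1], prior_scale)
    prior[names.index("Intercept")] = intercept_scale

    def neg_log_post(theta: np.ndarray) -> float:
        eta = Xs @ theta
        # w * [y*eta - log(1+e^eta)] is the binomial loglik up to a constant
        ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
        lp = float(np.sum(stats.cauchy.logpdf(theta, scale=prior)))
        return -(ll + lp)

    def grad(theta: np.ndarray) -> np.ndarray:
        mu = special.expit(Xs @ theta)
        g_ll = Xs.T @ (w * (y - mu))
        g_lp = -2.0 * theta / (prior**2 + theta**2)
        return -(g_ll + g_lp)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(X.shape[1])]
    starts += [rng.normal(scale=0.5, size=X.shape[1]) for _ in range(n_starts - 1)]
    solutions = []
    for x0 in starts:
        res = optimize.minimize(neg_log_post, x0, jac=grad, method="BFGS",
                                options={"gtol": 1e-9, "maxiter": 500})
        # polish: BFGS near-flat regions benefit from a Newton-CG restart
        res = optimize.minimize(neg_log_post, res.x, jac=grad, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        solutions.append(res)
    best = min(solutions, key=lambda r: r.fun)
    theta = best.x
    # BFGS may stop on precision loss at a tight gtol; judge convergence by
    # the actual gradient norm at the solution
    gnorm = float(np.max(np.abs(grad(theta))))
    converged = bool(best.success or gnorm < 1e-5)

    # back-transform to original predictor scale
    coefs = theta / scales
    intercept_idx = names.index("Intercept")
    adjust = sum(
        theta[j] * centers[j] / scales[j]
        for j in range(len(names)) if j != intercept_idx
    )
    coefs[intercept_idx] = theta[intercept_idx] - adjust

    mu = special.expit(Xs @ theta)
    eps = 1e-12
    ll = np.sum(w * (y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    y_safe = np.clip(y, eps, 1 - eps)
    ll_sat = np.sum(w * (y * np.log(y_safe) + (1 - y) * np.log(1 - y_safe)))
    start_spread = max(
        float(np.max(np.abs(s.x - theta))) for s in solutions
    )
    return FitResult(
        coefficients=dict(zip(names, (float(c) for c in coefs))),
        deviance=float(2.0 * (ll_sat - ll)),
        df_residual=int(len(y) - len(names)),
        converged=converged,
        penalized=True,
        diagnostics={
            "coefficients_standardized": dict(zip(names, map(float, theta))),
            "start_spread": start_spread,
            "gradient_norm": gnorm,
            "neg_log_posterior": float(best.fun),
        },
    )


# ---------------------------------------------------------------------------
# Box-Cox


def boxcox_lambda(
    x: np.ndarray | Sequence[float],
    grid: tuple[float, float, float] = (-2.0, 2.0, 0.01),
) -> tuple[float, np.ndarray]:
    """Profile-likelihood Box-Cox exponent on a fixed grid, plus transformed data.

    The transform is y = (x^lambda - 1)/lambda with the natural log at
    lambda = 0.  The grid default [-2, 2] in steps of 0.01 makes the
    estimate deterministic and reproducible.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    lo, hi, step = grid
    lambdas = np.round(np.arange(lo, hi + step / 2, step), 10)
    llf = np.array([stats.boxcox_llf(l, x) for l in lambdas])
    lam = float(lambdas[int(np.argmax(llf))])
    return lam, special.boxcox(x, lam)
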