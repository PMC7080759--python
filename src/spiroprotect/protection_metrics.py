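"""Composite Protective Index (PI) and its simulation-based inference.

The PI quantifies the net benefit a defensive symbiont gives its host in the
face of parasitoid attack, combining survival with the reproductive output of
survivors::

    PI = (s_e * f_e * m_e) / (s_u * f_u * m_u)

where ``s`` is larva-to-adult survival, ``f`` the proportion of surviving
females that are fertile, ``m`` the mean daughters of fertile females, and
the subscripts denote wasp-exposed (e) and unexposed (u) symbiont-carrying
flies.  A PI of 1 means attack costs the host nothing given the symbiont;
values below 1 measure the residual fitness cost.  The metric assumes
essentially complete mortality of symbiont-free hosts under attack, so it is
only defined for symbiont-carrying groups.

Uncertainty is propagated by Monte Carlo: each proportion gets a conjugate
Beta posterior (Beta(a0 + successes, b0 + failures)), each fecundity mean a
Normal(mean, se) truncated at zero, independent draws are combined into PI
draws, and the equal-tailed 2.5/97.5 percentile interval is reported.  The
same draws yield posterior ordering probabilities between wasp strains,
P(PI_a > PI_b).

When fertility of survivors could not be assayed (too few survivors), the
survival ratio serves as an upper bound for PI rather than an estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .experiment_data import (
    FemaleFertilityRecord,
    VialOutcome,
    WaspStrain,
)

__all__ = [
    "GroupSummary",
    "FecunditySummary",
    "ProtectionComponents",
    "PriorSpec",
    "ProtectionIndexResult",
    "PIBound",
    "PosteriorComparisonResult",
    "UndefinedSummaryError",
    "UndefinedPIError",
    "MissingCountsError",
    "NoControlError",
    "summarize_proportion",
    "compute_pi",
    "pi_survival_bound",
    "pi_posterior",
    "posterior_ordering",
    "percent_change",
    "build_components",
    "components_from_summaries",
    "reconstruct_counts",
    "reference_components",
]


class UndefinedSummaryError(ValueError):
    """A proportion summary was requested for an empty group."""


class UndefinedPIError(ValueError):
    """PI is undefined; the message names the zero or missing component."""


class MissingCountsError(ValueError):
    """Posterior simulation needs counts, not just proportions."""


class NoControlError(ValueError):
    """No unexposed symbiont-carrying control rows; the metric is undefined."""


@dataclass(frozen=True)
class GroupSummary:
    """A proportion with its 95% binomial confidence interval."""

    n_total: int
    n_success: int
    proportion: float
    ci_low: float
    ci_high: float
    method: str = "clopper_pearson"


@dataclass(frozen=True)
class FecunditySummary:
    """Mean daughters of fertile females with standard error of the mean."""

    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.n < 1:
            raise ValueError("a defined mean needs n >= 1")


@dataclass(frozen=True)
class ProtectionComponents:
    """The six summary quantities feeding PI, for one strain x ethanol block.

    Both sides describe symbiont-carrying flies; fertility and fecundity are
    either both present or both absent on each side (absent when survivors
    could not be assayed, which forces bound mode downstream).
    """

    exposed_survival: GroupSummary
    unexposed_survival: GroupSummary
    exposed_fertile: GroupSummary | None = None
    exposed_fecundity: FecunditySummary | None = None
    unexposed_fertile: GroupSummary | None = None
    unexposed_fecundity: FecunditySummary | None = None

    def __post_init__(self) -> None:
        for side in ("exposed", "unexposed"):
            fert = getattr(self, f"{side}_fertile")
            fec = getattr(self, f"{side}_fecundity")
            if (fert is None) != (fec is None):
                raise ValueError(
                    f"{side}: fertility and fecundity must be both present or both absent"
                )

    @property
    def complete(self) -> bool:
        """True when all six components are present (full PI is computable)."""
        return None not in (
            self.exposed_fertile, self.exposed_fecundity,
            self.unexposed_fertile, self.unexposed_fecundity,
        )


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the PI simulation.

    Proportions get a conjugate Beta(alpha0, beta0) prior (uniform by
    default); mean fecundity is modelled as Normal(summary mean, summary se)
    truncated at zero, which has no free hyperparameters.
    """

    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("Beta prior hyperparameters must be positive")

    @classmethod
    def jeffreys(cls) -> "PriorSpec":
        return cls(0.5, 0.5)


@dataclass(frozen=True)
class ProtectionIndexResult:
    """PI point estimate, 95% equal-tailed credible interval, and provenance."""

    point: float
    ci_low: float
    ci_high: float
    n_draws: int
    seed: int
    priors: PriorSpec
    draws: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class PIBound:
    """Survival-only upper bound for PI (fertility of survivors unmeasured)."""

    value: float
    convention: str = "ratio"
    is_bound: bool = True


@dataclass(frozen=True)
class PosteriorComparisonResult:
    """Posterior probability that one strain's PI exceeds another's."""

    p_greater: float
    n_draws: int
    seed: int


# ---------------------------------------------------------------------------
# proportion summaries


def summarize_proportion(
    n_success: int,
    n_total: int,
    method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
) -> GroupSummary:
    """Proportion with an exact Clopper-Pearson (default) or Wilson 95% CI."""
    if n_total <= 0:
        raise UndefinedSummaryError("cannot summarize a proportion with n_total = 0")
    if not 0 <= n_success <= n_total:
        raise ValueError(f"n_success={n_success} outside [0, {n_total}]")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}[method]
    low, high = proportion_confint(n_success, n_total, alpha=0.05, method=sm_method)
    low = 0.0 if math.isnan(low) else float(low)
    high = 1.0 if math.isnan(high) else float(high)
    return GroupSummary(
        n_total=n_total,
        n_success=n_success,
        proportion=n_success / n_total,
        ci_low=low,
        ci_high=high,
        method=method,
    )


# ---------------------------------------------------------------------------
# the index


def compute_pi(components: ProtectionComponents) -> float:
    """Plug-in Protective Index from the six group summaries."""
    if not components.complete:
        raise UndefinedPIError(
            "fertility/fecundity components absent; use pi_survival_bound"
        )
    parts = {
        "unexposed_survival": components.unexposed_survival.proportion,
        "unexposed_fertile": components.unexposed_fertile.proportion,
        "unexposed_fecundity": components.unexposed_fecundity.mean,
    }
    for name, value in parts.items():
        if value == 0:
            raise UndefinedPIError(f"denominator component {name} is zero")
    num = (
        components.exposed_survival.proportion
        * components.exposed_fertile.proportion
        * components.exposed_fecundity.mean
    )
    den = (
        parts["unexposed_survival"] * parts["unexposed_fertile"] * parts["unexposed_fecundity"]
    )
    return num / den


def pi_survival_bound(
    components: ProtectionComponents,
    convention: Literal["ratio", "product"] = "ratio",
) -> PIBound:
    """Upper bound for PI when survivor fertility could not be measured.

    The reproductive components of exposed survivors can only reduce PI
    below its survival part, so survival alone bounds the index from above.
    Two conventions are provided: ``ratio`` (exposed / unexposed survival,
    the default) and ``product`` (exposed x unexposed survival); neither is
    asserted as the canonical reading, see the methods note.
    """
    s_e = components.exposed_survival.proportion
    s_u = components.unexposed_survival.proportion
    if convention == "ratio":
        if s_u == 0:
            raise UndefinedPIError("unexposed survival is zero; bound undefined")
        return PIBound(value=s_e / s_u, convention="ratio")
    if convention == "product":
        return PIBound(value=s_e * s_u, convention="product")
    raise ValueError(f"unknown bound convention {convention!r}")


def percent_change(reference: float, comparison: float) -> float:
    """Percent reduction of ``comparison`` relative to ``reference``."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (1.0 - comparison / reference)


# ---------------------------------------------------------------------------
# posterior simulation


def _beta_draws(
    rng: np.random.Generator, summary: GroupSummary, priors: PriorSpec, size: int
) -> np.ndarray:
    a = priors.alpha0 + summary.n_success
    b = priors.beta0 + (summary.n_total - summary.n_success)
    return rng.beta(a, b, size=size)


def _truncnorm_draws(
    rng: np.random.Generator, summary: FecunditySummary, size: int
) -> np.ndarray:
    if summary.se == 0:
        return np.full(size, summary.mean)
    a = (0.0 - summary.mean) / summary.se
    return stats.truncnorm.rvs(
        a, np.inf, loc=summary.mean, scale=summary.se, size=size, random_state=rng
    )


def pi_posterior(
    components: ProtectionComponents,
    priors: PriorSpec | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> ProtectionIndexResult:
    """Simulate the PI posterior and report a 95% equal-tailed credible interval.

    Each proportion is drawn from its conjugate Beta posterior, each mean
    fecundity from a zero-truncated Normal(mean, se); the six draws are
    treated as independent (no attempt is made to model correlation between
    survival, fertility and fecundity) and combined into PI per draw.  The
    reported point estimate remains the plug-in ratio of summaries, not the
    posterior mean.
    """
    if priors is None:
        priors = PriorSpec()
    if not components.complete:
        raise MissingCountsError(
            "fertility/fecundity components absent: use pi_survival_bound, or "
            "reconstruct counts for all six components"
        )
    if n_draws < 1000:
        warnings.warn(
            f"n_draws={n_draws} < 1000 gives unstable percentile estimates",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    s_e = _beta_draws(rng, components.exposed_survival, priors, n_draws)
    s_u = _beta_draws(rng, components.unexposed_survival, priors, n_draws)
    f_e = _beta_draws(rng, components.exposed_fertile, priors, n_draws)
    f_u = _beta_draws(rng, components.unexposed_fertile, priors, n_draws)
    m_e = _truncnorm_draws(rng, components.exposed_fecundity, n_draws)
    m_u = _truncnorm_draws(rng, components.unexposed_fecundity, n_draws)
    draws = (s_e * f_e * m_e) / (s_u * f_u * m_u)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return ProtectionIndexResult(
        point=compute_pi(components),
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=n_draws,
        seed=seed,
        priors=priors,
        draws=draws,
    )


def posterior_ordering(
    a: ProtectionIndexResult, b: ProtectionIndexResult
) -> PosteriorComparisonResult:
    """Posterior probability that PI of ``a`` exceeds PI of ``b``.

    Draws are paired by index; ties count half, so p(a, b) + p(b, a) = 1
    exactly.
    """
    if a.draws is None or b.draws is None:
        raise ValueError("both results must retain their draws")
    if len(a.draws) != len(b.draws):
        raise ValueError(
            f"draw lengths differ ({len(a.draws)} vs {len(b.draws)})"
        )
    n = len(a.draws)
    greater = np.count_nonzero(a.draws > b.draws)
    ties = np.count_nonzero(a.draws == b.draws)
    return PosteriorComparisonResult(
        p_greater=(greater + 0.5 * ties) / n, n_draws=n, seed=a.seed
    )


# ---------------------------------------------------------------------------
# building components from assay tables


def _match_block(record_block: str, strain: WaspStrain, blocks_used: bool) -> bool:
    return (record_block == strain.value) if blocks_used else True


def build_components(
    vials: Iterable[VialOutcome],
    fertility: Iterable[FemaleFertilityRecord],
    strain: WaspStrain,
    ethanol: int,
    ci_method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
) -> ProtectionComponents:
    """Pool assay tables into the six PI components for one strain x ethanol.

    Survival pools larvae across vials (each larva a Bernoulli unit), which
    matches a single proportion per cell; vial structure matters only to the
    GLM layer.  Exposed groups are symbiont-carrying vials attacked by
    ``strain``; unexposed groups are no-wasp symbiont-carrying controls,
    restricted to the strain's assay block when block labels are present.
    Fecundity is summarised among fertile females only (se = SD / sqrt(n));
    if a side has no fertile females its reproductive components are absent
    and PI falls back to bound mode.
    """
    vials = list(vials)
    fertility = list(fertility)
    control_vials = [
        v for v in vials if not v.treatment.exposed and v.treatment.spiroplasma
    ]
    blocks_used = any(v.block for v in control_vials)

    def pool(selected: list[VialOutcome]) -> GroupSummary:
        n = sum(v.n_larvae for v in selected)
        k = sum(v.n_flies for v in selected)
        if n == 0:
            raise NoControlError(
                f"no vials for strain={strain.value}, ethanol={ethanol}"
            )
        return summarize_proportion(k, n, method=ci_method)

    exposed = [
        v for v in vials
        if v.treatment.wasp_strain is strain
        and v.treatment.spiroplasma
        and v.treatment.ethanol == ethanol
    ]
    unexposed = [
        v for v in control_vials
        if v.treatment.ethanol == ethanol and _match_block(v.block, strain, blocks_used)
    ]
    if not unexposed:
        raise NoControlError(
            f"no unexposed S+ control vials for strain={strain.value}, "
            f"ethanol={ethanol}; the metric is undefined without a control"
        )
    exposed_survival = pool(exposed)
    unexposed_survival = pool(unexposed)

    fert_blocks_used = any(
        r.block for r in fertility if not r.treatment.exposed and r.treatment.spiroplasma
    )

    def fert_side(exposed_side: bool) -> tuple[GroupSummary | None, FecunditySummary | None]:
        if exposed_side:
            recs = [
                r for r in fertility
                if r.treatment.wasp_strain is strain
                and r.treatment.spiroplasma
                and r.treatment.ethanol == ethanol
            ]
        else:
            recs = [
                r for r in fertility
                if not r.treatment.exposed
                and r.treatment.spiroplasma
                and r.treatment.ethanol == ethanol
                and _match_block(r.block, strain, fert_blocks_used)
            ]
        if not recs:
            return None, None
        fertile = [r for r in recs if r.fertile]
        if not fertile:
            return None, None
        daughters = np.array([r.daughters_total for r in fertile], dtype=float)
        se = float(daughters.std(ddof=1) / math.sqrt(len(daughters))) if len(daughters) > 1 else 0.0
        return (
            summarize_proportion(len(fertile), len(recs), method=ci_method),
            FecunditySummary(n=len(fertile), mean=float(daughters.mean()), se=se),
        )

    ef, efec = fert_side(True)
    uf, ufec = fert_side(False)
    if ef is None or uf is None:
        ef = efec = uf = ufec = None  # both sides needed for the full index
    return ProtectionComponents(
        exposed_survival=exposed_survival,
        unexposed_survival=unexposed_survival,
        exposed_fertile=ef,
        exposed_fecundity=efec,
        unexposed_fertile=uf,
        unexposed_fecundity=ufec,
    )


def components_from_summaries(
    exposed: tuple[float, float | None, float | None],
    unexposed: tuple[float, float | None, float | None],
) -> ProtectionComponents:
    """Build components from point summaries (survival, fertile, mean daughters).

    Intended for worked examples where a results table prints the six
    summaries directly: two-decimal proportions are represented as exact
    fractions over 100, and fecundity means carry zero se, so
    :func:`compute_pi` reproduces the table's plug-in index exactly.  Pass
    ``None`` fertility/fecundity for bound-only rows.
    """

    def side(vals):
        s, f, m = vals
        surv = summarize_proportion(round(s * 100), 100)
        if f is None or m is None:
            return surv, None, None
        return surv, summarize_proportion(round(f * 100), 100), FecunditySummary(1, m, 0.0)

    es, ef, em = side(exposed)
    us, uf, um = side(unexposed)
    if ef is None or uf is None:
        ef = em = uf = um = None
    return ProtectionComponents(
        exposed_survival=es,
        unexposed_survival=us,
        exposed_fertile=ef,
        exposed_fecundity=em,
        unexposed_fertile=uf,
        unexposed_fecundity=um,
    )


# ---------------------------------------------------------------------------
# reconstructing counts behind printed summaries


def reconstruct_counts(
    proportion: float, n_nominal: int, window: int = 10
) -> tuple[int, int]:
    """Integer (successes, total) nearest a printed proportion.

    Searches totals within ``window`` of the nominal design size and returns
    the pair whose realised fraction is closest to the printed value (ties
    favour totals nearest the nominal, then smaller).  This reconstructs
    plausible raw counts when a table prints only proportions; it is an
    approximation and documented as such.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion outside [0, 1]")
    best: tuple[float, int, int, int] | None = None
    for n in range(max(1, n_nominal - window), n_nominal + window + 1):
        k = min(n, max(0, round(proportion * n)))
        err = abs(k / n - proportion)
        key = (err, abs(n - n_nominal), n)
        if best is None or key < best[:3]:
            best = (*key[:3], k)
    assert best is not None
    _, _, n, k = best
    return k, n


def reference_components(
    strain: WaspStrain,
    ethanol: int,
    n_larvae_nominal: int = 450,
    n_females_nominal: int = 45,
    ci_method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
) -> ProtectionComponents:
    """PI components for one strain x ethanol from the default cell summaries.

    Builds :class:`ProtectionComponents` from the point summaries the
    package's generator defaults emulate, reconstructing integer counts from
    the stated design sizes (~450 larvae per survival cell, ~45 females per
    fertility cell).  Used for worked examples and desk-scale reproduction of
    the composite index.
    """
    from .synthetic_experiment import Cell, DEFAULT_CELL_SUMMARIES

    exp = DEFAULT_CELL_SUMMARIES[Cell(strain, True, ethanol, True)]
    unexp = DEFAULT_CELL_SUMMARIES[Cell(strain, True, ethanol, False)]

    def survival(s) -> GroupSummary:
        k, n = reconstruct_counts(s.survival, n_larvae_nominal)
        return summarize_proportion(k, n, method=ci_method)

    def fertility(s) -> tuple[GroupSummary | None, FecunditySummary | None]:
        if s.fertile is None:
            return None, None
        k, n = reconstruct_counts(s.fertile, n_females_nominal)
        return (
            summarize_proportion(k, n, method=ci_method),
            FecunditySummary(n=max(k, 1), mean=s.fecundity_mean, se=s.fecundity_se),
        )

    ef, efec = fertility(exp)
    uf, ufec = fertility(unexp)
    if ef is None or uf is None:
        ef = efec = uf = ufec = None
    return ProtectionComponents(
        exposed_survival=survival(exp),
        unexposed_survival=survival(unexp),
        exposed_fertile=ef,
        exposed_fecundity=efec,
        unexposed_fertile=uf,
        unexposed_fecundity=ufec,
    )
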