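"""Synthetic factorial assay generator.

Emulates the statistical structure of a Drosophila melanogaster /
Spiroplasma MSRO / Leptopilina heterotoma protection experiment: three
attacking wasp strains (Lh-Fr, Lh14, Lh-Mad), each assayed in its own block
crossing wasp exposure x symbiont infection x dietary ethanol (0/6%), with
~10-15 vials of 30 first-instar larvae per treatment cell, ~45 singly mated
females per fertility cell, wing-landmark photographs of survivors, and
Poisson oviposition counts from dissected larvae.

Default cell parameters reproduce the summary statistics of the original
field experiment (larva-to-adult survival, proportion fertile, mean
daughters of fertile females, wing areas), so downstream estimators can be
tested by parameter recovery.  Cells whose summaries were reported only as
bounds use the bound's midpoint; cells never measured (e.g. fertility of
symbiont-free or Lh14-attacked survivors) carry ``None`` and are skipped by
the generators, which naturally exercises the analysis layer's bound-only
mode.

The generative model per cell:

* fly survivors per vial ~ Binomial(n_larvae, p_fly), or beta-binomial with
  intra-vial correlation ``icc`` > 0 (between-vial variance inflated by the
  factor 1 + (n-1) icc);
* additional pupae among non-survivors ~ Binomial with the conditional rate
  (p_pupate - p_fly) / (1 - p_fly), so pupae >= flies by construction;
* wasp emergers ~ Binomial(pupae - flies, p_wasp); p_wasp is forced to 0 in
  symbiont-carrying cells (the symbiont kills the wasp in every case);
* fertile females ~ Bernoulli(p_fertile); daughters of fertile females are a
  zero-truncated rounded Normal(fecundity_mu, fecundity_sd) split across the
  four assay days by a symmetric multinomial;
* wing areas ~ Normal(wing_mu, wing_sd) mm^2, realised as a regular hexagon
  of exactly that area, randomly rotated and translated, at a fixed
  pixels-per-mm scale;
* oviposition counts ~ Poisson(lambda), lambda chosen so the mean eggs per
  larva lies between 1 and 2.

One global seed deterministically derives independent substreams per table,
so regenerating a single table never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .experiment_data import (
    ATTACKING_STRAINS,
    ETHANOL_LEVELS,
    FemaleFertilityRecord,
    OvipositionCount,
    Treatment,
    VialOutcome,
    WaspStrain,
    WingLandmarks,
)

__all__ = [
    "Cell",
    "CellSummary",
    "TreatmentParams",
    "ExperimentDesign",
    "DEFAULT_CELL_SUMMARIES",
    "default_params",
    "generate_vials",
    "generate_fertility",
    "generate_wings",
    "generate_oviposition",
    "generate_oviposition_table",
    "generate_all",
    "recover_params",
]

# substream indices for deriving per-table seeds from the global seed
_STREAMS = {"vials": 0, "fertility": 1, "wings": 2, "oviposition": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True, order=True)
class Cell:
    """One treatment cell within a wasp-strain assay block.

    ``block`` is the attacking strain whose assay the cell belongs to;
    unexposed cells keep the block so that each strain's own no-wasp
    controls can be told apart (their realised summaries differ between
    blocks run at different times).
    """

    block: WaspStrain
    spiroplasma: bool
    ethanol: int
    exposed: bool

    def __post_init__(self) -> None:
        if self.block is WaspStrain.NONE:
            raise ValueError("a cell's block must be an attacking strain")
        if self.ethanol not in ETHANOL_LEVELS:
            raise ValueError(f"ethanol must be one of {ETHANOL_LEVELS}")

    @property
    def treatment(self) -> Treatment:
        strain = self.block if self.exposed else WaspStrain.NONE
        return Treatment(strain, self.spiroplasma, self.ethanol)

    @property
    def label(self) -> str:
        s = "S+" if self.spiroplasma else "S-"
        w = "W+" if self.exposed else "W-"
        return f"{self.block.value}/E{self.ethanol}/{s}/{w}"


@dataclass(frozen=True)
class CellSummary:
    """Point summaries of one cell: the quantities a results table prints.

    ``fecundity_se`` is the standard error of the mean daughter count among
    fertile females; ``survival_is_bound`` marks survival values known only
    as an upper bound (stored as the bound's midpoint).
    """

    survival: float
    fertile: float | None = None
    fecundity_mean: float | None = None
    fecundity_se: float | None = None
    wing_mean: float | None = None
    survival_is_bound: bool = False


@dataclass(frozen=True)
class TreatmentParams:
    """Generative parameters of one treatment cell.

    ``p_fly`` is marginal larva-to-adult fly survival, ``p_pupate`` the
    marginal pupation probability (>= p_fly), ``p_wasp`` the wasp-emergence
    probability among pupated non-survivors (0 whenever spiroplasma is
    carried), ``icc`` the intra-vial correlation of the beta-binomial
    survival model (0 = plain binomial).  ``None`` fertility/wing fields
    mark cells the assay never measured.
    """

    cell: Cell
    p_pupate: float
    p_fly: float
    p_wasp: float
    p_fertile: float | None = None
    fecundity_mu: float | None = None
    fecundity_sd: float | None = None
    wing_mu: float | None = None
    wing_sd: float | None = None
    oviposition_lambda: float = 1.4
    icc: float = 0.0

    def __post_init__(self) -> None:
        probs = {"p_pupate": self.p_pupate, "p_fly": self.p_fly, "p_wasp": self.p_wasp}
        if self.p_fertile is not None:
            probs["p_fertile"] = self.p_fertile
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_fly > self.p_pupate + 1e-12:
            raise ValueError(f"p_fly={self.p_fly} exceeds p_pupate={self.p_pupate}")
        if self.cell.spiroplasma and self.p_wasp != 0.0:
            raise ValueError("symbiont-carrying cells must have p_wasp = 0")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(f"icc={self.icc} outside [0, 1)")
        for name in ("fecundity_sd", "wing_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} is negative")

    @property
    def treatment(self) -> Treatment:
        return self.cell.treatment


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample sizes of one full factorial run.

    Defaults mirror the original experiment: 12 vials x 30 larvae per
    treatment (the reported range is 10-15 vials), ~45 females per fertility
    cell, and ~25 dissected larvae (5 per each of 5 vials) per oviposition
    cell.
    """

    n_vials_per_treatment: int = 12
    larvae_per_vial: int = 30
    n_females_fertility: int = 45
    n_wings_per_group: int = 100
    n_larvae_oviposition: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_vials_per_treatment", "larvae_per_vial", "n_females_fertility",
            "n_wings_per_group", "n_larvae_oviposition",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")


# ---------------------------------------------------------------------------
# default parameters: the summary statistics the generator emulates

_N_FEMALES_NOMINAL = 45  # nominal fertility-assay group size


def _summaries() -> dict[Cell, CellSummary]:
    FR, L14, MAD = WaspStrain.LH_FR, WaspStrain.LH14, WaspStrain.LH_MAD
    s: dict[Cell, CellSummary] = {}

    # --- no ethanol ---------------------------------------------------------
    # Lh-Fr block
    s[Cell(FR, True, 0, True)] = CellSummary(0.42, 0.56, 10.9, 1.83, wing_mean=1.26)
    s[Cell(FR, True, 0, False)] = CellSummary(0.81, 0.97, 15.6, 1.31, wing_mean=1.30)
    s[Cell(FR, False, 0, True)] = CellSummary(0.005, survival_is_bound=True)
    s[Cell(FR, False, 0, False)] = CellSummary(0.81)
    # Lh14 block (too few survivors for fertility or wing assays)
    s[Cell(L14, True, 0, True)] = CellSummary(0.05)
    s[Cell(L14, True, 0, False)] = CellSummary(0.72)
    s[Cell(L14, False, 0, True)] = CellSummary(0.005, survival_is_bound=True)
    s[Cell(L14, False, 0, False)] = CellSummary(0.72)
    # Lh-Mad block
    s[Cell(MAD, True, 0, True)] = CellSummary(0.40, 0.40, 5.45, 1.54, wing_mean=1.17)
    s[Cell(MAD, True, 0, False)] = CellSummary(0.75, 0.95, 13.7, 0.985, wing_mean=1.22)
    s[Cell(MAD, False, 0, True)] = CellSummary(0.005, survival_is_bound=True)
    s[Cell(MAD, False, 0, False)] = CellSummary(0.75)

    # --- 6% ethanol ---------------------------------------------------------
    # wing means: rearing in ethanol shifts wing area down by ~0.02 mm^2
    s[Cell(FR, True, 6, True)] = CellSummary(0.33, 0.34, 9.98, 2.41, wing_mean=1.24)
    s[Cell(FR, True, 6, False)] = CellSummary(0.80, 1.00, 19.2, 1.38, wing_mean=1.28)
    s[Cell(FR, False, 6, True)] = CellSummary(0.03)
    s[Cell(FR, False, 6, False)] = CellSummary(0.80)
    s[Cell(L14, True, 6, True)] = CellSummary(0.01)
    s[Cell(L14, True, 6, False)] = CellSummary(0.69)
    s[Cell(L14, False, 6, True)] = CellSummary(0.005, survival_is_bound=True)
    s[Cell(L14, False, 6, False)] = CellSummary(0.69)
    s[Cell(MAD, True, 6, True)] = CellSummary(0.33, 0.60, 6.38, 1.28, wing_mean=1.15)
    s[Cell(MAD, True, 6, False)] = CellSummary(0.80, 0.95, 14.2, 0.805, wing_mean=1.20)
    s[Cell(MAD, False, 6, True)] = CellSummary(0.01)
    s[Cell(MAD, False, 6, False)] = CellSummary(0.80)
    return s


DEFAULT_CELL_SUMMARIES: dict[Cell, CellSummary] = _summaries()

# wasp emergence among pupated non-surviving larvae in symbiont-free attacked
# cells; ethanol reduces wasp success by roughly 40%/21%/60% per strain
_WASP_SUCCESS = {
    (WaspStrain.LH_FR, 0): 0.60,
    (WaspStrain.LH14, 0): 0.60,
    (WaspStrain.LH_MAD, 0): 0.60,
    (WaspStrain.LH_FR, 6): 0.36,
    (WaspStrain.LH14, 6): 0.47,
    (WaspStrain.LH_MAD, 6): 0.24,
}

_WING_SD = 0.07  # per-female SD of wing area, mm^2 (SE ~0.007 at n ~100)


def default_params(icc: float = 0.0) -> dict[Cell, TreatmentParams]:
    """Default generative parameters for every treatment cell.

    Point values match :data:`DEFAULT_CELL_SUMMARIES`; per-female fecundity
    SDs are back-calculated from the summary SE and the implied number of
    fertile females (``round(p_fertile * 45)``).  ``icc`` > 0 switches the
    survival draw to beta-binomial for robustness testing; the default 0
    matches a plain binomial model.
    """
    params: dict[Cell, TreatmentParams] = {}
    for cell, summ in DEFAULT_CELL_SUMMARIES.items():
        p_fly = summ.survival
        # attacked symbiont-free larvae mostly pupate (wasps emerge from the
        # pupal case); unexposed cells pupate a little above their eclosion rate
        if cell.exposed and not cell.spiroplasma:
            p_pupate = min(1.0, p_fly + 0.80)
        else:
            p_pupate = min(1.0, p_fly + 0.10)
        if cell.exposed and not cell.spiroplasma:
            p_wasp = _WASP_SUCCESS[(cell.block, cell.ethanol)]
        else:
            p_wasp = 0.0
        fecundity_sd = None
        if summ.fecundity_se is not None and summ.fertile is not None:
            n_fertile = max(2, round(summ.fertile * _N_FEMALES_NOMINAL))
            fecundity_sd = summ.fecundity_se * math.sqrt(n_fertile)
        params[cell] = TreatmentParams(
            cell=cell,
            p_pupate=p_pupate,
            p_fly=p_fly,
            p_wasp=p_wasp,
            p_fertile=summ.fertile,
            fecundity_mu=summ.fecundity_mean,
            fecundity_sd=fecundity_sd,
            wing_mu=summ.wing_mean,
            wing_sd=_WING_SD if summ.wing_mean is not None else None,
            oviposition_lambda=1.4,
            icc=icc,
        )
    return params


def _sorted_cells(params: Mapping[Cell, TreatmentParams]) -> list[Cell]:
    return sorted(
        params, key=lambda c: (c.block.value, c.ethanol, not c.spiroplasma, not c.exposed)
    )


# ---------------------------------------------------------------------------
# generators


def generate_vials(
    design: ExperimentDesign,
    params: Mapping[Cell, TreatmentParams],
    seed: int | None = None,
) -> list[VialOutcome]:
    """Simulate per-vial emergence counts for every cell in ``params``."""
    rng = _rng(design.seed if seed is None else seed, "vials")
    n = design.larvae_per_vial
    nv = design.n_vials_per_treatment
    out: list[VialOutcome] = []
    for cell in _sorted_cells(params):
        p = params[cell]
        if p.icc > 0:
            conc = (1.0 - p.icc) / p.icc
            p_vec = rng.beta(max(p.p_fly * conc, 1e-12), max((1 - p.p_fly) * conc, 1e-12), size=nv)
        else:
            p_vec = np.full(nv, p.p_fly)
        flies = rng.binomial(n, p_vec)
        q = 0.0 if p.p_fly >= 1.0 else (p.p_pupate - p.p_fly) / (1.0 - p.p_fly)
        pupae = flies + rng.binomial(n - flies, min(max(q, 0.0), 1.0))
        wasps = rng.binomial(pupae - flies, p.p_wasp)
        for i in range(nv):
            out.append(
                VialOutcome(
                    vial_id=f"{cell.label}/v{i:03d}",
                    treatment=cell.treatment,
                    n_larvae=n,
                    n_pupae=int(pupae[i]),
                    n_flies=int(flies[i]),
                    n_wasps=int(wasps[i]),
                    block=cell.block.value,
                )
            )
    return out


def _calibrated_truncnorm(mu: float, sd: float) -> tuple[float, float]:
    """Location for a zero-truncated normal whose mean equals ``mu``.

    Truncation at zero raises the mean above the location parameter, badly so
    when sd is comparable to the mean; solving for the location keeps the
    generated mean equal to the configured one (the parameter downstream
    estimators recover).  Returns (location, truncated-distribution SD).
    """
    from scipy.optimize import brentq

    if sd == 0:
        return mu, 0.0

    def mean_minus_target(loc: float) -> float:
        a = (0.0 - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - mu

    lo = mu - 10 * sd
    # truncated mean is increasing in loc and tends to 0+ as loc -> -inf
    loc = brentq(mean_minus_target, lo, mu + sd, xtol=1e-10)
    a = (0.0 - loc) / sd
    return loc, float(stats.truncnorm.std(a, np.inf, loc=loc, scale=sd))


def _truncated_normal_counts(
    rng: np.random.Generator, mu: float, sd: float, size: int
) -> np.ndarray:
    """Zero-truncated normal draws (mean calibrated to mu), rounded to counts >= 1."""
    if sd == 0:
        return np.full(size, max(1, round(mu)), dtype=int)
    loc, _ = _calibrated_truncnorm(mu, sd)
    a = (0.0 - loc) / sd
    draws = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, size=size, random_state=rng)
    return np.maximum(1, np.rint(draws).astype(int))


def generate_fertility(
    design: ExperimentDesign,
    params: Mapping[Cell, TreatmentParams],
    seed: int | None = None,
) -> list[FemaleFertilityRecord]:
    """Simulate per-female daughter counts for every cell with fertility data.

    Fertile females (Bernoulli ``p_fertile``) draw a zero-truncated rounded
    normal total, split across the four assay days by a symmetric
    multinomial; infertile females have all-zero days.
    """
    rng = _rng(design.seed if seed is None else seed, "fertility")
    out: list[FemaleFertilityRecord] = []
    for cell in _sorted_cells(params):
        p = params[cell]
        if p.p_fertile is None:
            continue
        if p.fecundity_mu is None or p.fecundity_sd is None:
            raise ValueError(f"cell {cell.label}: p_fertile set but fecundity missing")
        nf = design.n_females_fertility
        fertile = rng.random(nf) < p.p_fertile
        totals = np.zeros(nf, dtype=int)
        k = int(fertile.sum())
        if k:
            totals[fertile] = _truncated_normal_counts(rng, p.fecundity_mu, p.fecundity_sd, k)
        for i in range(nf):
            days = rng.multinomial(totals[i], [0.25] * 4)
            out.append(
                FemaleFertilityRecord(
                    female_id=f"{cell.label}/f{i:03d}",
                    treatment=cell.treatment,
                    daughters_by_day=tuple(int(d) for d in days),  # type: ignore[arg-type]
                    block=cell.block.value,
                )
            )
    return out


_PX_PER_MM = 200.0


def generate_wings(
    design: ExperimentDesign,
    params: Mapping[Cell, TreatmentParams],
    seed: int | None = None,
) -> list[WingLandmarks]:
    """Simulate six-landmark wing records for every cell with wing data.

    Each record is a regular hexagon whose interior area equals a
    Normal(wing_mu, wing_sd) draw (mm^2, floored at a small positive value),
    randomly rotated and translated, at a fixed pixels-per-mm scale; the
    landmark polygon therefore recovers the drawn area exactly.
    """
    rng = _rng(design.seed if seed is None else seed, "wings")
    out: list[WingLandmarks] = []
    for cell in _sorted_cells(params):
        p = params[cell]
        if p.wing_mu is None or p.wing_sd is None:
            continue
        nw = design.n_wings_per_group
        areas_mm2 = np.maximum(rng.normal(p.wing_mu, p.wing_sd, size=nw), 0.05)
        for i in range(nw):
            area_px2 = areas_mm2[i] * _PX_PER_MM**2
            # regular hexagon of area A has circumradius sqrt(2A / (3 sqrt 3))
            r = math.sqrt(2.0 * area_px2 / (3.0 * math.sqrt(3.0)))
            theta0 = rng.uniform(0, 2 * math.pi)
            cx, cy = rng.uniform(200, 1800, size=2)
            coords = tuple(
                (
                    cx + r * math.cos(theta0 + j * math.pi / 3.0),
                    cy + r * math.sin(theta0 + j * math.pi / 3.0),
                )
                for j in range(6)
            )
            out.append(
                WingLandmarks(
                    female_id=f"{cell.label}/w{i:03d}",
                    treatment=cell.treatment,
                    coords=coords,
                    scale=_PX_PER_MM,
                    block=cell.block.value,
                )
            )
    return out


def generate_oviposition(
    n_larvae: int,
    lam: float,
    seed: int,
    wasp_strain: WaspStrain = WaspStrain.LH_FR,
    spiroplasma: bool = False,
) -> list[OvipositionCount]:
    """Simulate Poisson(lam) egg/larva counts for ``n_larvae`` dissected larvae."""
    if lam <= 0:
        raise ValueError("oviposition rate lambda must be positive")
    rng = _rng(seed, "oviposition")
    counts = rng.poisson(lam, size=n_larvae)
    s = "S+" if spiroplasma else "S-"
    return [
        OvipositionCount(
            larva_id=f"{wasp_strain.value}/{s}/l{i:03d}",
            wasp_strain=wasp_strain,
            spiroplasma=spiroplasma,
            n_eggs_larvae=int(c),
        )
        for i, c in enumerate(counts)
    ]


def generate_oviposition_table(
    design: ExperimentDesign,
    params: Mapping[Cell, TreatmentParams],
    seed: int | None = None,
) -> list[OvipositionCount]:
    """Oviposition counts for every attacking strain x symbiont status.

    The oviposition assay ran without ethanol; rates come from the exposed
    no-ethanol cell of each strain.
    """
    base = design.seed if seed is None else seed
    rng = _rng(base, "oviposition")
    out: list[OvipositionCount] = []
    for strain in ATTACKING_STRAINS:
        for spiro in (False, True):
            cell = Cell(strain, spiro, 0, True)
            lam = params[cell].oviposition_lambda if cell in params else 1.4
            counts = rng.poisson(lam, size=design.n_larvae_oviposition)
            s = "S+" if spiro else "S-"
            out.extend(
                OvipositionCount(
                    larva_id=f"{strain.value}/{s}/l{i:03d}",
                    wasp_strain=strain,
                    spiroplasma=spiro,
                    n_eggs_larvae=int(c),
                )
                for i, c in enumerate(counts)
            )
    return out


def generate_all(
    design: ExperimentDesign,
    params: Mapping[Cell, TreatmentParams] | None = None,
    seed: int | None = None,
) -> dict[str, list]:
    """Generate all four assay tables from one seed; substreams are independent."""
    if params is None:
        params = default_params()
    base = design.seed if seed is None else seed
    return {
        "vials": generate_vials(design, params, base),
        "fertility": generate_fertility(design, params, base),
        "wings": generate_wings(design, params, base),
        "oviposition": generate_oviposition_table(design, params, base),
    }


# ---------------------------------------------------------------------------
# parameter recovery


def recover_params(
    vials: Iterable[VialOutcome],
    fertility: Iterable[FemaleFertilityRecord],
    true_params: Mapping[Cell, TreatmentParams],
):
    """Compare per-cell estimates against known generative parameters.

    Returns a DataFrame with one row per (cell, quantity): the truth, the
    estimate, its standard error evaluated at the truth, the absolute error,
    and whether the estimate lies within 3 SEs.  Empty cells are reported as
    unestimable rather than raising.
    """
    import pandas as pd

    vial_groups: dict[Cell, list[VialOutcome]] = {}
    for v in vials:
        t = v.treatment
        block = WaspStrain(v.block) if v.block else t.wasp_strain
        cell = Cell(block, t.spiroplasma, t.ethanol, t.exposed)
        vial_groups.setdefault(cell, []).append(v)
    fert_groups: dict[Cell, list[FemaleFertilityRecord]] = {}
    for r in fertility:
        t = r.treatment
        block = WaspStrain(r.block) if r.block else t.wasp_strain
        cell = Cell(block, t.spiroplasma, t.ethanol, t.exposed)
        fert_groups.setdefault(cell, []).append(r)

    rows = []

    def add(cell: Cell, quantity: str, truth: float, est, se, n) -> None:
        estimable = est is not None and n > 0
        err = abs(est - truth) if estimable else math.nan
        within = bool(err <= 3 * se) if estimable and se > 0 else (err == 0 if estimable else False)
        rows.append(
            {
                "cell": cell.label,
                "quantity": quantity,
                "truth": truth,
                "estimate": est if estimable else math.nan,
                "se": se,
                "abs_error": err,
                "n": n,
                "estimable": estimable,
                "within_3se": within,
            }
        )

    for cell, p in true_params.items():
        group = vial_groups.get(cell, [])
        n_larvae = sum(v.n_larvae for v in group)
        n_flies = sum(v.n_flies for v in group)
        est = n_flies / n_larvae if n_larvae else None
        se = math.sqrt(p.p_fly * (1 - p.p_fly) / n_larvae) if n_larvae else math.nan
        add(cell, "p_fly", p.p_fly, est, se, n_larvae)

        if p.p_fertile is not None:
            fgroup = fert_groups.get(cell, [])
            nf = len(fgroup)
            n_fertile = sum(r.fertile for r in fgroup)
            est = n_fertile / nf if nf else None
            se = math.sqrt(p.p_fertile * (1 - p.p_fertile) / nf) if nf else math.nan
            add(cell, "p_fertile", p.p_fertile, est, se, nf)

            daughters = [r.daughters_total for r in fgroup if r.fertile]
            if len(daughters) >= 2 and p.fecundity_mu is not None:
                mean = float(np.mean(daughters))
                _, trunc_sd = _calibrated_truncnorm(p.fecundity_mu, p.fecundity_sd)
                se = trunc_sd / math.sqrt(len(daughters))
                add(cell, "fecundity_mu", p.fecundity_mu, mean, se, len(daughters))
            elif p.fecundity_mu is not None:
                add(cell, "fecundity_mu", p.fecundity_mu, None, math.nan, len(daughters))

    return pd.DataFrame(rows)
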