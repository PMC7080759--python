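"""End-to-end reproducible pipeline: simulate or load the four assay tables,
run every analysis stage, and write diff-able CSV reports plus a provenance
log.

Outputs per run (all plain text, deterministic under a fixed seed):

``protection_report.csv``
    one row per strain x ethanol x group with survival, fertile proportion
    (each with 95% binomial CIs), fecundity +/- se, the protective index
    (or its survival-only bound when survivor fertility is unavailable) and
    its 95% credible interval;
``ordering_probabilities.csv``
    posterior P(PI_a > PI_b) for strain pairs within each ethanol level;
``term_tests.csv``
    analysis-of-deviance tables for each fitted response, after stepwise
    simplification, plus the dropped-term report;
``outcome_proportions.csv``
    per-treatment stacked outcome fractions (dead larvae, dead pupae,
    emerged flies, emerged wasps);
``wing_summary.csv``
    wing-area group means and attacked-vs-control differences;
``provenance.json``
    seed, config hash, package and library versions, and the sample sizes
    actually used for each credible interval.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiment_data import (
    ATTACKING_STRAINS,
    FemaleFertilityRecord,
    OvipositionCount,
    VialOutcome,
    WaspStrain,
    WingLandmarks,
    fertility_frame,
    read_fertility_table,
    read_oviposition_table,
    read_vial_table,
    read_wing_table,
    vials_frame,
    write_summary_table,
)
from .inferential_models import (
    ModelSpec,
    ModelTermTest,
    boxcox_lambda,
    fit_penalized_logistic,
    stepwise_simplify,
    term_tests,
)
from .protection_metrics import (
    NoControlError,
    PriorSpec,
    build_components,
    pi_posterior,
    pi_survival_bound,
    posterior_ordering,
)
from .synthetic_experiment import (
    ExperimentDesign,
    default_params,
    generate_all,
)
from .wing_morphometrics import summarize_wings, wing_areas


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One run's full configuration; every stochastic stage's seed derives
    from the single run seed."""

    outdir: Path = Path("spiroprotect_out")
    seed: int = 0
    n_draws: int = 100_000
    prior: tuple[float, float] = (1.0, 1.0)
    ci_method: str = "clopper_pearson"
    alpha: float = 0.05
    bound_convention: str = "ratio"
    icc: float = 0.0
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    # paths to existing tables; None for any -> simulate that table
    vials_path: Path | None = None
    fertility_path: Path | None = None
    wings_path: Path | None = None
    oviposition_path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = ExperimentDesign(**raw.pop("design", {}))
        paths = {
            f"{k}_path": Path(v)
            for k in ("vials", "fertility", "wings", "oviposition")
            if (v := raw.pop(f"{k}_path", None)) is not None
        }
        if "prior" in raw:
            raw["prior"] = tuple(raw["prior"])
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        return cls(design=design, **paths, **raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        for k in ("vials_path", "fertility_path", "wings_path", "oviposition_path"):
            d[k] = str(d[k]) if d[k] is not None else None
        return json.dumps(d, sort_keys=True, default=str)


@dataclass
class ReportBundle:
    """Paths of every report written by one pipeline run."""

    outdir: Path
    protection_report: Path
    ordering: Path
    term_tests: Path
    outcome_proportions: Path
    wing_summary: Path | None
    provenance: Path
    summary_text: Path


def _substream_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_or_simulate(config: RunConfig, outdir: Path):
    params = default_params(icc=config.icc)
    design = dataclasses.replace(config.design, seed=config.seed)
    simulated = generate_all(design, params, seed=config.seed)
    tables: dict[str, list] = {}
    readers = {
        "vials": (config.vials_path, read_vial_table),
        "fertility": (config.fertility_path, read_fertility_table),
        "wings": (config.wings_path, read_wing_table),
        "oviposition": (config.oviposition_path, read_oviposition_table),
    }
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    for name, (path, reader) in readers.items():
        if path is not None:
            tables[name] = reader(path)
        else:
            tables[name] = simulated[name]
            write_summary_table(tables[name], datadir / f"{name}.csv")
    return tables


def _protection_stage(config: RunConfig, tables, outdir: Path):
    vials: list[VialOutcome] = tables["vials"]
    fertility: list[FemaleFertilityRecord] = tables["fertility"]
    priors = PriorSpec(*config.prior)
    rows = []
    posteriors: dict[tuple[str, int], object] = {}
    sizes = {}
    for ethanol in (0, 6):
        for strain in ATTACKING_STRAINS:
            try:
                comps = build_components(
                    vials, fertility, strain, ethanol, ci_method=config.ci_method
                )
            except NoControlError:
                continue
            base = {"wasp_strain": strain.value, "ethanol": ethanol}

            def group_row(label, surv, fert, fec):
                r = dict(base)
                r.update(
                    group=label,
                    survival=surv.proportion if surv else np.nan,
                    survival_ci_low=surv.ci_low if surv else np.nan,
                    survival_ci_high=surv.ci_high if surv else np.nan,
                    fertile=fert.proportion if fert else np.nan,
                    fertile_ci_low=fert.ci_low if fert else np.nan,
                    fertile_ci_high=fert.ci_high if fert else np.nan,
                    fecundity_mean=fec.mean if fec else np.nan,
                    fecundity_se=fec.se if fec else np.nan,
                )
                return r

            exposed_row = group_row(
                "exposed_Splus", comps.exposed_survival,
                comps.exposed_fertile, comps.exposed_fecundity,
            )
            unexposed_row = group_row(
                "unexposed_Splus", comps.unexposed_survival,
                comps.unexposed_fertile, comps.unexposed_fecundity,
            )
            # symbiont-free attacked survival: diagnostic only, PI undefined
            sminus = [
                v for v in vials
                if v.treatment.wasp_strain is strain
                and not v.treatment.spiroplasma
                and v.treatment.ethanol == ethanol
            ]
            if sminus:
                n = sum(v.n_larvae for v in sminus)
                k = sum(v.n_flies for v in sminus)
                exposed_row["sminus_survival_diagnostic"] = k / n
            if comps.complete:
                seed = _substream_seed(config.seed, f"pi:{strain.value}:{ethanol}")
                post = pi_posterior(
                    comps, priors=priors, n_draws=config.n_draws, seed=seed
                )
                posteriors[(strain.value, ethanol)] = post
                sizes[f"{strain.value}:E{ethanol}"] = {
                    "survival_n": [comps.exposed_survival.n_total,
                                   comps.unexposed_survival.n_total],
                    "fertility_n": [comps.exposed_fertile.n_total,
                                    comps.unexposed_fertile.n_total],
                }
                exposed_row.update(
                    pi=post.point, pi_ci_low=post.ci_low, pi_ci_high=post.ci_high,
                    pi_mode="estimate",
                )
            else:
                bound = pi_survival_bound(comps, convention=config.bound_convention)
                exposed_row.update(
                    pi=bound.value, pi_ci_low=np.nan, pi_ci_high=np.nan,
                    pi_mode=f"survival_bound_{bound.convention}",
                )
            rows.extend([exposed_row, unexposed_row])
    report = pd.DataFrame(rows)
    path = outdir / "protection_report.csv"
    report.to_csv(path, index=False, float_format="%.6g")

    pairs = []
    for ethanol in (0, 6):
        keys = [k for k in posteriors if k[1] == ethanol]
        for a in keys:
            for b in keys:
                if a < b:
                    cmp_res = posterior_ordering(posteriors[a], posteriors[b])
                    pairs.append(
                        {
                            "ethanol": ethanol,
                            "strain_a": a[0],
                            "strain_b": b[0],
                            "p_pi_a_greater": cmp_res.p_greater,
                            "n_draws": cmp_res.n_draws,
                        }
                    )
    opath = outdir / "ordering_probabilities.csv"
    pd.DataFrame(pairs).to_csv(opath, index=False, float_format="%.6g")
    return path, opath, report, sizes


def _tests_frame(analysis: str, tests: Iterable[ModelTermTest], dropped=False):
    rows = []
    for t in tests:
        df = t.df if isinstance(t.df, int) else f"{t.df[0]},{t.df[1]}"
        rows.append(
            {
                "analysis": analysis,
                "term": t.term,
                "statistic_kind": t.statistic_kind,
                "statistic": t.statistic,
                "df": df,
                "p_value": t.p_value,
                "dropped": dropped,
            }
        )
    return pd.DataFrame(rows)


def _glm_stage(config: RunConfig, tables, outdir: Path):
    vials = vials_frame(tables["vials"])
    frames = []

    def run(analysis: str, data: pd.DataFrame, spec: ModelSpec):
        minimal, dropped = stepwise_simplify(data, spec, alpha=config.alpha)
        if minimal.terms:
            frames.append(_tests_frame(analysis, term_tests(data, minimal)))
        if dropped:
            frames.append(_tests_frame(analysis, dropped, dropped=True))

    # fly survival among wasp-exposed vials: symbiont x strain x ethanol
    exposed = vials[vials["exposed"]].copy()
    if len(exposed) and exposed["wasp_strain"].nunique() > 1:
        run(
            "fly_survival_exposed", exposed,
            ModelSpec(
                ("n_flies", "n_larvae"), "binomial",
                ("spiroplasma", "wasp_strain", "ethanol"),
                (
                    ("spiroplasma", "wasp_strain"), ("spiroplasma", "ethanol"),
                    ("wasp_strain", "ethanol"),
                    ("spiroplasma", "wasp_strain", "ethanol"),
                ),
            ),
        )
    # no-wasp controls: symbiont x ethanol
    controls = vials[~vials["exposed"]].copy()
    if len(controls):
        run(
            "fly_survival_controls", controls,
            ModelSpec(
                ("n_flies", "n_larvae"), "binomial",
                ("spiroplasma", "ethanol"), (("spiroplasma", "ethanol"),),
            ),
        )
    # wasp success: separation-robust fit; symbiont interactions excluded
    if len(exposed):
        spec = ModelSpec(
            ("n_wasps", "n_larvae"), "binomial",
            ("spiroplasma", "wasp_strain", "ethanol"),
            (("wasp_strain", "ethanol"),),
        )
        fit = fit_penalized_logistic(exposed, spec, seed=_substream_seed(config.seed, "waspglm"))
        frames.append(
            pd.DataFrame(
                [
                    {
                        "analysis": "wasp_success_penalized",
                        "term": name,
                        "statistic_kind": "coefficient",
                        "statistic": est,
                        "df": "",
                        "p_value": np.nan,
                        "dropped": False,
                    }
                    for name, est in fit.coefficients.items()
                ]
            )
        )
    # fertility and daughters per strain: exposure x ethanol among S+ females
    fert = fertility_frame(tables["fertility"])
    for strain in ATTACKING_STRAINS:
        sub = fert[
            fert["spiroplasma"]
            & ((fert["wasp_strain"] == strain.value) | (fert["exposure"] == "unexposed"))
        ].copy()
        if "block" in sub.columns and sub["block"].any():
            sub = sub[(sub["block"] == strain.value) | (sub["exposure"] == "exposed")]
        if sub.empty or sub["exposure"].nunique() < 2:
            continue
        sub["fertile_n"] = sub["fertile"].astype(int)
        sub["one"] = 1
        run(
            f"fertile_{strain.value}", sub,
            ModelSpec(("fertile_n", "one"), "binomial",
                      ("exposure", "ethanol"), (("ethanol", "exposure"),)),
        )
        fertile_only = sub[sub["fertile"]]
        if fertile_only["exposure"].nunique() == 2 and len(fertile_only) > 8:
            run(
                f"daughters_{strain.value}", fertile_only,
                ModelSpec("daughters_total", "gaussian",
                          ("exposure", "ethanol"), (("ethanol", "exposure"),)),
            )
    # oviposition: strain x symbiont Poisson
    ovi = tables["oviposition"]
    if ovi:
        ovi_df = pd.DataFrame(
            {
                "wasp_strain": [o.wasp_strain.value for o in ovi],
                "spiroplasma": [o.spiroplasma for o in ovi],
                "n_eggs": [o.n_eggs_larvae for o in ovi],
            }
        )
        run(
            "oviposition", ovi_df,
            ModelSpec("n_eggs", "poisson", ("spiroplasma", "wasp_strain"),
                      (("spiroplasma", "wasp_strain"),)),
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    path = outdir / "term_tests.csv"
    out.to_csv(path, index=False, float_format="%.6g")
    return path, out


def _wing_stage(config: RunConfig, tables, outdir: Path):
    wings: list[WingLandmarks] = tables["wings"]
    if not wings:
        return None, None
    areas = wing_areas(wings)
    meta = {w.female_id: w for w in wings}

    def group(fid: str) -> str:
        w = meta[fid]
        return f"{w.block or w.treatment.wasp_strain.value}:{w.exposure}"

    frames = []
    for block in sorted({w.block for w in wings if w.block}):
        sub = [a for a in areas if meta[a.female_id].block == block]
        labels = {a.female_id: group(a.female_id) for a in sub}
        if len(set(labels.values())) < 2:
            continue
        groups, pairs = summarize_wings(sub, labels, control=f"{block}:unexposed")
        groups["block"] = block
        pairs["block"] = block
        frames.append((groups, pairs))
    if not frames:
        return None, None
    groups = pd.concat([g for g, _ in frames], ignore_index=True)
    pairs = pd.concat([p for _, p in frames], ignore_index=True)
    # gaussian model on Box-Cox transformed areas per block
    tests = []
    for block in groups["block"].unique():
        sub_wings = [w for w in wings if w.block == block]
        sub_areas = {a.female_id: a.area_mm2 for a in areas if meta[a.female_id].block == block}
        df = pd.DataFrame(
            {
                "area": [sub_areas[w.female_id] for w in sub_wings],
                "exposure": [w.exposure for w in sub_wings],
                "ethanol": [w.treatment.ethanol for w in sub_wings],
            }
        )
        lam, transformed = boxcox_lambda(df["area"].to_numpy())
        df["area_bc"] = transformed
        spec = ModelSpec("area_bc", "gaussian", ("exposure", "ethanol"),
                         (("ethanol", "exposure"),))
        minimal, dropped = stepwise_simplify(df, spec, alpha=config.alpha)
        if minimal.terms:
            frame = _tests_frame(f"wing_area_{block}", term_tests(df, minimal))
            frame["boxcox_lambda"] = lam
            tests.append(frame)
        if dropped:
            frame = _tests_frame(f"wing_area_{block}", dropped, dropped=True)
            frame["boxcox_lambda"] = lam
            tests.append(frame)
    path = outdir / "wing_summary.csv"
    pd.concat([groups, pairs], ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )
    tests_frame = pd.concat(tests, ignore_index=True) if tests else pd.DataFrame()
    return path, tests_frame


def _outcome_stage(tables, outdir: Path):
    vials = vials_frame(tables["vials"])
    grouped = vials.groupby(
        ["block", "wasp_strain", "spiroplasma", "ethanol"], as_index=False
    )[["n_larvae", "n_pupae", "n_flies", "n_wasps"]].sum()
    grouped["p_dead_larvae"] = (grouped.n_larvae - grouped.n_pupae) / grouped.n_larvae
    grouped["p_dead_pupae"] = (
        grouped.n_pupae - grouped.n_flies - grouped.n_wasps
    ) / grouped.n_larvae
    grouped["p_flies"] = grouped.n_flies / grouped.n_larvae
    grouped["p_wasps"] = grouped.n_wasps / grouped.n_larvae
    path = outdir / "outcome_proportions.csv"
    grouped.to_csv(path, index=False, float_format="%.6g")
    return path


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report bundle; deterministic per seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except (PipelineStageError, Exception) as exc:
            if isinstance(exc, PipelineStageError):
                raise
            raise PipelineStageError(name, str(exc)) from exc

    tables = stage("load_or_simulate", _load_or_simulate, config, outdir)
    prot_path, order_path, _, ci_sizes = stage(
        "protection", _protection_stage, config, tables, outdir
    )
    glm_path, glm_frame = stage("glm", _glm_stage, config, tables, outdir)
    wing_path, wing_tests = stage("wings", _wing_stage, config, tables, outdir)
    if wing_tests is not None and not wing_tests.empty:
        merged = pd.concat([glm_frame, wing_tests], ignore_index=True)
        merged.to_csv(glm_path, index=False, float_format="%.6g")
    outcome_path = stage("outcomes", _outcome_stage, tables, outdir)

    import scipy
    import statsmodels

    provenance = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "versions": {
            "spiroprotect": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "credible_interval_sample_sizes": ci_sizes,
        "n_draws": config.n_draws,
        "prior": list(config.prior),
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True))

    summary_path = outdir / "summary.txt"
    lines = [
        f"spiroprotect {__version__} run (seed={config.seed})",
        f"tables: {', '.join(f'{k} n={len(v)}' for k, v in tables.items())}",
        f"reports: {prot_path.name}, {order_path.name}, {glm_path.name}, "
        f"{outcome_path.name}" + (f", {wing_path.name}" if wing_path else ""),
    ]
    summary_path.write_text("\n".join(lines) + "\n")

    return ReportBundle(
        outdir=outdir,
        protection_report=prot_path,
        ordering=order_path,
        term_tests=glm_path,
        outcome_proportions=outcome_path,
        wing_summary=wing_path,
        provenance=prov_path,
        summary_text=summary_path,
    )
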