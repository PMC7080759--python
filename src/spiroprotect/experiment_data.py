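"""Data model and CSV I/O for the four assay tables.

The factorial experiment crosses three factors per attacking-wasp strain:
wasp exposure (attacked / no-wasp control), *Spiroplasma* infection (S+ / S-)
and dietary ethanol (0% / 6%).  Four tidy tables capture its outcomes:

``vials.csv``
    per-vial larva-to-adult counts (larvae placed, pupae, emerging flies,
    emerging wasps),
``fertility.csv``
    per-female daily daughter counts over assay days 2-5,
``wings.csv``
    six wing-landmark coordinates (pixels) plus a pixels-per-mm scale,
``oviposition.csv``
    per-dissected-larva counts of wasp eggs/larvae.

All files are UTF-8, comma-delimited, one header row.  Derived quantities
(total daughters, fertile flag) are always recomputed from raw columns on
read; a stored value can never contradict them.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WaspStrain",
    "ATTACKING_STRAINS",
    "ETHANOL_LEVELS",
    "Treatment",
    "VialOutcome",
    "FemaleFertilityRecord",
    "WingLandmarks",
    "OvipositionCount",
    "SchemaError",
    "RowValidationError",
    "read_vial_table",
    "read_fertility_table",
    "read_wing_table",
    "read_oviposition_table",
    "write_summary_table",
    "vials_frame",
    "fertility_frame",
]


class SchemaError(ValueError):
    """A file's header does not match the documented schema."""


class RowValidationError(ValueError):
    """A row violates a domain invariant; the message names the offending id."""


class WaspStrain(str, enum.Enum):
    """Attacking Leptopilina heterotoma strain; NONE encodes the no-wasp control arm."""

    NONE = "NONE"
    LH_FR = "LH_FR"
    LH14 = "LH14"
    LH_MAD = "LH_MAD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ATTACKING_STRAINS: tuple[WaspStrain, ...] = (
    WaspStrain.LH_FR,
    WaspStrain.LH14,
    WaspStrain.LH_MAD,
)

ETHANOL_LEVELS: tuple[int, ...] = (0, 6)

_SPIRO_CODES = {
    "S+": True,
    "SPLUS": True,
    "TRUE": True,
    "1": True,
    "S-": False,
    "S−": False,  # unicode minus
    "SMINUS": False,
    "FALSE": False,
    "0": False,
}

_DAY_COLUMNS = ("daughters_day2", "daughters_day3", "daughters_day4", "daughters_day5")

VIAL_COLUMNS = [
    "vial_id", "wasp_strain", "spiroplasma", "ethanol",
    "n_larvae", "n_pupae", "n_flies", "n_wasps",
]
FERTILITY_COLUMNS = [
    "female_id", "wasp_strain", "spiroplasma", "ethanol", *_DAY_COLUMNS,
]
WING_COLUMNS = [
    "female_id", "wasp_strain", "spiroplasma", "ethanol",
    "x1", "y1", "x2", "y2", "x3", "y3", "x4", "y4", "x5", "y5", "x6", "y6",
    "scale_px_per_mm",
]
OVIPOSITION_COLUMNS = ["larva_id", "wasp_strain", "spiroplasma", "n_eggs_larvae"]


def _parse_strain(code: str, row_id: str) -> WaspStrain:
    code = str(code).strip().upper().replace("-", "_")
    aliases = {"LHFR": "LH_FR", "LH_14": "LH14", "LHMAD": "LH_MAD", "": "NONE"}
    code = aliases.get(code, code)
    try:
        return WaspStrain(code)
    except ValueError:
        raise RowValidationError(
            f"row {row_id!r}: unknown wasp_strain code {code!r}"
        ) from None


def _parse_spiroplasma(code: str, row_id: str) -> bool:
    key = str(code).strip().upper()
    if key not in _SPIRO_CODES:
        raise RowValidationError(f"row {row_id!r}: unknown spiroplasma code {code!r}")
    return _SPIRO_CODES[key]


def _parse_ethanol(code: str, row_id: str) -> int:
    key = str(code).strip().upper().removeprefix("ETOH").removesuffix("%")
    try:
        level = int(key)
    except ValueError:
        raise RowValidationError(f"row {row_id!r}: unknown ethanol code {code!r}") from None
    if level not in ETHANOL_LEVELS:
        raise RowValidationError(
            f"row {row_id!r}: ethanol level {level} not in {ETHANOL_LEVELS}"
        )
    return level


def _parse_count(value: str, column: str, row_id: str) -> int:
    """Parse a non-negative integer count; decimal counts are rejected, not rounded."""
    text = str(value).strip()
    try:
        as_float = float(text)
    except ValueError:
        raise RowValidationError(
            f"row {row_id!r}: column {column!r} value {value!r} is not a number"
        ) from None
    if not as_float.is_integer():
        raise RowValidationError(
            f"row {row_id!r}: column {column!r} value {value!r} is not an integer count"
        )
    n = int(as_float)
    if n < 0:
        raise RowValidationError(
            f"row {row_id!r}: column {column!r} value {n} is negative"
        )
    return n


@dataclass(frozen=True)
class Treatment:
    """One cell of the factorial design.

    ``wasp_strain`` is NONE for the no-wasp control arms; the cross of the
    three factors yields the experiment's eight treatments per wasp strain.
    """

    wasp_strain: WaspStrain
    spiroplasma: bool
    ethanol: int

    def __post_init__(self) -> None:
        if not isinstance(self.wasp_strain, WaspStrain):
            object.__setattr__(self, "wasp_strain", WaspStrain(self.wasp_strain))
        if self.ethanol not in ETHANOL_LEVELS:
            raise ValueError(f"ethanol must be one of {ETHANOL_LEVELS}, got {self.ethanol}")

    @property
    def exposed(self) -> bool:
        """Whether this arm was exposed to wasp attack."""
        return self.wasp_strain is not WaspStrain.NONE

    @property
    def code(self) -> str:
        s = "S+" if self.spiroplasma else "S-"
        return f"{self.wasp_strain.value},{s},{self.ethanol}"


def _treatment_from_row(row: pd.Series, row_id: str) -> Treatment:
    return Treatment(
        wasp_strain=_parse_strain(row["wasp_strain"], row_id),
        spiroplasma=_parse_spiroplasma(row["spiroplasma"], row_id),
        ethanol=_parse_ethanol(row["ethanol"], row_id),
    )


@dataclass(frozen=True)
class VialOutcome:
    """Per-vial emergence counts under one treatment.

    ``block`` names the assay batch (the attacking strain whose experimental
    block the vial belongs to); for exposed vials it defaults to the strain
    itself, for no-wasp controls it may be empty when unknown.
    """

    vial_id: str
    treatment: Treatment
    n_larvae: int
    n_pupae: int
    n_flies: int
    n_wasps: int
    block: str = ""

    def __post_init__(self) -> None:
        for name in ("n_larvae", "n_pupae", "n_flies", "n_wasps"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise RowValidationError(
                    f"vial {self.vial_id!r}: {name}={v!r} must be a non-negative integer"
                )
        if self.n_flies + self.n_wasps > self.n_pupae:
            raise RowValidationError(
                f"vial {self.vial_id!r}: n_flies + n_wasps = "
                f"{self.n_flies + self.n_wasps} exceeds n_pupae = {self.n_pupae}"
            )
        if self.n_pupae > self.n_larvae:
            raise RowValidationError(
                f"vial {self.vial_id!r}: n_pupae = {self.n_pupae} exceeds "
                f"n_larvae = {self.n_larvae}"
            )
        if not self.block and self.treatment.exposed:
            object.__setattr__(self, "block", self.treatment.wasp_strain.value)


@dataclass(frozen=True)
class FemaleFertilityRecord:
    """Per-female daughter production over assay days 2-5.

    A female is fertile iff she produced at least one daughter over the four
    assay days; both ``daughters_total`` and ``fertile`` are derived, never
    stored authority.
    """

    female_id: str
    treatment: Treatment
    daughters_by_day: tuple[int, int, int, int]
    block: str = ""

    def __post_init__(self) -> None:
        if len(self.daughters_by_day) != 4:
            raise RowValidationError(
                f"female {self.female_id!r}: expected 4 daily counts, "
                f"got {len(self.daughters_by_day)}"
            )
        for d in self.daughters_by_day:
            if not isinstance(d, int) or isinstance(d, bool) or d < 0:
                raise RowValidationError(
                    f"female {self.female_id!r}: daily count {d!r} must be a "
                    "non-negative integer"
                )
        object.__setattr__(self, "daughters_by_day", tuple(self.daughters_by_day))
        if not self.block and self.treatment.exposed:
            object.__setattr__(self, "block", self.treatment.wasp_strain.value)

    @property
    def daughters_total(self) -> int:
        return sum(self.daughters_by_day)

    @property
    def fertile(self) -> bool:
        return self.daughters_total > 0

    @property
    def exposure(self) -> str:
        return "exposed" if self.treatment.exposed else "unexposed"


@dataclass(frozen=True)
class WingLandmarks:
    """Six wing-landmark coordinates (pixels) plus a per-image scale."""

    female_id: str
    treatment: Treatment
    coords: tuple[tuple[float, float], ...]
    scale: float  # pixels per millimetre
    block: str = ""

    def __post_init__(self) -> None:
        if len(self.coords) != 6:
            raise RowValidationError(
                f"female {self.female_id!r}: expected 6 landmarks, got {len(self.coords)}"
            )
        object.__setattr__(
            self, "coords", tuple((float(x), float(y)) for x, y in self.coords)
        )
        if not self.scale > 0:
            raise RowValidationError(
                f"female {self.female_id!r}: scale must be positive, got {self.scale}"
            )
        if not self.block and self.treatment.exposed:
            object.__setattr__(self, "block", self.treatment.wasp_strain.value)

    @property
    def exposure(self) -> str:
        return "exposed" if self.treatment.exposed else "unexposed"


@dataclass(frozen=True)
class OvipositionCount:
    """Wasp eggs/larvae counted in one dissected fly larva."""

    larva_id: str
    wasp_strain: WaspStrain
    spiroplasma: bool
    n_eggs_larvae: int

    def __post_init__(self) -> None:
        if not isinstance(self.wasp_strain, WaspStrain):
            object.__setattr__(self, "wasp_strain", WaspStrain(self.wasp_strain))
        if self.wasp_strain is WaspStrain.NONE:
            raise RowValidationError(
                f"larva {self.larva_id!r}: oviposition requires an attacking strain"
            )
        if (
            not isinstance(self.n_eggs_larvae, int)
            or isinstance(self.n_eggs_larvae, bool)
            or self.n_eggs_larvae < 0
        ):
            raise RowValidationError(
                f"larva {self.larva_id!r}: n_eggs_larvae={self.n_eggs_larvae!r} "
                "must be a non-negative integer"
            )


# ---------------------------------------------------------------------------
# readers


def _load_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    return frame


def read_vial_table(path: str | Path) -> list[VialOutcome]:
    """Read and validate ``vials.csv`` into a list of :class:`VialOutcome`."""
    frame = _load_frame(path, VIAL_COLUMNS)
    out = []
    for _, row in frame.iterrows():
        rid = str(row["vial_id"])
        out.append(
            VialOutcome(
                vial_id=rid,
                treatment=_treatment_from_row(row, rid),
                n_larvae=_parse_count(row["n_larvae"], "n_larvae", rid),
                n_pupae=_parse_count(row["n_pupae"], "n_pupae", rid),
                n_flies=_parse_count(row["n_flies"], "n_flies", rid),
                n_wasps=_parse_count(row["n_wasps"], "n_wasps", rid),
                block=str(row.get("block", "") or ""),
            )
        )
    return out


def read_fertility_table(path: str | Path) -> list[FemaleFertilityRecord]:
    """Read ``fertility.csv``; total daughters and the fertile flag are derived.

    If the file carries a stored ``fertile`` column that contradicts the
    derived flag, the derived flag wins and a warning is logged.
    """
    frame = _load_frame(path, FERTILITY_COLUMNS)
    out = []
    for _, row in frame.iterrows():
        rid = str(row["female_id"])
        days = tuple(_parse_count(row[c], c, rid) for c in _DAY_COLUMNS)
        rec = FemaleFertilityRecord(
            female_id=rid,
            treatment=_treatment_from_row(row, rid),
            daughters_by_day=days,  # type: ignore[arg-type]
            block=str(row.get("block", "") or ""),
        )
        if "fertile" in frame.columns:
            stored = str(row["fertile"]).strip().upper() in {"TRUE", "1", "YES"}
            if stored != rec.fertile:
                logger.warning(
                    "female %r: stored fertile=%s contradicts derived %s; "
                    "derived flag wins",
                    rid, stored, rec.fertile,
                )
        out.append(rec)
    return out


def read_wing_table(path: str | Path) -> list[WingLandmarks]:
    """Read ``wings.csv`` into :class:`WingLandmarks` records."""
    frame = _load_frame(path, WING_COLUMNS)
    out = []
    for _, row in frame.iterrows():
        rid = str(row["female_id"])
        try:
            coords = tuple(
                (float(row[f"x{i}"]), float(row[f"y{i}"])) for i in range(1, 7)
            )
            scale = float(row["scale_px_per_mm"])
        except ValueError as exc:
            raise RowValidationError(f"row {rid!r}: non-numeric coordinate ({exc})")
        out.append(
            WingLandmarks(
                female_id=rid,
                treatment=_treatment_from_row(row, rid),
                coords=coords,
                scale=scale,
                block=str(row.get("block", "") or ""),
            )
        )
    return out


def read_oviposition_table(path: str | Path) -> list[OvipositionCount]:
    """Read ``oviposition.csv`` into :class:`OvipositionCount` records."""
    frame = _load_frame(path, OVIPOSITION_COLUMNS)
    out = []
    for _, row in frame.iterrows():
        rid = str(row["larva_id"])
        out.append(
            OvipositionCount(
                larva_id=rid,
                wasp_strain=_parse_strain(row["wasp_strain"], rid),
                spiroplasma=_parse_spiroplasma(row["spiroplasma"], rid),
                n_eggs_larvae=_parse_count(row["n_eggs_larvae"], "n_eggs_larvae", rid),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers


def _treatment_cols(t: Treatment) -> dict[str, str]:
    return {
        "wasp_strain": t.wasp_strain.value,
        "spiroplasma": "S+" if t.spiroplasma else "S-",
        "ethanol": str(t.ethanol),
    }


def _vial_row(v: VialOutcome) -> dict[str, object]:
    return {
        "vial_id": v.vial_id,
        **_treatment_cols(v.treatment),
        "n_larvae": v.n_larvae,
        "n_pupae": v.n_pupae,
        "n_flies": v.n_flies,
        "n_wasps": v.n_wasps,
        "block": v.block,
    }


def _fertility_row(r: FemaleFertilityRecord) -> dict[str, object]:
    row: dict[str, object] = {"female_id": r.female_id, **_treatment_cols(r.treatment)}
    row.update(dict(zip(_DAY_COLUMNS, r.daughters_by_day)))
    row["block"] = r.block
    return row


def _wing_row(w: WingLandmarks) -> dict[str, object]:
    row: dict[str, object] = {"female_id": w.female_id, **_treatment_cols(w.treatment)}
    for i, (x, y) in enumerate(w.coords, start=1):
        row[f"x{i}"] = repr(x)
        row[f"y{i}"] = repr(y)
    row["scale_px_per_mm"] = repr(w.scale)
    row["block"] = w.block
    return row


def _oviposition_row(o: OvipositionCount) -> dict[str, object]:
    return {
        "larva_id": o.larva_id,
        "wasp_strain": o.wasp_strain.value,
        "spiroplasma": "S+" if o.spiroplasma else "S-",
        "n_eggs_larvae": o.n_eggs_larvae,
    }


_WRITERS = {
    VialOutcome: (_vial_row, VIAL_COLUMNS + ["block"]),
    FemaleFertilityRecord: (_fertility_row, FERTILITY_COLUMNS + ["block"]),
    WingLandmarks: (_wing_row, WING_COLUMNS + ["block"]),
    OvipositionCount: (_oviposition_row, OVIPOSITION_COLUMNS),
}


def write_summary_table(records: Iterable[object], path: str | Path) -> None:
    """Write a collection of assay records (or any dataclass rows) to CSV.

    Writing then reading with the corresponding ``read_*_table`` is lossless
    for the four assay table types.  An empty collection of a known type (or
    an empty list) produces a header-only file only when the type is known;
    a plain empty list writes an empty file with the vial header by default.
    """
    path = Path(path)
    records = list(records)
    if records:
        rtype = type(records[0])
        if rtype in _WRITERS:
            row_fn, columns = _WRITERS[rtype]
            frame = pd.DataFrame([row_fn(r) for r in records], columns=columns)
        elif dataclasses.is_dataclass(records[0]):
            frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            frame = pd.DataFrame(records)
    else:
        frame = pd.DataFrame(columns=VIAL_COLUMNS + ["block"])
    frame.to_csv(path, index=False, encoding="utf-8")


def write_empty_table(record_type: type, path: str | Path) -> None:
    """Write a header-only CSV for the given assay record type."""
    _, columns = _WRITERS[record_type]
    pd.DataFrame(columns=columns).to_csv(Path(path), index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# tidy frames for the modelling layer


def vials_frame(vials: Iterable[VialOutcome]) -> pd.DataFrame:
    """Vial records as a tidy frame with one row per vial, for GLM fitting."""
    rows = []
    for v in vials:
        t = v.treatment
        rows.append(
            {
                "vial_id": v.vial_id,
                "block": v.block,
                "wasp_strain": t.wasp_strain.value,
                "exposed": t.exposed,
                "spiroplasma": t.spiroplasma,
                "ethanol": t.ethanol,
                "n_larvae": v.n_larvae,
                "n_pupae": v.n_pupae,
                "n_flies": v.n_flies,
                "n_wasps": v.n_wasps,
            }
        )
    columns = [
        "vial_id", "block", "wasp_strain", "exposed", "spiroplasma", "ethanol",
        "n_larvae", "n_pupae", "n_flies", "n_wasps",
    ]
    return pd.DataFrame(rows, columns=columns)


def fertility_frame(records: Iterable[FemaleFertilityRecord]) -> pd.DataFrame:
    """Fertility records as a tidy frame with derived columns included."""
    rows = []
    for r in records:
        t = r.treatment
        rows.append(
            {
                "female_id": r.female_id,
                "block": r.block,
                "wasp_strain": t.wasp_strain.value,
                "exposure": r.exposure,
                "spiroplasma": t.spiroplasma,
                "ethanol": t.ethanol,
                "daughters_total": r.daughters_total,
                "fertile": r.fertile,
            }
        )
    columns = [
        "female_id", "block", "wasp_strain", "exposure", "spiroplasma",
        "ethanol", "daughters_total", "fertile",
    ]
    return pd.DataFrame(rows, columns=columns)
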