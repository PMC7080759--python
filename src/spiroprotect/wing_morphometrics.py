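"""Wing-size proxy from six landmark coordinates.

Adult wing area tracks body size in Drosophila and serves as a proxy for
developmental stress.  Each wing is summarised by the interior area of the
hexagon traced through six standard landmarks (supplied in boundary order),
converted from pixel units to mm^2 with a per-image pixels-per-mm scale.
The landmarks are treated as an opaque ordered hexagon; no shape analysis
(Procrustes etc.) is attempted, and landmark detection from images is out
of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .experiment_data import WingLandmarks

logger = logging.getLogger(__name__)

__all__ = ["WingAreaResult", "polygon_area", "wing_areas", "summarize_wings"]


@dataclass(frozen=True)
class WingAreaResult:
    """Wing area in pixel^2 and mm^2 (mm^2 = px^2 / scale^2)."""

    female_id: str
    area_px2: float
    area_mm2: float


def polygon_area(
    coords: Sequence[tuple[float, float]],
    scale: float,
    female_id: str = "",
) -> WingAreaResult:
    """Interior (shoelace) area of the six-landmark polygon, in px^2 and mm^2.

    The area is orientation-independent (absolute value of the signed ring
    area).  Duplicate consecutive landmarks merely collapse an edge; fewer
    than three distinct points give zero area with a warning, as does a
    self-intersecting landmark ordering (which the assay would normally
    exclude rather than repair).
    """
    if len(coords) != 6:
        raise ValueError(f"expected six landmark coordinates, got {len(coords)}")
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    distinct = set((float(x), float(y)) for x, y in coords)
    if len(distinct) < 3:
        logger.warning(
            "wing %r: fewer than 3 distinct landmarks; area is zero", female_id
        )
        area_px2 = 0.0
    else:
        poly = Polygon(coords)
        if not poly.is_valid:
            logger.warning(
                "wing %r: self-intersecting landmark ordering; using absolute "
                "signed area", female_id,
            )
        area_px2 = float(poly.area)
    return WingAreaResult(
        female_id=female_id, area_px2=area_px2, area_mm2=area_px2 / scale**2
    )


def wing_areas(records: Iterable[WingLandmarks]) -> list[WingAreaResult]:
    """Areas for a batch of landmark records, using each record's own scale."""
    return [polygon_area(r.coords, r.scale, r.female_id) for r in records]


def summarize_wings(
    results: Iterable[WingAreaResult],
    grouping: Mapping[str, str] | Callable[[str], str],
    control: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means +/- SE and pairwise differences against a control group.

    ``grouping`` maps each female id to a group label.  Groups with fewer
    than two observations are excluded with a warning.  The second frame
    holds, for every non-control group, the control-minus-group mean
    difference (mm^2) and that difference as a percent of the control mean;
    ``control`` defaults to the lexicographically first group.
    """
    label = grouping if callable(grouping) else grouping.__getitem__
    by_group: dict[str, list[float]] = {}
    for r in results:
        by_group.setdefault(label(r.female_id), []).append(r.area_mm2)
    for g in sorted(by_group):
        if len(by_group[g]) < 2:
            logger.warning("wing group %r has <2 observations; excluded", g)
            del by_group[g]
    if len(by_group) < 2:
        raise ValueError("need at least two groups with >= 2 observations each")
    rows = []
    for g in sorted(by_group):
        vals = np.asarray(by_group[g])
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "mean_mm2": float(vals.mean()),
                "se_mm2": float(vals.std(ddof=1) / math.sqrt(len(vals))),
            }
        )
    groups = pd.DataFrame(rows)
    if control is None:
        control = str(groups["group"].iloc[0])
    if control not in set(groups["group"]):
        raise ValueError(f"control group {control!r} not present")
    cmean = float(groups.loc[groups["group"] == control, "mean_mm2"].iloc[0])
    pairs = []
    for _, row in groups.iterrows():
        if row["group"] == control:
            continue
        diff = cmean - row["mean_mm2"]
        pairs.append(
            {
                "group": row["group"],
                "control": control,
                "difference_mm2": diff,
                "percent_of_control": 100.0 * diff / cmean,
            }
        )
    return groups, pd.DataFrame(pairs)
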