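"""District-level validation and gradient summaries.

Valid prediction cells are averaged within game-management districts and
correlated (Spearman) with harvest densities — the only state-wide
abundance-related data available for an indirect check of the predicted
surface.  Districts whose valid prediction area covers less than half of
the district are excluded.  Predicted densities are also summarised along
the climate × land-use gradient of the study design (medians and
quartiles per class; no formal test, since model predictions are smoothed
and not independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .predict import PredictionCell

__all__ = [
    "DistrictRecord",
    "QuadrantClass",
    "gradient_design",
    "aggregate_to_districts",
    "filter_districts",
    "spearman_correlation",
    "gradient_summary",
]

CLIMATE_CLASSES = (1, 2, 3, 4, 5)
LANDSCAPE_TYPES = ("near-natural", "agricultural", "urban")

#: multi-year mean-temperature bins (°C) delimiting the five climate zones
CLIMATE_BINS = (-np.inf, 7.5, 8.0, 8.5, 9.0, np.inf)


@dataclass
class DistrictRecord:
    district_id: str
    area_km2: float
    harvest_density: float               # animals per km²
    mean_density: float                  # mean predicted pellet density over valid cells
    valid_fraction: float                # valid-cell area / district area
    included: bool


@dataclass
class QuadrantClass:
    quadrant_id: str
    climate: int                         # 1 (coldest) … 5 (warmest)
    landscape: str                       # near-natural | agricultural | urban


def climate_class(mean_temp_c: float) -> int:
    """Climate zone 1–5 from multi-year mean temperature."""
    return int(np.digitize(mean_temp_c, CLIMATE_BINS[1:-1]) + 1)


def gradient_design(
    n_climate: int = 5,
    landscapes: tuple[str, ...] = LANDSCAPE_TYPES,
    replicates: int = 4,
) -> pd.DataFrame:
    """The factorial quadrant design: climate × landscape × replicates.

    With the defaults (5 climate zones, 3 landscape types, 4 replicates)
    this enumerates the 60 study quadrants.
    """
    rows = []
    q = 0
    for c in range(1, n_climate + 1):
        for l in landscapes:
            for _ in range(replicates):
                rows.append({"quadrant_id": f"Q{q:03d}", "climate": c, "landscape": l})
                q += 1
    return pd.DataFrame(rows)


def aggregate_to_districts(
    cells: list[PredictionCell],
    district_of_cell: dict[str, str],
    district_info: pd.DataFrame,
) -> list[DistrictRecord]:
    """Average valid-cell predicted densities per district.

    ``district_of_cell`` maps cell id → district id (cell-centre-in-polygon
    assignment, or nearest-seed for synthetic Voronoi districts);
    ``district_info`` is indexed by district id with columns ``area_km2``
    and ``harvest_density``.  The valid-area fraction is the summed area of
    valid cells over the district area; districts with no valid cell get an
    undefined mean and fraction 0.
    """
    dens_sum: dict[str, float] = {d: 0.0 for d in district_info.index}
    valid_area: dict[str, float] = {d: 0.0 for d in district_info.index}
    n_valid: dict[str, int] = {d: 0 for d in district_info.index}
    for c in cells:
        d = district_of_cell.get(c.cell_id)
        if d is None or d not in dens_sum:
            continue
        if c.valid:
            dens_sum[d] += c.abundance / (c.area_m2 / 1e6)   # density per km²
            valid_area[d] += c.area_m2 / 1e6
            n_valid[d] += 1
    out = []
    for d, row in district_info.iterrows():
        area = float(row["area_km2"])
        frac = valid_area[d] / area if area > 0 else 0.0
        mean = dens_sum[d] / n_valid[d] if n_valid[d] > 0 else np.nan
        out.append(DistrictRecord(
            district_id=str(d), area_km2=area,
            harvest_density=float(row["harvest_density"]),
            mean_density=mean, valid_fraction=min(frac, 1.0),
            included=frac >= 0.5,
        ))
    return out


def filter_districts(
    records: list[DistrictRecord],
    min_fraction: float = 0.5,
) -> tuple[list[DistrictRecord], dict[str, int]]:
    """Keep districts whose valid prediction area reaches ``min_fraction``.

    The boundary is inclusive (a district with exactly half its area valid
    is kept).  Returns the included subset and the included/excluded counts.
    """
    for r in records:
        r.included = r.valid_fraction >= min_fraction and np.isfinite(r.mean_density)
    included = [r for r in records if r.included]
    counts = {"included": len(included), "excluded": len(records) - len(included)}
    return included, counts


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-aware average ranks.

    The p-value uses the t approximation.  Constant input is an error
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length ≥ 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def gradient_summary(
    cell_values: pd.DataFrame,
    quadrant_classes: pd.DataFrame,
) -> pd.DataFrame:
    """Median and quartiles of predicted density per climate × landscape class.

    ``cell_values`` needs columns ``quadrant_id`` and ``density`` (one row
    per valid summarised cell); ``quadrant_classes`` columns
    ``quadrant_id``, ``climate``, ``landscape``.  Classes without cells
    appear with n = 0.
    """
    merged = cell_values.merge(quadrant_classes, on="quadrant_id", how="inner")
    rows = []
    for c in sorted(quadrant_classes["climate"].unique()):
        for l in quadrant_classes["landscape"].unique():
            v = merged.loc[(merged["climate"] == c) & (merged["landscape"] == l), "density"]
            rows.append({
                "climate": c, "landscape": l, "n_cells": len(v),
                "median": float(v.median()) if len(v) else np.nan,
                "q1": float(v.quantile(0.25)) if len(v) else np.nan,
                "q3": float(v.quantile(0.75)) if len(v) else np.nan,
            })
    return pd.DataFrame(rows)
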