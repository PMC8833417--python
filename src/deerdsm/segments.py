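"""Transect segmentation, strip-area offsets and buffered covariates.

Transects are cut at the ground-cover transition points recorded during the
survey, so each segment is homogeneous in ground cover; the segment strip
area A = 2·w·l is the offset of the second-stage density regression.  Each
segment centroid is buffered with a 500-m disk (an average roe deer monthly
home range simplified as a circle) and landscape covariates are summarised
over the disk — means for continuous grids, percentage cover for fraction
grids.  Covariates entering the regression are screened for pairwise
collinearity (|Pearson r| > 0.7), keeping the ecologically higher-priority
member of each conflicting pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CovariateGrid
from .synthetic import TransectRecord

__all__ = [
    "SegmentRecord",
    "build_segments",
    "segment_area",
    "extract_buffer_covariates",
    "reclassify_landcover",
    "filter_collinear",
    "segments_to_frame",
]


@dataclass
class SegmentRecord:
    segment_id: str
    transect_id: str
    start_m: float
    end_m: float
    length: float
    x: float       # centroid
    y: float
    ground_cover: str
    covariates: dict[str, float] = field(default_factory=dict)

    def area(self, w: float) -> float:
        return segment_area(self.length, w)


def segment_area(length: float, w: float) -> float:
    """Strip area 2·w·l of a segment surveyed to half-width w (m²)."""
    if w <= 0:
        raise ValueError("half-width must be positive")
    return 2.0 * w * length


def build_segments(
    transects: list[TransectRecord],
    sections: pd.DataFrame,
) -> list[SegmentRecord]:
    """Partition each transect into homogeneous segments.

    ``sections`` holds one row per homogeneous ground-cover stretch
    (transect_id, start_m, end_m, ground_cover), as produced by the survey
    simulator or transcribed from field notes; transects absent from the
    table become a single segment.  Segment lengths always sum exactly to
    the transect length.
    """
    by_tr = {t.id: t for t in transects}
    out: list[SegmentRecord] = []
    grouped = dict(tuple(sections.groupby("transect_id"))) if len(sections) else {}
    for tr in transects:
        rows = grouped.get(tr.id)
        if rows is None or len(rows) == 0:
            pieces = [(0.0, tr.length, "grass_forb")]
        else:
            rows = rows.sort_values("start_m")
            if rows["end_m"].max() > tr.length + 1e-6:
                raise ValueError(f"section beyond the end of transect {tr.id}")
            pieces = list(zip(rows["start_m"], rows["end_m"], rows["ground_cover"]))
            # force an exact partition of [0, length]
            if abs(pieces[-1][1] - tr.length) > 1e-9:
                a, _, c = pieces[-1]
                pieces[-1] = (a, tr.length, c)
        for k, (a, b, gc) in enumerate(pieces):
            mid = 0.5 * (a + b)
            x, y = tr.point_at(mid)
            out.append(SegmentRecord(
                segment_id=f"{tr.id}-s{k:02d}", transect_id=tr.id,
                start_m=float(a), end_m=float(b), length=float(b - a),
                x=x, y=y, ground_cover=str(gc),
            ))
    # sanity: conservation of effort
    tot_seg = sum(s.length for s in out)
    tot_tr = sum(t.length for t in by_tr.values())
    if abs(tot_seg - tot_tr) > 1e-6 * max(tot_tr, 1.0):
        raise AssertionError("segments do not partition the transects")
    return out


def extract_buffer_covariates(
    segments: list[SegmentRecord],
    grids: dict[str, CovariateGrid],
    radius: float = 500.0,
) -> pd.DataFrame:
    """Summarise each grid over a disk of ``radius`` around each centroid.

    A cell belongs to the buffer iff its centre lies within the radius of
    the segment centroid.  Continuous grids contribute the mean cell value;
    fraction grids the percentage cover (mean fraction × 100).  Results are
    written into each segment's ``covariates`` dict and returned as a table.
    """
    if not grids:
        raise ValueError("no grids supplied")
    ref = next(iter(grids.values()))
    X, Y = ref.cell_centers()
    for g in grids.values():
        if not g.compatible_with(ref):
            raise ValueError(f"grid {g.name!r} not aligned with {ref.name!r}")
    x0, y0 = ref.origin
    wid, hei = ref.extent
    rows = []
    for seg in segments:
        if not (x0 - radius <= seg.x <= x0 + wid + radius and y0 - radius <= seg.y <= y0 + hei + radius):
            raise ValueError(f"buffer of segment {seg.segment_id} outside the grid extent")
        mask = (X - seg.x) ** 2 + (Y - seg.y) ** 2 <= radius**2
        if not mask.any():
            raise ValueError(f"buffer of segment {seg.segment_id} covers no cell centre")
        vals = {}
        for name, g in grids.items():
            m = float(g.values[mask].mean())
            vals[name] = 100.0 * m if g.kind == "fraction" else m
        seg.covariates.update(vals)
        rows.append({"segment_id": seg.segment_id, **vals})
    return pd.DataFrame(rows).set_index("segment_id")


def reclassify_landcover(
    raw: dict[str, CovariateGrid],
    mapping: dict[str, str],
) -> dict[str, CovariateGrid]:
    """Aggregate raw land-cover fraction grids into target classes.

    ``mapping`` sends each raw class name to a target class (e.g. a CORINE
    level-2 class to one of coniferous / deciduous_and_mixed / arable /
    grass_and_shrubs / artificial / water).  Target fractions are sums of
    their raw members, so per-cell compositional closure is preserved.
    """
    missing = [k for k in raw if k not in mapping]
    if missing:
        raise ValueError(f"unmapped raw classes: {missing}")
    ref = next(iter(raw.values()))
    out_vals: dict[str, np.ndarray] = {}
    for rname, g in raw.items():
        t = mapping[rname]
        out_vals[t] = out_vals.get(t, np.zeros(ref.shape)) + g.values
    return {
        t: CovariateGrid(name=t, kind="fraction", resolution=ref.resolution,
                         origin=ref.origin, values=np.clip(v, 0.0, 1.0))
        for t, v in out_vals.items()
    }


def filter_collinear(
    table: pd.DataFrame,
    priority: list[str],
    r_threshold: float = 0.7,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one of each pair of collinear covariates (|Pearson r| > threshold).

    ``priority`` orders the candidate covariates most-ecologically-relevant
    first and must contain each column exactly once.  Conflicting pairs are
    processed in descending |r|; the lower-priority member is dropped and
    remaining pairs re-checked.  Zero-variance columns are dropped with a
    warning.  Returns the retained names (in priority order) and a drop log.
    """
    cols = list(table.columns)
    if sorted(priority) != sorted(cols):
        raise ValueError("priority list must contain every covariate exactly once")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    rank = {c: i for i, c in enumerate(priority)}
    log: list[dict] = []
    active = [c for c in priority]
    for c in list(active):
        if float(table[c].std()) == 0.0:
            warnings.warn(f"zero-variance covariate {c!r} dropped", stacklevel=2)
            active.remove(c)
            log.append({"dropped": c, "kept": "", "r": np.nan, "reason": "zero variance"})
    while True:
        sub = table[active]
        r = sub.corr().to_numpy()
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(r)), r.shape) if len(active) > 1 else (0, 0)
        if len(active) < 2 or abs(r[i, j]) <= r_threshold:
            break
        a, b = active[i], active[j]
        drop, keep = (b, a) if rank[a] < rank[b] else (a, b)
        active.remove(drop)
        log.append({"dropped": drop, "kept": keep, "r": float(r[i, j]), "reason": "collinear"})
    return active, pd.DataFrame(log, columns=["dropped", "kept", "r", "reason"])


def segments_to_frame(segments: list[SegmentRecord], w: float) -> pd.DataFrame:
    """Flat table of segments with area offsets and covariates."""
    rows = []
    for s in segments:
        rows.append({
            "segment_id": s.segment_id, "transect_id": s.transect_id,
            "start_m": s.start_m, "end_m": s.end_m, "length_m": s.length,
            "area_m2": s.area(w), "x": s.x, "y": s.y,
            "cover_class": s.ground_cover, **s.covariates,
        })
    return pd.DataFrame(rows)
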