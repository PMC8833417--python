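"""End-to-end pipeline driver: simulate → detect → segment → fit →
predict → evaluate → validate.

Each stage is a standalone function over explicit inputs so it can be run
(and tested) on its own; :func:`run_pipeline` chains them on a synthetic
survey, logging parameters and row counts, and writes every artifact as
text (CSV / GeoJSON / ASCII grid / YAML).  Identical config + seed gives
identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection as det
from . import dsm as dsm_mod
from . import extrapolation as ex
from . import io as io_mod
from . import predict as pred
from . import segments as seg_mod
from . import synthetic as syn
from . import validation as val
from .config import PipelineConfig
from .grids import CovariateGrid, write_ascii_grid

__all__ = ["run_pipeline", "PipelineResult", "classify_quadrants", "total_effort_km"]

log = logging.getLogger("deerdsm")


def total_effort_km(n_transects: int, transect_length_m: float) -> float:
    """Total survey effort in km (e.g. 512 × 200 m → 102.4 km)."""
    return n_transects * transect_length_m / 1000.0


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: syn.TruthSurface
    transects: list
    obs: pd.DataFrame
    detection_fit: det.DetectionFit
    p_bar: float
    p_bar_cv: float
    gof: det.GofResult | None
    segments: list
    covariate_table: pd.DataFrame
    retained_covariates: list[str]
    dsm_fits: dict
    selected_dsm: dsm_mod.DSMFit
    comparison: pd.DataFrame
    cells: list
    class_summary: pd.DataFrame
    districts: list
    spearman: tuple[float, float]
    gradient: pd.DataFrame
    artifacts: dict[str, str] = field(default_factory=dict)


def _observer_spec(cfg: PipelineConfig) -> syn.DetectionSpec:
    factors = np.linspace(0.75, 1.3, cfg.n_observers)
    return syn.DetectionSpec(
        key=cfg.true_key, sigma0=cfg.true_sigma_m, shape_b=2.5,
        observer_effects={f"obs{k + 1}": float(f) for k, f in enumerate(factors)},
        w_gen=2.0,
    )


def stage_simulate(cfg: PipelineConfig):
    """Landscape, truth surface, survey design and observation table."""
    n_cells = int(round(cfg.landscape_km * 1000 / cfg.resolution_m))
    spec = syn.default_landscape_spec(resolution=cfg.resolution_m, nx=n_cells, ny=n_cells)
    grids = syn.generate_landscape(spec, seed=cfg.seed)
    truth = syn.generate_truth(grids, syn.default_effects())
    design = syn.SurveyDesignSpec(
        mode="designed", n_transects=cfg.n_designed_transects,
        woodland_effort=cfg.woodland_effort,
    )
    transects = syn.design_survey(grids, design, seed=cfg.seed + 1)
    if cfg.n_plot_quadrants > 0:
        rng = np.random.default_rng(cfg.seed + 2)
        ext = cfg.landscape_km * 1000.0
        centers = tuple(
            (float(rng.uniform(0.05 * ext, 0.95 * ext)), float(rng.uniform(0.05 * ext, 0.95 * ext)))
            for _ in range(cfg.n_plot_quadrants)
        )
        undes = syn.design_survey(
            grids,
            syn.SurveyDesignSpec(mode="undesigned", plot_centers=centers),
            seed=cfg.seed + 3,
        )
        transects = transects + undes
    detspec = _observer_spec(cfg)
    obs, true_counts, sections = syn.simulate_observations(
        truth, transects, detspec, seed=cfg.seed + 4, grids=grids, season=cfg.season,
    )
    log.info("simulate: %d transects, %d generated, %d detected",
             len(transects), true_counts["n_true"].sum(), len(obs))
    return grids, truth, transects, obs, true_counts, sections


def stage_detect(cfg: PipelineConfig, obs: pd.DataFrame, effort_per_observer: dict[str, float]):
    """Truncation, observer grouping, candidate MCDS fits, selection, GOF."""
    obs_t, n_disc = det.truncate_distances(obs, cfg.truncation_m)
    log.info("detect: truncated at %.2f m, %d discarded / %d recorded",
             cfg.truncation_m, n_disc, len(obs))
    obs_t = det.assign_observer_groups(obs_t, effort_per_observer, cfg.min_group_detections)
    fits = []
    for key in cfg.candidate_keys:
        fits.append(det.fit_detection_function(obs_t, key=key, w=cfg.truncation_m))
        for adj in cfg.candidate_adjustments:
            fits.append(det.fit_detection_function(obs_t, key=key, adjustment=adj, w=cfg.truncation_m))
        for cov in cfg.detection_covariates:
            fits.append(det.fit_detection_function(obs_t, key=key, covariates=(cov,), w=cfg.truncation_m))
    best = det.select_detection_model(fits)
    p_bar, p_cv = det.average_detection_probability(best, obs_t)
    gof = None
    if cfg.cvm_bootstrap > 0:
        gof = det.cvm_goodness_of_fit(best, obs_t, n_boot=cfg.cvm_bootstrap, seed=cfg.seed + 5)
    log.info("detect: best %s/%s cov=%s, p_bar=%.3f (cv %.3f)",
             best.key, best.adjustment or "none", best.covariates, p_bar, p_cv)
    return obs_t, fits, best, p_bar, p_cv, gof


#: ecological priority of the synthetic covariate roster, most relevant
#: first (climate and habitat before terrain-like proxies)
DEFAULT_PRIORITY = [
    "coniferous", "deciduous_and_mixed", "arable", "grass_and_shrubs",
    "artificial", "water", "private_forest", "state_forest", "corporate_forest",
    "win_mean_temp", "win_temp_range", "spr_temp_range", "spr_acc_precip",
    "edge_proximity",
]


def stage_segment(cfg: PipelineConfig, transects, sections, grids):
    """Segmentation, buffered covariates and collinearity screening."""
    segments = seg_mod.build_segments(transects, sections)
    covtable = seg_mod.extract_buffer_covariates(segments, grids, radius=cfg.buffer_radius_m)
    priority = [c for c in DEFAULT_PRIORITY if c in covtable.columns]
    priority += [c for c in covtable.columns if c not in priority]
    retained, droplog = seg_mod.filter_collinear(covtable, priority, cfg.r_threshold)
    log.info("segment: %d segments, %d/%d covariates retained",
             len(segments), len(retained), covtable.shape[1])
    return segments, covtable, retained, droplog


def stage_dsm(cfg: PipelineConfig, obs_t, best_fit, segments, covtable, retained):
    """HT segment abundances, family candidates, backward selection."""
    ab = dsm_mod.ht_segment_abundance(obs_t, best_fit, segments, cfg.truncation_m)
    fits = {}
    for family in ("tweedie", "negative_binomial"):
        full = dsm_mod.fit_dsm(ab, covtable[retained], family=family,
                               basis_df=cfg.basis_df, season=cfg.season)
        sel, removed = dsm_mod.backward_select(full, alpha=cfg.alpha)
        fits[family] = sel
        log.info("dsm[%s]: removed %s; aic=%.2f, %%dev=%.1f",
                 family, removed, sel.aic, sel.pct_deviance)
    comparison = dsm_mod.compare_dsm(list(fits.values()))
    best_family = comparison.loc[comparison["best"], "family"].iloc[0]
    return ab, fits, fits[best_family], comparison


def prediction_grid_covariates(cfg: PipelineConfig, grids: dict[str, CovariateGrid]) -> pd.DataFrame:
    """Cell-centre covariates of the regular prediction grid, extracted
    with the same buffer rule as the training segments."""
    ref = next(iter(grids.values()))
    cell_m = cfg.grid_cell_km * 1000.0
    wid, hei = ref.extent
    nx = int(wid // cell_m)
    ny = int(hei // cell_m)
    rows = []
    pseudo = []
    for iy in range(ny):
        for ix in range(nx):
            cx = ref.origin[0] + (ix + 0.5) * cell_m
            cy = ref.origin[1] + (iy + 0.5) * cell_m
            pseudo.append(seg_mod.SegmentRecord(
                segment_id=f"cell_{ix}_{iy}", transect_id="grid",
                start_m=0, end_m=1, length=1, x=cx, y=cy, ground_cover="",
            ))
            rows.append({"cell_id": f"cell_{ix}_{iy}", "x": cx, "y": cy})
    table = seg_mod.extract_buffer_covariates(pseudo, grids, radius=cfg.buffer_radius_m)
    out = pd.DataFrame(rows).set_index("cell_id")
    return out.join(table).reset_index()


def stage_predict(cfg: PipelineConfig, fit: dsm_mod.DSMFit, grids, cv_detection: float):
    grid_cov = prediction_grid_covariates(cfg, grids)
    cells = pred.predict_grid(fit, grid_cov, cell_area=(cfg.grid_cell_km * 1000.0) ** 2)
    pred.cell_cv(cells, cv_detection)
    log.info("predict: %d cells, mean abundance %.0f", len(cells),
             float(np.mean([c.abundance for c in cells])))
    return cells, grid_cov


def stage_evaluate(cfg: PipelineConfig, cells, reference: pd.DataFrame):
    target = pd.DataFrame([c.covariates for c in cells])[reference.columns]
    exres = ex.exdet_classify(reference, target)
    near = ex.percent_data_nearby(reference, target)
    for c, cl, pn in zip(cells, exres.classes, near.pct_nearby):
        c.exdet_class = str(cl)
        c.pct_nearby = float(pn)
    mask = ex.apply_discard_rule(cells, cfg.nearby_threshold_pct, strict=cfg.strict_discard)
    summary = ex.class_summary(cells)
    log.info("evaluate: %s; %d/%d cells valid",
             summary.to_dict("records"), int(mask.sum()), len(cells))
    return exres, near, mask, summary


def _voronoi_districts(cfg: PipelineConfig, cells, rng: np.random.Generator):
    """Synthetic game-management districts: Voronoi cells around random
    seeds, with harvest densities tied (noisily) to true mean density."""
    ext = cfg.landscape_km * 1000.0
    seeds = rng.uniform(0, ext, size=(cfg.n_districts, 2))
    xy = np.array([[c.x, c.y] for c in cells])
    d2 = ((xy[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    district_of_cell = {c.cell_id: f"d{k:03d}" for c, k in zip(cells, assign)}
    return district_of_cell, seeds, assign


def district_polygons(seeds: np.ndarray, extent_m: float) -> dict[str, list[tuple[float, float]]]:
    """Voronoi polygons of the district seeds, clipped to the landscape box."""
    from shapely.geometry import MultiPoint, Point, box
    from shapely.ops import voronoi_diagram

    bbox = box(0.0, 0.0, extent_m, extent_m)
    cells = voronoi_diagram(MultiPoint([tuple(s) for s in seeds]), envelope=bbox)
    out: dict[str, list[tuple[float, float]]] = {}
    for geom in cells.geoms:
        poly = geom.intersection(bbox)
        for k, s in enumerate(seeds):
            if poly.contains(Point(*s)):
                out[f"d{k:03d}"] = [(float(x), float(y)) for x, y in poly.exterior.coords]
                break
    return out


def stage_validate(cfg: PipelineConfig, cells, truth: syn.TruthSurface, grids):
    rng = np.random.default_rng(cfg.seed + 6)
    district_of_cell, seeds, assign = _voronoi_districts(cfg, cells, rng)
    cell_area_km2 = (cfg.grid_cell_km) ** 2
    # true mean pellet density per district drives the synthetic harvest
    true_dens = np.array([
        float(truth.intensity_at(c.x, c.y)) * 1e6 for c in cells  # per km²
    ])
    info_rows = []
    for k in range(cfg.n_districts):
        m = assign == k
        if not m.any():
            continue
        base = float(np.mean(true_dens[m]))
        harvest = 1.5e-3 * base * float(rng.lognormal(0.0, 0.35))
        info_rows.append({"district_id": f"d{k:03d}",
                          "area_km2": float(m.sum() * cell_area_km2),
                          "harvest_density": harvest})
    info = pd.DataFrame(info_rows).set_index("district_id")
    records = val.aggregate_to_districts(cells, district_of_cell, info)
    included, counts = val.filter_districts(records, cfg.min_valid_fraction)
    log.info("validate: %d districts included, %d excluded",
             counts["included"], counts["excluded"])
    if len(included) >= 3:
        rho, p = val.spearman_correlation(
            [r.mean_density for r in included], [r.harvest_density for r in included])
    else:
        rho, p = float("nan"), float("nan")
    quad = classify_quadrants(cfg, grids)
    cellvals = pd.DataFrame([
        {"quadrant_id": _quadrant_of(cfg, c.x, c.y),
         "density": c.abundance / ((c.area_m2) / 1e6)}
        for c in cells if c.valid
    ])
    gradient = val.gradient_summary(cellvals, quad) if len(cellvals) else pd.DataFrame()
    return records, included, (rho, p), gradient, district_of_cell, seeds


_QUAD_KM = 4.0  # quadrant tile edge in the synthetic world


def _quadrant_of(cfg: PipelineConfig, x: float, y: float) -> str:
    qm = _QUAD_KM * 1000.0
    nq = int(cfg.landscape_km / _QUAD_KM)
    ix = min(int(x // qm), nq - 1)
    iy = min(int(y // qm), nq - 1)
    return f"q{iy * nq + ix:03d}"


def classify_quadrants(cfg: PipelineConfig, grids) -> pd.DataFrame:
    """Classify synthetic quadrant tiles along the climate × land-use
    gradient: climate class by quintile of mean winter temperature,
    landscape type by dominant land-use shares (near-natural ≥ 50% forest
    or ≥ 85% near-natural cover; agricultural > 40% arable+grass; urban >
    14% artificial)."""
    qm = _QUAD_KM * 1000.0
    nq = int(cfg.landscape_km / _QUAD_KM)
    ref = next(iter(grids.values()))
    X, Y = ref.cell_centers()
    rows = []
    temps = []
    for iy in range(nq):
        for ix in range(nq):
            m = ((X >= ix * qm) & (X < (ix + 1) * qm) & (Y >= iy * qm) & (Y < (iy + 1) * qm))
            forest = float((grids["coniferous"].values[m] + grids["deciduous_and_mixed"].values[m]).mean())
            agri = float((grids["arable"].values[m] + grids["grass_and_shrubs"].values[m]).mean())
            art = float(grids["artificial"].values[m].mean())
            if art > 0.14:
                landscape = "urban"
            elif agri > 0.40:
                landscape = "agricultural"
            elif forest >= 0.50:
                landscape = "near-natural"
            else:
                landscape = "agricultural" if agri >= forest else "near-natural"
            t = float(grids["win_mean_temp"].values[m].mean())
            temps.append(t)
            rows.append({"quadrant_id": f"q{iy * nq + ix:03d}", "landscape": landscape, "_t": t})
    out = pd.DataFrame(rows)
    out["climate"] = pd.qcut(out["_t"], 5, labels=False, duplicates="drop") + 1
    return out.drop(columns="_t")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on a synthetic survey and write all artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        cfg.to_yaml(outdir / "config_resolved.yaml")
        log.info("config: %s", cfg.model_dump())

        grids, truth, transects, obs, true_counts, sections = stage_simulate(cfg)
        effort = true_counts.groupby("observer")["effort_m"].sum().to_dict()
        obs.to_csv(outdir / "observations.csv", index=False)
        true_counts.to_csv(outdir / "true_counts.csv", index=False)
        sections.to_csv(outdir / "sections.csv", index=False)
        io_mod.write_transects_geojson(transects, outdir / "transects.geojson")
        write_ascii_grid(CovariateGrid("lambda", "continuous", truth.resolution,
                                       truth.origin, truth.lam), outdir / "truth_lambda.asc")
        io_mod.write_effects_yaml(truth, outdir / "truth_effects.yaml")

        obs_t, fits, best, p_bar, p_cv, gof = stage_detect(cfg, obs, effort)
        det.aic_ladder(fits).to_csv(outdir / "detection_aic_ladder.csv", index=False)

        segments, covtable, retained, droplog = stage_segment(cfg, transects, sections, grids)
        seg_mod.segments_to_frame(segments, cfg.truncation_m).to_csv(outdir / "segments.csv", index=False)
        droplog.to_csv(outdir / "collinearity_drops.csv", index=False)

        ab, dsm_fits, selected, comparison = stage_dsm(cfg, obs_t, best, segments, covtable, retained)
        comparison.to_csv(outdir / "dsm_comparison.csv", index=False)

        cells, grid_cov = stage_predict(cfg, selected, grids, p_cv)
        reference = selected._covars[selected.term_names] if selected.terms else covtable[retained]
        exres, near, mask, summary = stage_evaluate(cfg, cells, reference)
        summary.to_csv(outdir / "extrapolation_summary.csv", index=False)

        records, included, (rho, p), gradient, district_of_cell, seeds = stage_validate(cfg, cells, truth, grids)
        pred.cells_to_frame(cells).to_csv(outdir / "prediction_cells.csv", index=False)
        dist_df = pd.DataFrame([{
            "district_id": r.district_id, "area_km2": r.area_km2,
            "harvest_density": r.harvest_density, "mean_density": r.mean_density,
            "valid_fraction": r.valid_fraction, "included": r.included,
        } for r in records]).set_index("district_id")
        dist_df.reset_index().to_csv(outdir / "districts.csv", index=False)
        io_mod.write_districts_geojson(
            district_polygons(seeds, cfg.landscape_km * 1000.0),
            dist_df[["harvest_density", "valid_fraction"]],
            outdir / "districts.geojson")
        if len(gradient):
            gradient.to_csv(outdir / "gradient_summary.csv", index=False)
        (outdir / "correlation.txt").write_text(
            f"spearman_rho {rho:.4f}\np_value {p:.4g}\nn_districts {len(included)}\n")
        log.info("validate: spearman rho=%.3f p=%.3g", rho, p)

        return PipelineResult(
            config=cfg, truth=truth, transects=transects, obs=obs_t,
            detection_fit=best, p_bar=p_bar, p_bar_cv=p_cv, gof=gof,
            segments=segments, covariate_table=covtable, retained_covariates=retained,
            dsm_fits=dsm_fits, selected_dsm=selected, comparison=comparison,
            cells=cells, class_summary=summary, districts=records,
            spearman=(rho, p), gradient=gradient,
            artifacts={p.name: str(p) for p in outdir.iterdir()},
        )
    finally:
        log.removeHandler(fh)
        fh.close()
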