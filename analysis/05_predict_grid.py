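"""Predict pellet-group abundance on the 1-km² grid with uncertainty.

Evaluates the selected density surface on a regular grid whose covariates
come from the same 500-m buffer rule as the training segments, attaches
delta-method CVs (detection ⊕ regression), and bins the surface into
seven abundance quantiles.  Writes the cell table and rasters under
results/05_prediction/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import get_config

from deerdsm.grids import CovariateGrid, write_ascii_grid
from deerdsm.pipeline import (
    stage_detect,
    stage_dsm,
    stage_predict,
    stage_segment,
    stage_simulate,
)
from deerdsm.predict import cells_to_frame


def main() -> None:
    cfg = get_config("05_prediction")
    grids, truth, transects, obs, true_counts, sections = stage_simulate(cfg)
    effort = true_counts.groupby("observer")["effort_m"].sum().to_dict()
    obs_t, fits, best, p_bar, p_cv, gof = stage_detect(cfg, obs, effort)
    segments, covtable, retained, _ = stage_segment(cfg, transects, sections, grids)
    ab, dsm_fits, selected, comparison = stage_dsm(cfg, obs_t, best, segments, covtable, retained)
    cells, grid_cov = stage_predict(cfg, selected, grids, p_cv)
    out = Path(cfg.outdir)

    table = cells_to_frame(cells)
    table.to_csv(out / "prediction_cells.csv", index=False)

    # rasterise abundance, CV and the 7-quantile class map
    n = int(cfg.landscape_km / cfg.grid_cell_km)
    cell_m = cfg.grid_cell_km * 1000.0
    abun = table["abundance"].to_numpy().reshape(n, n)
    cv = table["cv"].to_numpy().reshape(n, n)
    quantile_bins = np.quantile(abun, np.linspace(0, 1, 8)[1:-1])
    classes = 1.0 + np.digitize(abun, quantile_bins)
    for name, vals in (("abundance", abun), ("cv", cv), ("quantile_class", classes)):
        write_ascii_grid(CovariateGrid(name, "continuous", cell_m, (0.0, 0.0), vals),
                         out / f"{name}.asc")

    dens = table["abundance"] / (cfg.grid_cell_km**2)
    q1, q3 = dens.quantile([0.25, 0.75])
    print(f"{len(cells)} cells of {cfg.grid_cell_km:.0f} km²")
    print(f"predicted density: mean {dens.mean():,.0f} /km², "
          f"IQR {q1:,.0f}–{q3:,.0f} /km²")
    true_mean = truth.lam.mean() * 1e6
    print(f"true mean density: {true_mean:,.0f} /km² "
          f"(ratio predicted/true = {dens.mean() / true_mean:.2f})")
    print(f"per-cell total CV: median {table['cv'].median():.3f} "
          f"(detection component {p_cv:.3f})")
    print(f"artifacts -> {out}")


if __name__ == "__main__":
    main()
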