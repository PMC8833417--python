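"""Quantify extrapolation: ExDet classes, %N support and the discard rule.

Classifies every prediction cell against the training-segment covariate
cloud (analogue / combinatorial / univariate), computes the percentage of
reference data within the mean-Gower-distance radius, and masks cells that
extrapolate or lack support (%N < 5).  Writes the class summary, validity
mask and most-influential-covariate table under results/06_extrapolation/.
"""

import sys
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import get_config

from deerdsm.grids import CovariateGrid, write_ascii_grid
from deerdsm.pipeline import (
    stage_detect,
    stage_dsm,
    stage_evaluate,
    stage_predict,
    stage_segment,
    stage_simulate,
)
from deerdsm.predict import cells_to_frame


def main() -> None:
    cfg = get_config("06_extrapolation")
    grids, truth, transects, obs, true_counts, sections = stage_simulate(cfg)
    effort = true_counts.groupby("observer")["effort_m"].sum().to_dict()
    obs_t, fits, best, p_bar, p_cv, gof = stage_detect(cfg, obs, effort)
    segments, covtable, retained, _ = stage_segment(cfg, transects, sections, grids)
    ab, dsm_fits, selected, comparison = stage_dsm(cfg, obs_t, best, segments, covtable, retained)
    cells, grid_cov = stage_predict(cfg, selected, grids, p_cv)
    reference = selected._covars[selected.term_names]
    exres, near, mask, summary = stage_evaluate(cfg, cells, reference)
    out = Path(cfg.outdir)

    summary.to_csv(out / "class_summary.csv", index=False)
    cells_to_frame(cells).to_csv(out / "cells_evaluated.csv", index=False)
    mic = Counter(m for m, c in zip(exres.mic, exres.classes) if c == "univariate")
    pd.DataFrame(sorted(mic.items(), key=lambda kv: -kv[1]),
                 columns=["covariate", "n_univariate_cells"]).to_csv(
        out / "most_influential_covariates.csv", index=False)

    n = int(cfg.landscape_km / cfg.grid_cell_km)
    cell_m = cfg.grid_cell_km * 1000.0
    write_ascii_grid(CovariateGrid("valid", "continuous", cell_m, (0.0, 0.0),
                                   mask.astype(float).reshape(n, n)), out / "validity_mask.asc")
    write_ascii_grid(CovariateGrid("pct_nearby", "continuous", cell_m, (0.0, 0.0),
                                   near.pct_nearby.reshape(n, n)), out / "pct_nearby.asc")

    print("extrapolation classes:")
    print(summary.to_string(index=False))
    print(f"%N: Gower radius {near.threshold:.4f}; "
          f"median support {np.median(near.pct_nearby):.1f}% of reference data")
    if mic:
        print(f"most influential covariate in univariate cells: "
              f"{mic.most_common(1)[0][0]} ({mic.most_common(1)[0][1]} cells)")
    print(f"discard rule ({'strict' if cfg.strict_discard else 'loose'}, "
          f"%N ≥ {cfg.nearby_threshold_pct:g}): "
          f"{mask.sum()}/{len(cells)} cells valid ({mask.mean():.1%})")
    print(f"artifacts -> {out}")


if __name__ == "__main__":
    main()
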