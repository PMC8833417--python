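"""Simulate the synthetic pellet-group survey.

Generates a 20 × 20 km landscape of habitat/climate/management covariates,
a true pellet-group intensity surface, a stratified designed survey (75%
woodland effort) plus plot-centred undesigned transects, and the thinned
observation table.  Writes the observation CSV, transect GeoJSON, ground-
cover sections and the truth rasters under results/01_survey/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import get_config

from deerdsm.grids import CovariateGrid, write_ascii_grid
from deerdsm.io import write_effects_yaml, write_transects_geojson
from deerdsm.pipeline import stage_simulate, total_effort_km


def main() -> None:
    cfg = get_config("01_survey")
    grids, truth, transects, obs, true_counts, sections = stage_simulate(cfg)
    out = Path(cfg.outdir)

    obs.to_csv(out / "observations.csv", index=False)
    true_counts.to_csv(out / "true_counts.csv", index=False)
    sections.to_csv(out / "sections.csv", index=False)
    write_transects_geojson(transects, out / "transects.geojson")
    for name, g in grids.items():
        write_ascii_grid(g, out / f"grid_{g.kind}_{name}.asc")
    write_ascii_grid(CovariateGrid("lambda", "continuous", truth.resolution,
                                   truth.origin, truth.lam), out / "truth_lambda.asc")
    write_effects_yaml(truth, out / "truth_effects.yaml")

    n_designed = sum(t.design == "designed" for t in transects)
    wood = sum(t.length for t in transects if t.design == "designed" and t.stratum == "woodland")
    designed_len = sum(t.length for t in transects if t.design == "designed")
    print(f"landscape: {cfg.landscape_km:.0f} km x {cfg.landscape_km:.0f} km, "
          f"{len(grids)} covariate grids")
    print(f"true expected total: {truth.expected_total:,.0f} pellet groups")
    print(f"transects: {len(transects)} ({n_designed} designed, "
          f"{len(transects) - n_designed} undesigned); "
          f"effort {total_effort_km(len(transects), 200.0):.1f} km")
    print(f"designed woodland effort share: {100 * wood / designed_len:.1f}%")
    print(f"detections: {len(obs)} of {true_counts['n_true'].sum()} generated "
          f"pellet groups ({true_counts['n_true'].sum() and len(obs) / true_counts['n_true'].sum():.0%})")
    print(f"artifacts -> {out}")


if __name__ == "__main__":
    main()
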