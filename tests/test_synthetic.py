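"""The survey generator: seeded reproducibility, compositional closure,
spatial correlation, effort stratification and thinned-Poisson counts."""

import math

import numpy as np
import pandas as pd
import pytest

from deerdsm.detection import half_normal_pbar
from deerdsm.synthetic import (
    CompositionalFamilySpec,
    ContinuousFieldSpec,
    DetectionSpec,
    EffectSpec,
    LandscapeSpec,
    SurveyDesignSpec,
    TransectRecord,
    default_landscape_spec,
    design_survey,
    generate_landscape,
    generate_truth,
    simulate_observations,
)

FRACTION_CLASSES = ("coniferous", "deciduous_and_mixed", "arable",
                    "grass_and_shrubs", "artificial", "water")


class TestGenerateLandscape:
    def test_seed_reproducibility(self):
        spec = default_landscape_spec(nx=20, ny=20)
        a = generate_landscape(spec, seed=3)
        b = generate_landscape(spec, seed=3)
        for name in a:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_single_class_family_is_one_everywhere(self):
        spec = LandscapeSpec(nx=10, ny=10, families=(
            CompositionalFamilySpec("lc", ("only",), correlation_scale_m=500.0),
        ))
        grids = generate_landscape(spec, seed=0)
        np.testing.assert_allclose(grids["only"].values, 1.0)

    def test_compositional_sums_bounded(self, landscape):
        total = sum(landscape[c].values for c in FRACTION_CLASSES)
        assert np.all(total <= 1 + 1e-9)
        owner = sum(landscape[c].values for c in
                    ("private_forest", "state_forest", "corporate_forest"))
        assert np.all(owner <= 1 + 1e-9)

    def test_correlation_decays_with_lag(self):
        # empirical correlogram oracle: correlation at 500-m lag must exceed
        # that at 4000-m lag for a field with a 2000-m correlation scale
        spec = LandscapeSpec(resolution=100.0, nx=80, ny=80, continuous=(
            ContinuousFieldSpec("f", correlation_scale_m=2000.0),
        ))
        v = generate_landscape(spec, seed=5)["f"].values

        def corr_at_lag(lag_cells):
            a = v[:, :-lag_cells].ravel()
            b = v[:, lag_cells:].ravel()
            return np.corrcoef(a, b)[0, 1]

        assert corr_at_lag(5) > corr_at_lag(40)

    def test_rejects_bad_extent(self):
        with pytest.raises(ValueError):
            LandscapeSpec(resolution=-5.0)
        with pytest.raises(ValueError):
            LandscapeSpec(nx=0)


class TestGenerateTruth:
    def test_zero_effects_constant_intensity(self, landscape):
        t = generate_truth(landscape, (), intercept=math.log(2e-3))
        np.testing.assert_allclose(t.lam, 2e-3)

    def test_monotone_effect_preserves_ordering(self, landscape):
        t = generate_truth(landscape, (EffectSpec("win_mean_temp", "linear", amplitude=1.0),))
        z = landscape["win_mean_temp"].values.ravel()
        lam = t.lam.ravel()
        order = np.argsort(z)
        assert np.all(np.diff(lam[order]) >= 0)

    def test_unknown_covariate_rejected(self, landscape):
        with pytest.raises(ValueError):
            generate_truth(landscape, (EffectSpec("no_such_grid"),))

    def test_expected_total_matches_simulation(self):
        # Monte-Carlo oracle: Poisson counts per cell, ≥200 replicates
        spec = default_landscape_spec(nx=10, ny=10)
        grids = generate_landscape(spec, seed=2)
        t = generate_truth(grids, (EffectSpec("coniferous", "linear", amplitude=1.0),))
        rng = np.random.default_rng(42)
        reps = 300
        totals = rng.poisson(t.lam * t.cell_area, size=(reps, *t.lam.shape)).sum(axis=(1, 2))
        se = totals.std(ddof=1) / math.sqrt(reps)
        assert abs(totals.mean() - t.expected_total) < 3 * se


class TestDesignSurvey:
    def test_effort_split_75_25(self, landscape):
        d = SurveyDesignSpec(mode="designed", n_transects=20)
        trs = design_survey(landscape, d, seed=1)
        wood = [t for t in trs if t.stratum == "woodland"]
        assert len(trs) == 20
        assert len(wood) == 15 and len(trs) - len(wood) == 5

    def test_designed_transects_run_west_east(self, landscape):
        trs = design_survey(landscape, SurveyDesignSpec(n_transects=12), seed=4)
        for t in trs:
            assert t.y0 == t.y1
            assert t.x1 > t.x0

    def test_undesigned_start_within_30m_of_plot_center(self, landscape):
        d = SurveyDesignSpec(mode="undesigned", plot_centers=((2000.0, 2000.0),))
        for seed in range(5):
            (t,) = design_survey(landscape, d, seed=seed)
            assert math.hypot(t.x0 - 2000.0, t.y0 - 2000.0) <= 30.0 + 1e-9

    def test_empty_stratum_with_effort_rejected(self):
        spec = LandscapeSpec(nx=10, ny=10, families=(
            CompositionalFamilySpec("lc", ("coniferous", "deciduous_and_mixed", "arable"),
                                    correlation_scale_m=500.0),
        ))
        grids = generate_landscape(spec, seed=0)
        # force an all-open landscape: threshold no cell can reach
        d = SurveyDesignSpec(mode="designed", n_transects=8, woodland_threshold=1.1)
        with pytest.raises(ValueError, match="zero area"):
            design_survey(grids, d, seed=0)

    def test_seed_determinism(self, landscape):
        d = SurveyDesignSpec(n_transects=10)
        a = design_survey(landscape, d, seed=9)
        b = design_survey(landscape, d, seed=9)
        assert [(t.x0, t.y0, t.x1, t.y1) for t in a] == [(t.x0, t.y0, t.x1, t.y1) for t in b]


class TestSimulateObservations:
    def _transects(self, n=10, length=200.0, y=2000.0):
        return [TransectRecord(id=f"T{i}", quadrant="Q", x0=200.0 + 300.0 * i, y0=y,
                               x1=200.0 + 300.0 * i + length, y1=y, length=length,
                               design="designed", stratum="woodland")
                for i in range(n)]

    def test_zero_intensity_gives_empty_table(self, landscape, det_spec):
        t = generate_truth(landscape, (), intercept=-np.inf)
        t.lam = np.zeros_like(t.lam)
        obs, counts, _ = simulate_observations(t, self._transects(3), det_spec, seed=0)
        assert len(obs) == 0
        assert counts["n_true"].sum() == 0

    def test_perfect_detection_keeps_every_pellet(self, landscape):
        t = generate_truth(landscape, (), intercept=math.log(5e-3))
        det = DetectionSpec(key="half_normal", sigma0=1e6, w_gen=1.5)
        obs, counts, _ = simulate_observations(t, self._transects(5), det, seed=1)
        assert len(obs) == counts["n_true"].sum() == counts["n_detected"].sum()

    def test_thinned_poisson_expectation(self, landscape):
        # oracle: E[detected] = 2 · w_gen · Σ lengths · λ · p̄ for constant λ
        lam = 5e-3
        t = generate_truth(landscape, (), intercept=math.log(lam))
        det = DetectionSpec(key="half_normal", sigma0=0.6, w_gen=1.5)
        trs = self._transects(10)
        effort = sum(tr.length for tr in trs)
        pbar = half_normal_pbar(0.6, 1.5)
        expected = 2.0 * det.w_gen * effort * lam * pbar
        counts = [len(simulate_observations(t, trs, det, seed=s)[0]) for s in range(200)]
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_detection_frequency_matches_g_by_distance(self, landscape):
        # thinning correctness at n ≥ 1e4: empirical retention per distance
        # bin within binomial error of g(x)
        t = generate_truth(landscape, (), intercept=math.log(0.9))
        det = DetectionSpec(key="half_normal", sigma0=0.6,
                            observer_effects={"obs1": 1.0}, w_gen=1.5)
        trs = self._transects(20, length=200.0)
        obs, counts, _ = simulate_observations(t, trs, det, seed=100)
        d = obs["distance_m"].to_numpy()
        n_true = counts["n_true"].sum()
        assert n_true >= 10_000
        edges = np.linspace(0, det.w_gen, 6)
        # generated distances are uniform: expected per bin = n_true/5 · mean g
        for lo, hi in zip(edges[:-1], edges[1:]):
            grid = np.linspace(lo, hi, 50)
            g_mean = det.g(grid, "obs1").mean()
            n_bin = n_true / 5.0
            obs_bin = np.sum((d >= lo) & (d < hi))
            se = math.sqrt(n_bin * g_mean * (1 - g_mean) + 1.0)
            assert abs(obs_bin - n_bin * g_mean) < 4 * se + 0.02 * n_bin

    def test_sections_partition_transects(self, landscape, truth, det_spec):
        trs = self._transects(6)
        _, _, sections = simulate_observations(truth, trs, det_spec, seed=3,
                                               grids=landscape)
        total = sections.groupby("transect_id").apply(
            lambda g: (g["end_m"] - g["start_m"]).sum(), include_groups=False)
        for tr in trs:
            assert total[tr.id] == pytest.approx(tr.length)

    def test_seed_determinism(self, truth, det_spec):
        trs = self._transects(4)
        a, _, _ = simulate_observations(truth, trs, det_spec, seed=5)
        b, _, _ = simulate_observations(truth, trs, det_spec, seed=5)
        pd.testing.assert_frame_equal(a, b)
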