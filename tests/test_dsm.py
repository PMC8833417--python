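"""Stage 2: Horvitz–Thompson segment abundances and the penalized
additive density model (families, selection, comparison)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from deerdsm.dsm import (
    SegmentAbundance,
    backward_select,
    compare_dsm,
    fit_dsm,
    ht_segment_abundance,
    qq_points,
)
from deerdsm.segments import SegmentRecord

from .conftest import tweedie_segment_data as _tweedie_data


def _segments(n=3, length=100.0):
    return [SegmentRecord(segment_id=f"s{i}", transect_id="T1",
                          start_m=i * length, end_m=(i + 1) * length,
                          length=length, x=0.0, y=0.0, ground_cover="bare")
            for i in range(n)]


class _FixedPFit:
    """Detection-fit stand-in with known per-observation p (synthetic)."""

    def __init__(self, p):
        self.p = np.asarray(p, dtype=float)

    def p_per_observation(self, obs):
        return self.p[: len(obs)]


class TestHTAbundance:
    def _obs(self, alongs, tid="T1"):
        return pd.DataFrame({"transect_id": tid, "along_m": alongs})

    def test_uniform_weights(self):
        segs = _segments(1, 300.0)
        obs = self._obs([10.0, 20.0, 30.0])
        out = ht_segment_abundance(obs, _FixedPFit([0.5, 0.5, 0.5]), segs, w=1.5)
        assert out[0].nhat == pytest.approx(6.0)
        assert out[0].n == 3

    def test_perfect_detection_identity(self):
        segs = _segments(1, 300.0)
        obs = self._obs([10.0, 250.0])
        out = ht_segment_abundance(obs, _FixedPFit([1.0, 1.0]), segs, w=1.5)
        assert out[0].nhat == out[0].n == 2

    def test_mixed_weights_hand_arithmetic(self):
        segs = _segments(1, 300.0)
        obs = self._obs([5.0, 15.0])
        out = ht_segment_abundance(obs, _FixedPFit([0.5, 0.25]), segs, w=1.5)
        assert out[0].nhat == pytest.approx(6.0)

    def test_assignment_by_position_and_empty_segments(self):
        segs = _segments(3, 100.0)
        obs = self._obs([50.0, 150.0, 160.0])
        out = ht_segment_abundance(obs, _FixedPFit([0.5, 0.5, 0.5]), segs, w=1.5)
        assert [o.nhat for o in out] == [pytest.approx(2.0), pytest.approx(4.0), 0.0]
        assert out[2].n == 0

    def test_detection_without_segment_is_error(self):
        segs = _segments(1, 100.0)
        obs = self._obs([150.0])
        with pytest.raises(ValueError, match="no segment"):
            ht_segment_abundance(obs, _FixedPFit([0.5]), segs, w=1.5)

    def test_area_offset_attached(self):
        segs = _segments(2, 50.0)
        out = ht_segment_abundance(self._obs([]), _FixedPFit([]), segs, w=1.5)
        assert all(o.area_m2 == 150.0 for o in out)


class TestFitDSM:
    def test_recovers_single_smooth_effect(self):
        ab, cov = _tweedie_data(500, seed=10, noise_cov=False)
        fit = fit_dsm(ab, cov, family="tweedie")
        grid = pd.DataFrame({"z1": np.linspace(0.02, 0.98, 60)})
        eta, _ = fit.linear_predictor(grid)
        truth = 1.2 * np.sin(2 * np.pi * grid["z1"])
        assert np.corrcoef(eta, truth)[0, 1] > 0.9

    def test_null_signal_gives_flat_smooth(self):
        rng = np.random.default_rng(12)
        n = 300
        ids = [f"s{i}" for i in range(n)]
        ab = pd.DataFrame({"segment_id": ids,
                           "nhat": rng.gamma(4.0, 1.0, n),
                           "area_m2": np.full(n, 300.0)})
        cov = pd.DataFrame({"z": rng.uniform(0, 1, n)}, index=ids)
        fit = fit_dsm(ab, cov, family="tweedie")
        assert fit.terms[0].edf < 2.0
        assert fit.terms[0].p_value > 0.05

    def test_offset_equivariance(self):
        ab, cov = _tweedie_data(400, seed=14, noise_cov=False)
        fit1 = fit_dsm(ab, cov, family="tweedie")
        ab2 = ab.copy()
        ab2["area_m2"] = 2.0 * ab2["area_m2"]
        fit2 = fit_dsm(ab2, cov, family="tweedie",
                       alphas=fit1._alphas, dispersion=fit1.dispersion)
        # doubling every offset shifts the intercept by −log 2, smooths unchanged
        assert fit2.params[0] - fit1.params[0] == pytest.approx(-np.log(2.0), abs=0.02)
        np.testing.assert_allclose(fit2.params[1:], fit1.params[1:], atol=0.05)

    def test_too_few_segments_is_error(self):
        ab, cov = _tweedie_data(15, seed=1)
        with pytest.raises(ValueError, match="fewer segments"):
            fit_dsm(ab, cov, family="tweedie")

    def test_nb_rounds_noninteger_response_with_warning(self):
        ab, cov = _tweedie_data(300, seed=15, noise_cov=False)
        with pytest.warns(UserWarning, match="rounded"):
            fit = fit_dsm(ab, cov, family="negative_binomial")
        assert fit.family == "negative_binomial"
        assert fit.dispersion > 0

    def test_pct_deviance_definition(self):
        ab, cov = _tweedie_data(300, seed=16, noise_cov=False)
        fit = fit_dsm(ab, cov, family="tweedie")
        res = fit._results
        assert fit.pct_deviance == pytest.approx(
            100.0 * (1 - res.deviance / res.null_deviance))
        assert 0 <= fit.pct_deviance <= 100


class TestBackwardSelect:
    def test_fixed_point_when_all_significant(self):
        ab, cov = _tweedie_data(500, seed=17, noise_cov=False)
        fit = fit_dsm(ab, cov, family="tweedie")
        assert all(t.p_value <= 0.05 for t in fit.terms)
        sel, removed = backward_select(fit)
        assert removed == []
        assert sel.term_names == fit.term_names

    def test_noise_covariate_dropped(self):
        ab, cov = _tweedie_data(500, seed=18, noise_cov=True)
        fit = fit_dsm(ab, cov, family="tweedie")
        sel, removed = backward_select(fit)
        assert "z_noise" in removed
        assert sel.term_names == ["z1"]


class TestCompare:
    def test_printed_aic_table_deltas(self):
        # ΔAIC within season from published-style AIC values
        class Rec:
            def __init__(self, season, family, aic):
                self.season, self.family, self.aic = season, family, aic
                self.formula, self.pct_deviance = "", np.nan

        table = compare_dsm([
            Rec("spring", "tweedie", 1046.11), Rec("spring", "negative_binomial", 1064.06),
            Rec("autumn", "tweedie", 1177.12), Rec("autumn", "negative_binomial", 1248.35),
        ])
        spring = table[table["season"] == "spring"].set_index("family")
        autumn = table[table["season"] == "autumn"].set_index("family")
        assert spring.loc["negative_binomial", "delta_aic"] == pytest.approx(17.95)
        assert autumn.loc["negative_binomial", "delta_aic"] == pytest.approx(71.23)
        assert spring.loc["tweedie", "best"] and autumn.loc["tweedie", "best"]

    def test_single_fit_delta_zero(self):
        class Rec:
            season, family, formula, aic, pct_deviance = "s", "tweedie", "", 10.0, 1.0

        t = compare_dsm([Rec()])
        assert t["delta_aic"].iloc[0] == 0.0

    def test_delta_nonnegative_with_one_zero_per_season(self):
        ab, cov = _tweedie_data(300, seed=19, noise_cov=False)
        f1 = fit_dsm(ab, cov, family="tweedie", season="spring")
        with pytest.warns(UserWarning):
            f2 = fit_dsm(ab, cov, family="negative_binomial", season="spring")
        t = compare_dsm([f1, f2])
        assert (t["delta_aic"] >= 0).all()
        assert (t["delta_aic"] == 0).sum() == 1

    def test_family_comparison_prefers_tweedie_for_compound_poisson(self):
        wins = 0
        for rep in range(30):
            ab, cov = _tweedie_data(250, seed=100 + rep, noise_cov=False)
            f_tw = fit_dsm(ab, cov, family="tweedie")
            with pytest.warns(UserWarning):
                f_nb = fit_dsm(ab, cov, family="negative_binomial")
            if f_tw.aic < f_nb.aic:
                wins += 1
        assert wins >= 21  # ≥70% of 30 replicates

    def test_qq_points_shape(self):
        ab, cov = _tweedie_data(300, seed=20, noise_cov=False)
        fit = fit_dsm(ab, cov, family="tweedie")
        qq = qq_points(fit)
        assert len(qq) == 300
        assert qq["theoretical"].is_monotonic_increasing
        assert qq["deviance_residual"].is_monotonic_increasing


def test_tweedie_series_density_against_mgcv_oracle():
    """Dunn–Smyth series values frozen from mgcv::ldTweedie(y, mu, p=1.5, phi=1.3)."""
    fam = sm.families.Tweedie(var_power=1.5)
    y = np.array([0.0, 0.5, 2.0, 7.3])
    mu = np.array([1.0, 1.5, 2.0, 5.0])
    got = fam.loglike_obs(y, mu, scale=1.3)
    expected = np.array([-1.538462, -1.108033, -1.669177, -2.738459])
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_rmse_decreases_with_segment_count():
    """Predicted vs true log-density RMSE shrinks from 500 to 2000 segments."""
    rmses = []
    for n in (500, 2000):
        ab, cov = _tweedie_data(n, seed=33, noise_cov=False)
        fit = fit_dsm(ab, cov, family="tweedie")
        grid = pd.DataFrame({"z1": np.linspace(0.02, 0.98, 100)})
        eta, _ = fit.linear_predictor(grid)
        truth = np.log(0.004) + 1.2 * np.sin(2 * np.pi * grid["z1"])
        rmses.append(float(np.sqrt(np.mean((eta - truth) ** 2))))
    assert rmses[1] < rmses[0]
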