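"""Stage-1 detection functions: truncation, observer grouping, MCDS
likelihood fitting, AIC selection, Cramér–von Mises GOF and p̄."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deerdsm.detection import (
    _w2_stat,
    aic_ladder,
    assign_observer_groups,
    average_detection_probability,
    cvm_goodness_of_fit,
    detection_probability,
    fit_detection_function,
    half_normal_pbar,
    select_detection_model,
    truncate_distances,
)


class TestTruncation:
    def test_rule_application(self):
        obs = pd.DataFrame({"distance_m": [0.2, 1.4, 1.6]})
        out, n_disc = truncate_distances(obs, 1.5)
        assert out["distance_m"].tolist() == [0.2, 1.4]
        assert n_disc == 1

    def test_noop_when_all_within(self):
        obs = pd.DataFrame({"distance_m": [0.1, 0.5, 1.0]})
        out, n_disc = truncate_distances(obs, 1.5)
        assert n_disc == 0
        pd.testing.assert_frame_equal(out, obs)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out, n_disc = truncate_distances(pd.DataFrame({"distance_m": []}), 1.5)
        assert len(out) == 0 and n_disc == 0

    def test_tighter_truncation_retains_fewer(self, halfnormal_obs):
        wide, _ = truncate_distances(halfnormal_obs, 1.5)
        narrow, _ = truncate_distances(halfnormal_obs, 0.5)
        assert len(narrow) < len(wide)


class TestObserverGroups:
    def test_single_observer_single_group(self):
        obs = pd.DataFrame({"observer": ["a"] * 100, "distance_m": 0.5})
        out = assign_observer_groups(obs, {"a": 1000.0})
        assert set(out["observer_group"]) == {"g1"}

    def test_greedy_accumulation_hand_trace(self):
        # observers in descending effort with detections 80/40/40/30:
        # o1 alone reaches 70; o2+o3 reach 80; trailing o4 merges back
        rows = ([{"observer": "o1"}] * 80 + [{"observer": "o2"}] * 40
                + [{"observer": "o3"}] * 40 + [{"observer": "o4"}] * 30)
        obs = pd.DataFrame(rows)
        effort = {"o1": 4000.0, "o2": 3000.0, "o3": 2000.0, "o4": 1000.0}
        out = assign_observer_groups(obs, effort, min_detections=70)
        g = out.groupby("observer")["observer_group"].first()
        assert g["o1"] == "g1"
        assert g["o2"] == g["o3"] == g["o4"] == "g2"

    def test_every_group_meets_minimum(self):
        rng = np.random.default_rng(0)
        observers = [f"o{i}" for i in range(8)]
        obs = pd.DataFrame({"observer": rng.choice(observers, size=400)})
        effort = {o: float(1000 + 100 * i) for i, o in enumerate(observers)}
        out = assign_observer_groups(obs, effort, min_detections=70)
        assert (out.groupby("observer_group").size() >= 70).all()

    def test_too_few_detections_single_group_with_warning(self):
        obs = pd.DataFrame({"observer": ["a"] * 10 + ["b"] * 5})
        with pytest.warns(UserWarning):
            out = assign_observer_groups(obs, {"a": 10.0, "b": 5.0}, min_detections=70)
        assert set(out["observer_group"]) == {"g1"}


class TestFitting:
    def test_hazard_rate_is_one_at_zero(self):
        for sigma, b in [(0.3, 1.5), (0.8, 2.5), (2.0, 5.0)]:
            assert detection_probability(np.array([0.0]), "hazard_rate", sigma, b)[0] == 1.0

    def test_half_normal_sigma_recovery(self, halfnormal_obs):
        fit = fit_detection_function(halfnormal_obs, key="half_normal", w=1.5)
        sigma_hat = float(np.exp(fit.beta[0]))
        assert fit.converged
        assert abs(sigma_hat - 0.6) / 0.6 < 0.10

    def test_flat_detection_limit(self):
        # σ ≫ w: detections uniform, p̄ → 1
        rng = np.random.default_rng(5)
        obs = pd.DataFrame({"distance_m": rng.uniform(0, 1.5, 800)})
        fit = fit_detection_function(obs, key="half_normal", w=1.5)
        pbar, _ = average_detection_probability(fit, obs)
        assert pbar > 0.9

    def test_covariate_scale_model_orders_sigmas(self):
        # two observer groups with different true σ: fitted σ ordering matches
        from .conftest import sample_key_distances

        x1 = sample_key_distances("half_normal", 0.4, None, 1.5, 500, seed=1)
        x2 = sample_key_distances("half_normal", 0.8, None, 1.5, 500, seed=2)
        obs = pd.DataFrame({
            "distance_m": np.concatenate([x1, x2]),
            "observer_group": ["a"] * 500 + ["b"] * 500,
        })
        fit = fit_detection_function(obs, key="half_normal",
                                     covariates=("observer_group",), w=1.5)
        sig_a = float(np.exp(fit.beta[0]))
        sig_b = float(np.exp(fit.beta[0] + fit.beta[1]))
        assert fit.converged
        assert sig_a < sig_b
        assert abs(sig_a - 0.4) / 0.4 < 0.15
        assert abs(sig_b - 0.8) / 0.8 < 0.15

    def test_adjustment_with_covariates_rejected(self, halfnormal_obs):
        with pytest.raises(ValueError):
            fit_detection_function(halfnormal_obs, adjustment="cosine",
                                   covariates=("observer_group",))

    def test_optimum_beats_perturbations(self, halfnormal_obs):
        fit = fit_detection_function(halfnormal_obs, key="half_normal", w=1.5)
        rng = np.random.default_rng(3)
        sigma_hat = float(np.exp(fit.beta[0]))

        def loglik(sigma):
            mu = sigma * math.sqrt(math.pi / 2) * math.erf(1.5 / (sigma * math.sqrt(2)))
            x = halfnormal_obs["distance_m"].to_numpy()
            return float(np.sum(-(x**2) / (2 * sigma**2)) - len(x) * math.log(mu))

        best = loglik(sigma_hat)
        for _ in range(20):
            assert loglik(sigma_hat * math.exp(rng.normal(0, 0.2))) <= best + 1e-9


class TestSelection:
    def test_argmin_aic(self, halfnormal_obs):
        f1 = fit_detection_function(halfnormal_obs, key="half_normal", w=1.5)
        f2 = fit_detection_function(halfnormal_obs, key="hazard_rate", w=1.5)
        best = select_detection_model([f1, f2])
        assert best.aic == min(f1.aic, f2.aic)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            select_detection_model([])

    def test_ladder_invariant_to_observation_order(self, halfnormal_obs):
        shuffled = halfnormal_obs.sample(frac=1.0, random_state=4).reset_index(drop=True)
        ladders = []
        for obs in (halfnormal_obs, shuffled):
            fits = [fit_detection_function(obs, key=k, w=1.5, compute_vcov=False)
                    for k in ("half_normal", "hazard_rate")]
            ladders.append(aic_ladder(fits))
        pd.testing.assert_frame_equal(ladders[0], ladders[1], check_exact=False, atol=1e-6)


class TestCvM:
    def test_formula_minimum(self):
        n = 10
        u = (2 * np.arange(1, n + 1) - 1) / (2.0 * n)
        assert _w2_stat(u) == pytest.approx(1.0 / (12 * n))

    def test_single_point_hand_arithmetic(self):
        # n = 1, u = 0.9 → 1/12 + 0.16 = 0.24333…
        assert _w2_stat(np.array([0.9])) == pytest.approx(1.0 / 12.0 + 0.16)

    def test_pvalue_reasonable_for_true_model(self, halfnormal_obs):
        obs = halfnormal_obs.iloc[:300].reset_index(drop=True)
        fit = fit_detection_function(obs, key="half_normal", w=1.5)
        res = cvm_goodness_of_fit(fit, obs, n_boot=99, seed=8)
        assert res.n == 300
        assert res.w2 >= 1.0 / (12 * res.n)
        assert res.p_value > 0.05

    def test_tiny_sample_omits_pvalue(self):
        obs = pd.DataFrame({"distance_m": [0.1, 0.3, 0.5, 0.9]})
        fit = fit_detection_function(obs, key="half_normal", w=1.5)
        with pytest.warns(UserWarning):
            res = cvm_goodness_of_fit(fit, obs)
        assert res.p_value is None

    def test_bootstrap_pvalues_near_uniform_under_null(self):
        # data simulated from the fitted model: rejection rate at α = 0.05
        # should be within [0.01, 0.12] over 100 replicates
        rng = np.random.default_rng(21)
        rejections = 0
        n, w, sigma = 60, 1.5, 0.6
        for rep in range(100):
            x = np.abs(rng.normal(0, sigma, 4 * n))
            x = x[x <= w][:n]
            obs = pd.DataFrame({"distance_m": x})
            fit = fit_detection_function(obs, key="half_normal", w=w, compute_vcov=False)
            res = cvm_goodness_of_fit(fit, obs, n_boot=99, seed=1000 + rep)
            if res.p_value is not None and res.p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / 100 <= 0.12


class TestAverageDetectability:
    def test_quadrature_value_half_normal(self):
        # (1/w)∫₀ʷ exp(−x²/2σ²) dx at σ = 0.6, w = 1.5
        from scipy.integrate import quad

        val, _ = quad(lambda x: math.exp(-(x**2) / (2 * 0.36)), 0, 1.5)
        assert half_normal_pbar(0.6, 1.5) == pytest.approx(val / 1.5, abs=1e-10)
        assert half_normal_pbar(0.6, 1.5) == pytest.approx(0.495, abs=0.001)

    def test_closed_form_matches_fit(self, halfnormal_obs):
        fit = fit_detection_function(halfnormal_obs, key="half_normal", w=1.5)
        pbar, cv = average_detection_probability(fit, halfnormal_obs)
        sigma_hat = float(np.exp(fit.beta[0]))
        assert pbar == pytest.approx(half_normal_pbar(sigma_hat, 1.5), abs=1e-6)
        assert 0 < cv < 0.2


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
def test_w2_at_least_formula_minimum(u):
    """W² ≥ 1/(12n) for any u-vector (the statistic's algebraic floor)."""
    w2 = _w2_stat(np.asarray(u))
    assert w2 >= 1.0 / (12 * len(u)) - 1e-12
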