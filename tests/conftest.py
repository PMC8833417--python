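import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from deerdsm.synthetic import (
    DetectionSpec,
    default_effects,
    default_landscape_spec,
    generate_landscape,
    generate_truth,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def landscape():
    """A 4 km × 4 km landscape at 100-m resolution (seeded)."""
    spec = default_landscape_spec(resolution=100.0, nx=40, ny=40)
    return generate_landscape(spec, seed=7)


@pytest.fixture(scope="session")
def truth(landscape):
    return generate_truth(landscape, default_effects())


@pytest.fixture(scope="session")
def halfnormal_obs():
    """2000 perpendicular distances from a half-normal (σ=0.6) truncated at 1.5 m."""
    rng = np.random.default_rng(11)
    x = np.abs(rng.normal(0.0, 0.6, size=8000))
    x = x[x <= 1.5][:2000]
    return pd.DataFrame({"distance_m": x})


def sample_key_distances(key, sigma, b, w, n, seed):
    """Rejection-sample detection distances with density ∝ g(x) on [0, w]."""
    from deerdsm.detection import detection_probability

    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        x = rng.uniform(0, w, size=4 * n)
        keep = rng.uniform(size=4 * n) < detection_probability(x, key, sigma, b)
        out.extend(x[keep].tolist())
    return np.asarray(out[:n])


@pytest.fixture(scope="session")
def hazard_obs():
    """2000 distances from a hazard-rate detection function (σ=0.5, b=2.5, w=1.5)."""
    return pd.DataFrame({"distance_m": sample_key_distances("hazard_rate", 0.5, 2.5, 1.5, 2000, seed=13)})


@pytest.fixture
def det_spec():
    return DetectionSpec(key="half_normal", sigma0=0.6,
                         observer_effects={"obs1": 1.0, "obs2": 1.2}, w_gen=1.5)


def tweedie_segment_data(n, seed, noise_cov=True, effect=1.2):
    """Segment-like abundance data with one true smooth effect and optional
    noise covariate; compound Poisson–gamma response with HT-style weights."""
    rng = np.random.default_rng(seed)
    z1 = rng.uniform(0, 1, n)
    area = rng.uniform(100, 600, n)
    mu = np.exp(np.log(area) + np.log(0.004) + effect * np.sin(2 * np.pi * z1))
    npell = rng.poisson(mu / 2.1)
    w = rng.gamma(6.0, 2.1 / 6.0, size=npell.sum())  # HT weights around 2.1
    y = np.zeros(n)
    np.add.at(y, np.repeat(np.arange(n), npell), w)
    ids = [f"s{i}" for i in range(n)]
    ab = pd.DataFrame({"segment_id": ids, "nhat": y, "area_m2": area})
    cov = pd.DataFrame({"z1": z1}, index=ids)
    if noise_cov:
        cov["z_noise"] = rng.uniform(0, 1, n)
    return ab, cov
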