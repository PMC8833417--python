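"""Detection-function fitting for line-transect distance sampling (stage 1).

Perpendicular detection distances, truncated at distance ``w``, are fitted
by maximum conditional likelihood

    L(θ) = Π_i g(x_i; z_i, θ) / μ(z_i, θ),      μ(z) = ∫₀ʷ g(x; z) dx,

with half-normal ``g(x) = exp(−x²/2σ²)`` or hazard-rate
``g(x) = 1 − exp(−(x/σ)^−b)`` key functions, optional cosine / Hermite /
simple-polynomial adjustment series (key-only models), and a log-linear
scale model σ(z) = exp(β₀ + Σ βₖ zₖ) over observation-level covariates
(multiple covariate distance sampling).  Candidate models are ranked by
AIC and checked with the Cramér–von Mises statistic under a parametric
bootstrap.

Observers surveying little effort rarely accumulate the ~70 detections
needed to support an observer-specific detection curve, so observers are
post-stratified by effort into groups meeting that minimum before being
used as a covariate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import erf

__all__ = [
    "DetectionFit",
    "GofResult",
    "detection_probability",
    "truncate_distances",
    "assign_observer_groups",
    "fit_detection_function",
    "select_detection_model",
    "cvm_goodness_of_fit",
    "average_detection_probability",
    "half_normal_pbar",
]

_ADJ_ORDERS = {"cosine": (2, 3), "hermite": (4, 6), "simple_polynomial": (4, 6)}


def detection_probability(x: np.ndarray, key: str, sigma: float | np.ndarray, b: float | None = None) -> np.ndarray:
    """Key detection function g(x); g(0) = 1 for both keys."""
    x = np.asarray(x, dtype=float)
    if key == "half_normal":
        return np.exp(-(x**2) / (2.0 * np.asarray(sigma) ** 2))
    if key == "hazard_rate":
        if b is None:
            raise ValueError("hazard_rate needs a shape parameter b")
        with np.errstate(divide="ignore", over="ignore"):
            r = np.where(x > 0, (x / np.asarray(sigma)) ** (-b), np.inf)
        return -np.expm1(-r)
    raise ValueError(f"unknown key function {key!r}")


def _adjustment_series(u: np.ndarray, series: str | None, orders: tuple[int, ...], coefs: np.ndarray) -> np.ndarray:
    """1 + Σ a_j h_j(u) for scaled distance u = x/w."""
    if series is None or len(coefs) == 0:
        return np.ones_like(u)
    out = np.ones_like(u)
    for j, a in zip(orders, coefs):
        if series == "cosine":
            out = out + a * np.cos(j * math.pi * u)
        elif series == "hermite":
            out = out + a * _hermite(j, u)
        elif series == "simple_polynomial":
            out = out + a * u**j
        else:
            raise ValueError(f"unknown adjustment series {series!r}")
    return out


def _hermite(n: int, u: np.ndarray) -> np.ndarray:
    # probabilists' Hermite polynomials, the convention used for
    # distance-sampling adjustment series
    if n == 4:
        return u**4 - 6 * u**2 + 3
    if n == 6:
        return u**6 - 15 * u**4 + 45 * u**2 - 15
    raise ValueError(f"hermite order {n} not supported")


# ---------------------------------------------------------------------------
# basic data operations

def truncate_distances(obs: pd.DataFrame, w: float) -> tuple[pd.DataFrame, int]:
    """Drop detections beyond the truncation distance w.

    Returns the retained table and the number of discarded records.
    """
    if w <= 0:
        raise ValueError("truncation distance must be positive")
    if len(obs) == 0:
        warnings.warn("empty observation table", stacklevel=2)
        return obs.copy(), 0
    keep = obs["distance_m"] <= w
    return obs.loc[keep].reset_index(drop=True), int((~keep).sum())


def assign_observer_groups(
    obs: pd.DataFrame,
    effort_per_observer: dict[str, float],
    min_detections: int = 70,
) -> pd.DataFrame:
    """Post-stratify observers into groups with ≥ ``min_detections`` each.

    Observers are sorted by descending survey effort and accumulated
    greedily into a group until the group reaches the minimum number of
    detections; a trailing group below the minimum is merged into its
    predecessor.  Deterministic given the inputs.  Adds an
    ``observer_group`` column.
    """
    counts = obs["observer"].value_counts().to_dict()
    order = sorted(effort_per_observer, key=lambda o: (-effort_per_observer[o], o))
    groups: list[list[str]] = []
    current: list[str] = []
    n_current = 0
    for o in order:
        current.append(o)
        n_current += counts.get(o, 0)
        if n_current >= min_detections:
            groups.append(current)
            current, n_current = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            warnings.warn(
                f"total detections below min_detections={min_detections}; single group",
                stacklevel=2,
            )
            groups.append(current)
    label_of = {o: f"g{k + 1}" for k, grp in enumerate(groups) for o in grp}
    out = obs.copy()
    out["observer_group"] = out["observer"].map(label_of)
    return out


# ---------------------------------------------------------------------------
# model fit container

@dataclass
class DetectionFit:
    """A fitted detection function with its covariate scale model."""

    key: str
    adjustment: str | None
    adjustment_orders: tuple[int, ...]
    covariates: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]           # per covariate: ordered levels, first = baseline
    beta: np.ndarray                              # log-scale coefficients (intercept + dummies)
    shape_b: float | None
    adj_coefs: np.ndarray
    w: float
    loglik: float
    aic: float
    n: int
    converged: bool
    message: str = ""
    vcov: np.ndarray | None = field(default=None, repr=False)
    param_names: tuple[str, ...] = ()
    p_bar: float | None = None
    p_bar_cv: float | None = None

    @property
    def n_params(self) -> int:
        return len(self.beta) + (1 if self.key == "hazard_rate" else 0) + len(self.adj_coefs)

    # -- scale model -------------------------------------------------------
    def design_row(self, row: pd.Series | dict) -> np.ndarray:
        z = [1.0]
        for cov in self.covariates:
            lev = self.levels[cov]
            val = row[cov]
            z.extend(1.0 if val == l else 0.0 for l in lev[1:])
        return np.asarray(z)

    def design_matrix(self, obs: pd.DataFrame) -> np.ndarray:
        Z = np.ones((len(obs), 1))
        cols = [Z]
        for cov in self.covariates:
            lev = self.levels[cov]
            vals = obs[cov].to_numpy()
            cols.append(np.column_stack([(vals == l).astype(float) for l in lev[1:]]))
        return np.hstack(cols)

    def sigma(self, Z: np.ndarray) -> np.ndarray:
        return np.exp(Z @ self.beta)

    def g(self, x: np.ndarray, sigma: float | np.ndarray) -> np.ndarray:
        base = detection_probability(x, self.key, sigma, self.shape_b)
        if self.adjustment is None:
            return base
        u = np.asarray(x) / self.w
        num = _adjustment_series(u, self.adjustment, self.adjustment_orders, self.adj_coefs)
        den = _adjustment_series(np.zeros(1), self.adjustment, self.adjustment_orders, self.adj_coefs)[0]
        return base * num / den

    def mu(self, sigma: float) -> float:
        """Effective strip half-width μ(z) = ∫₀ʷ g(x; z) dx."""
        return _mu(self.key, self.w, float(sigma), self.shape_b, self.adjustment, self.adjustment_orders, self.adj_coefs)

    def p_of_sigma(self, sigma: float) -> float:
        return self.mu(sigma) / self.w

    def p_per_observation(self, obs: pd.DataFrame) -> np.ndarray:
        Z = self.design_matrix(obs)
        sig = self.sigma(Z)
        uniq, inv = np.unique(sig, return_inverse=True)
        mus = np.array([self.mu(s) for s in uniq])
        return mus[inv] / self.w

    def cdf(self, x: np.ndarray, sigma: float) -> np.ndarray:
        """Fitted CDF of detection distances at scale sigma."""
        grid = np.linspace(0.0, self.w, 257)
        gv = self.g(grid, sigma)
        cums = integrate.cumulative_trapezoid(gv, grid, initial=0.0)
        cums /= cums[-1]
        return np.interp(np.asarray(x, dtype=float), grid, cums)

    def sample(self, n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling of detection distances at scale sigma."""
        grid = np.linspace(0.0, self.w, 513)
        gv = self.g(grid, sigma)
        cums = integrate.cumulative_trapezoid(gv, grid, initial=0.0)
        cums /= cums[-1]
        return np.interp(rng.uniform(size=n), cums, grid)


def _mu(key, w, sigma, b, adjustment, orders, coefs) -> float:
    if key == "half_normal" and adjustment is None:
        return float(sigma * math.sqrt(math.pi / 2.0) * erf(w / (sigma * math.sqrt(2.0))))

    def integrand(x):
        base = detection_probability(np.asarray([x]), key, sigma, b)[0]
        if adjustment is None:
            return base
        num = _adjustment_series(np.asarray([x / w]), adjustment, orders, coefs)[0]
        den = _adjustment_series(np.zeros(1), adjustment, orders, coefs)[0]
        return base * num / den

    val, _ = integrate.quad(integrand, 0.0, w, epsabs=1e-8, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# fitting

def _unpack(theta: np.ndarray, n_beta: int, key: str, n_adj: int):
    beta = theta[:n_beta]
    pos = n_beta
    b = None
    if key == "hazard_rate":
        b = 1.0 + math.exp(theta[pos])  # enforce b > 1
        pos += 1
    adj = theta[pos:pos + n_adj]
    return beta, b, adj


def fit_detection_function(
    obs: pd.DataFrame,
    key: str = "half_normal",
    adjustment: str | None = None,
    covariates: tuple[str, ...] = (),
    w: float | None = None,
    adjustment_orders: tuple[int, ...] | None = None,
    sigma_starts: tuple[float, ...] | None = None,
    compute_vcov: bool = True,
) -> DetectionFit:
    """Fit one candidate detection model by maximum conditional likelihood.

    ``covariates`` name categorical columns of the (already truncated)
    observation table entering the log-linear scale model; models with
    covariates cannot carry adjustment terms.  Multiple quasi-Newton starts
    (σ₀ at w/4, w/2 and w) guard against local optima; non-convergence or a
    non-monotone adjusted curve produces a fit flagged ``converged=False``
    that model selection will skip.
    """
    if adjustment is not None and covariates:
        raise ValueError("models with covariates do not include adjustment terms")
    x = obs["distance_m"].to_numpy(dtype=float)
    n = len(x)
    if n < 2 or len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct distances")
    if w is None:
        w = float(np.max(x))
    if np.any(x < 0) or np.any(x > w):
        raise ValueError("distances must lie in [0, w]; truncate first")

    levels = {c: tuple(sorted(pd.unique(obs[c].astype(str)))) for c in covariates}
    proto = DetectionFit(
        key=key, adjustment=adjustment,
        adjustment_orders=tuple(adjustment_orders or (_ADJ_ORDERS.get(adjustment, ()) if adjustment else ())),
        covariates=tuple(covariates), levels=levels,
        beta=np.zeros(1), shape_b=None, adj_coefs=np.zeros(0),
        w=w, loglik=-np.inf, aic=np.inf, n=n, converged=False,
    )
    Z = proto.design_matrix(obs.astype({c: str for c in covariates}))
    n_beta = Z.shape[1]
    n_adj = len(proto.adjustment_orders)
    orders = proto.adjustment_orders

    # group identical covariate rows once: μ is evaluated per unique sigma
    Zu, inv = np.unique(Z, axis=0, return_inverse=True)

    def negloglik(theta: np.ndarray) -> float:
        beta, b, adj = _unpack(theta, n_beta, key, n_adj)
        sig_u = np.exp(Zu @ beta)
        if np.any(~np.isfinite(sig_u)) or np.any(sig_u <= 0):
            return 1e10
        base = detection_probability(x, key, np.exp(Z @ beta), b)
        if adjustment is not None:
            series = _adjustment_series(x / w, adjustment, orders, adj)
            at0 = _adjustment_series(np.zeros(1), adjustment, orders, adj)[0]
            if at0 <= 0 or np.any(series <= 0):
                return 1e10
            gx = base * series / at0
        else:
            gx = base
        if np.any(gx <= 0):
            return 1e10
        try:
            mus = np.array([_mu(key, w, s, b, adjustment, orders, adj) for s in sig_u])
        except Exception:
            return 1e10
        if np.any(mus <= 0) or np.any(~np.isfinite(mus)):
            return 1e10
        ll = float(np.sum(np.log(gx)) - np.sum(np.log(mus[inv])))
        return -ll if np.isfinite(ll) else 1e10

    best = None
    for sigma0 in (sigma_starts or (w / 4.0, w / 2.0, w)):
        theta0 = np.zeros(n_beta + (1 if key == "hazard_rate" else 0) + n_adj)
        theta0[0] = math.log(sigma0)
        if key == "hazard_rate":
            theta0[n_beta] = math.log(2.5 - 1.0)
        res = optimize.minimize(negloglik, theta0, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    assert best is not None
    converged = bool(np.isfinite(best.fun) and best.fun < 1e9)

    beta, b, adj = _unpack(best.x, n_beta, key, n_adj)
    fit = DetectionFit(
        key=key, adjustment=adjustment, adjustment_orders=orders,
        covariates=tuple(covariates), levels=levels,
        beta=np.asarray(beta), shape_b=b, adj_coefs=np.asarray(adj),
        w=w, loglik=-float(best.fun),
        aic=2.0 * float(best.fun) + 2.0 * (n_beta + (1 if key == "hazard_rate" else 0) + n_adj),
        n=n, converged=converged, message=str(best.message),
    )
    fit.param_names = tuple(
        [f"beta_{i}" for i in range(n_beta)]
        + (["log_bm1"] if key == "hazard_rate" else [])
        + [f"adj_{o}" for o in orders]
    )

    # monotonicity check of the adjusted curve on a 100-point grid
    if adjustment is not None and converged:
        grid = np.linspace(0.0, w, 100)
        gv = fit.g(grid, float(np.exp(beta[0])))
        if np.any(np.diff(gv) > 1e-6):
            fit.converged = False
            fit.message = "adjusted detection function non-monotone"
            return fit

    if converged and compute_vcov:
        fit.vcov = _numeric_vcov(negloglik, best.x)
    return fit


def _numeric_vcov(negloglik, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray | None:
    """Inverse of the numeric Hessian of the negative log-likelihood."""
    k = len(theta)
    H = np.zeros((k, k))
    f0 = negloglik(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            fpp = negloglik(theta + ei + ej)
            fpm = negloglik(theta + ei - ej)
            fmp = negloglik(theta - ei + ej)
            fmm = negloglik(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(V)):
        return None
    return V


def select_detection_model(fits: list[DetectionFit]) -> DetectionFit:
    """Minimum-AIC model among converged candidates; ties → fewer parameters."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged detection fit to select from")
    return min(ok, key=lambda f: (round(f.aic, 10), f.n_params))


def aic_ladder(fits: list[DetectionFit]) -> pd.DataFrame:
    rows = [{
        "key": f.key, "adjustment": f.adjustment or "none",
        "covariates": "+".join(f.covariates) or "none",
        "n_params": f.n_params, "loglik": f.loglik, "aic": f.aic,
        "converged": f.converged,
    } for f in fits]
    out = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out.loc[out["converged"], "aic"].min()
    return out


# ---------------------------------------------------------------------------
# goodness of fit and average detectability

@dataclass
class GofResult:
    w2: float
    p_value: float | None
    n: int


def cvm_goodness_of_fit(
    fit: DetectionFit,
    obs: pd.DataFrame,
    n_boot: int = 499,
    seed: int = 0,
    refit: bool = True,
) -> GofResult:
    """Cramér–von Mises GOF with a parametric-bootstrap p-value.

    W² = 1/(12n) + Σᵢ (u₍ᵢ₎ − (2i−1)/(2n))² with u = fitted CDF of the
    observed distances.  The null distribution of W² is built by simulating
    ``n_boot`` datasets from the fitted model (at each observation's
    covariates) and recomputing W², refitting the same model specification
    on each resample.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    x = obs["distance_m"].to_numpy(dtype=float)
    n = len(x)
    Z = fit.design_matrix(obs.astype({c: str for c in fit.covariates}))
    sig = fit.sigma(Z)
    u = np.array([fit.cdf(xi, si) for xi, si in zip(x, sig)])
    w2 = _w2_stat(u)
    if n < 5:
        warnings.warn("fewer than 5 observations; p-value omitted", stacklevel=2)
        return GofResult(w2=w2, p_value=None, n=n)

    rng = np.random.default_rng(seed)
    uniq, inv = np.unique(sig, return_inverse=True)
    exceed = 0
    for _ in range(n_boot):
        xb = np.empty(n)
        for k, s in enumerate(uniq):
            m = inv == k
            xb[m] = fit.sample(int(m.sum()), s, rng)
        bobs = obs.copy()
        bobs["distance_m"] = xb
        bfit = fit
        if refit:
            try:
                bfit = fit_detection_function(
                    bobs, key=fit.key, adjustment=fit.adjustment,
                    covariates=fit.covariates, w=fit.w,
                    adjustment_orders=fit.adjustment_orders or None,
                    sigma_starts=(float(np.exp(fit.beta[0])),),
                    compute_vcov=False,
                )
                if not bfit.converged:
                    bfit = fit
            except Exception:
                bfit = fit
        Zb = bfit.design_matrix(bobs.astype({c: str for c in bfit.covariates}))
        sb = bfit.sigma(Zb)
        su, sinv = np.unique(sb, return_inverse=True)
        ub = np.empty(n)
        for k, s in enumerate(su):
            m = sinv == k
            ub[m] = bfit.cdf(xb[m], s)
        if _w2_stat(ub) >= w2:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return GofResult(w2=w2, p_value=p, n=n)


def _w2_stat(u: np.ndarray) -> float:
    n = len(u)
    us = np.sort(u)
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((us - (2 * i - 1) / (2.0 * n)) ** 2))


def average_detection_probability(fit: DetectionFit, obs: pd.DataFrame) -> tuple[float, float]:
    """Harmonic-mean average detectability p̄ with its delta-method CV.

    p̄ = n / Σᵢ 1/p(zᵢ), the average implied by the Horvitz–Thompson
    correction.  The CV propagates the observed-information covariance of
    the fit parameters through a numeric gradient of p̄(θ); covariate-
    distribution uncertainty is not included.
    """
    p = fit.p_per_observation(obs)
    if np.any(p <= 0):
        raise ValueError("non-positive detection probability; failed fit")
    n = len(p)
    pbar = n / float(np.sum(1.0 / p))
    if fit.vcov is None:
        return pbar, float("nan")

    theta0 = _theta_of(fit)
    eps = 1e-5

    def pbar_at(theta: np.ndarray) -> float:
        f2 = _fit_with_theta(fit, theta)
        p2 = f2.p_per_observation(obs)
        return n / float(np.sum(1.0 / p2))

    grad = np.array([
        (pbar_at(theta0 + eps * e) - pbar_at(theta0 - eps * e)) / (2 * eps)
        for e in np.eye(len(theta0))
    ])
    var = float(grad @ fit.vcov @ grad)
    cv = math.sqrt(max(var, 0.0)) / pbar
    return pbar, cv


def _theta_of(fit: DetectionFit) -> np.ndarray:
    parts = [fit.beta]
    if fit.key == "hazard_rate":
        parts.append([math.log(fit.shape_b - 1.0)])
    parts.append(fit.adj_coefs)
    return np.concatenate([np.atleast_1d(p) for p in parts])


def _fit_with_theta(fit: DetectionFit, theta: np.ndarray) -> DetectionFit:
    beta, b, adj = _unpack(theta, len(fit.beta), fit.key, len(fit.adj_coefs))
    import copy
    f2 = copy.copy(fit)
    f2.beta = np.asarray(beta)
    f2.shape_b = b
    f2.adj_coefs = np.asarray(adj)
    return f2


def half_normal_pbar(sigma: float, w: float) -> float:
    """Closed-form average detectability of an uncovariate half-normal:
    p̄ = σ√(π/2)·erf(w/(σ√2)) / w."""
    return float(sigma * math.sqrt(math.pi / 2.0) * erf(w / (sigma * math.sqrt(2.0))) / w)
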