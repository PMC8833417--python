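"""Density surface modelling (stage 2).

Per-segment abundances corrected for imperfect detection by a
Horvitz–Thompson-like estimator, n̂ⱼ = Σᵢ 1/p(zᵢ) over the segment's
detections, are regressed on landscape covariates through a penalized
additive model with a log link and the segment strip area as offset:

    log E[n̂ⱼ] = log Aⱼ + β₀ + Σₖ fₖ(zⱼₖ).

The fₖ are low-rank penalized regression splines with smoothness chosen by
generalized cross-validation.  Either a Tweedie (compound Poisson–gamma,
power 1 < p < 2 profiled over a grid) or a negative binomial (theta by
outer profile likelihood) response is used; both handle the over-dispersed,
zero-heavy segment counts typical of pellet surveys.  Model selection is
backward stepwise on approximate Wald p-values of the smooths, and
candidate families are compared on AIC, percentage deviance explained and
quantile–quantile data of the deviance residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .detection import DetectionFit
from .segments import SegmentRecord

__all__ = [
    "SegmentAbundance",
    "DSMFit",
    "ht_segment_abundance",
    "fit_dsm",
    "backward_select",
    "compare_dsm",
    "qq_points",
]

TWEEDIE_POWER_GRID = tuple(np.round(np.arange(1.1, 2.0, 0.1), 1))
NB_ALPHA_GRID = (0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.5, 4.0)
_ALPHA_GRID = (1e-3, 1e-1, 1e1, 1e3, 1e5)


@dataclass
class SegmentAbundance:
    segment_id: str
    n: int
    nhat: float
    area_m2: float


def ht_segment_abundance(
    obs: pd.DataFrame,
    fit: DetectionFit,
    segments: list[SegmentRecord],
    w: float,
) -> list[SegmentAbundance]:
    """Horvitz–Thompson-corrected abundance per segment.

    Each detection contributes 1/p(zᵢ), where p(z) = μ(z)/w from the fitted
    detection function; detections are assigned to segments by transect id
    and along-transect position.  Segments without detections get n̂ = 0.
    """
    p = fit.p_per_observation(obs) if len(obs) else np.zeros(0)
    if np.any(p <= 0):
        raise ValueError("non-positive detection probability")
    by_tr: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_tr.setdefault(s.transect_id, []).append(s)
    acc_n = {s.segment_id: 0 for s in segments}
    acc_nhat = {s.segment_id: 0.0 for s in segments}
    for (_, row), pi in zip(obs.iterrows(), p):
        segs = by_tr.get(row["transect_id"], [])
        hit = None
        for s in segs:
            if s.start_m - 1e-9 <= row["along_m"] <= s.end_m + 1e-9:
                hit = s
                break
        if hit is None:
            raise ValueError(
                f"detection at {row['along_m']:.1f} m on transect {row['transect_id']} has no segment"
            )
        acc_n[hit.segment_id] += 1
        acc_nhat[hit.segment_id] += 1.0 / pi
    return [
        SegmentAbundance(segment_id=s.segment_id, n=acc_n[s.segment_id],
                         nhat=acc_nhat[s.segment_id], area_m2=s.area(w))
        for s in segments
    ]


# ---------------------------------------------------------------------------

@dataclass
class TermInfo:
    name: str
    basis_df: int
    edf: float
    p_value: float


@dataclass
class DSMFit:
    """A fitted density surface model (penalized additive regression)."""

    family: str                       # tweedie | negative_binomial
    dispersion: float                 # tweedie power p or NB theta
    scale: float                      # estimated dispersion phi (tweedie) or 1
    terms: list[TermInfo]
    params: np.ndarray = field(repr=False)
    cov_params: np.ndarray = field(repr=False)
    loglik: float = np.nan
    aic: float = np.nan
    pct_deviance: float = np.nan
    converged: bool = True
    season: str = ""
    n: int = 0
    # private refit/predict state
    _endog: np.ndarray = field(default=None, repr=False)
    _offset: np.ndarray = field(default=None, repr=False)
    _covars: pd.DataFrame = field(default=None, repr=False)
    _smoother: BSplines = field(default=None, repr=False)
    _alphas: list[float] = field(default=None, repr=False)
    _basis_df: int = 10
    _train_range: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)
    _results: object = field(default=None, repr=False)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def formula(self) -> str:
        if not self.terms:
            return "~ 1 + offset(log area)"
        return " + ".join(f"s({t.name})" for t in self.terms) + " + offset(log area)"

    @property
    def edf_total(self) -> float:
        return 1.0 + sum(t.edf for t in self.terms)

    def design(self, covars: pd.DataFrame) -> np.ndarray:
        """Model matrix [1 | spline bases] for new covariate rows.

        Values are clipped to the training range of each covariate; how far
        outside that range a prediction point lies is the business of the
        extrapolation diagnostics, not of the basis functions.
        """
        n = len(covars)
        if not self.terms:
            return np.ones((n, 1))
        cols = []
        for t in self.terms:
            if t.name not in covars.columns:
                raise ValueError(f"prediction covariates missing model term {t.name!r}")
            lo, hi = self._train_range[t.name]
            cols.append(np.clip(covars[t.name].to_numpy(dtype=float), lo, hi))
        Xraw = np.column_stack(cols)
        basis = self._smoother.transform(Xraw)
        if basis.ndim == 1:
            basis = basis[:, None]
        return np.hstack([np.ones((n, 1)), basis])

    def linear_predictor(self, covars: pd.DataFrame, log_offset: np.ndarray | float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """(η̂, SE(η̂)) for new covariate rows; SE from the coefficient covariance."""
        X = self.design(covars)
        eta = X @ self.params + log_offset
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov_params, X), 0.0))
        return eta, se

    def fitted_values(self) -> np.ndarray:
        eta, _ = self.linear_predictor(self._covars, self._offset)
        return np.exp(eta)

    def deviance_residuals(self) -> np.ndarray:
        return np.asarray(self._results.resid_deviance)


def _make_family(family: str, dispersion: float):
    if family == "tweedie":
        return sm.families.Tweedie(var_power=float(dispersion))
    if family == "negative_binomial":
        # statsmodels parameterises NB by alpha = 1/theta
        return sm.families.NegativeBinomial(alpha=1.0 / float(dispersion))
    raise ValueError(f"unknown family {family!r}")


def _gam_fit(endog, offset, Xraw, basis_df, family_obj, alphas):
    smoother = BSplines(Xraw, df=[basis_df] * Xraw.shape[1], degree=[3] * Xraw.shape[1],
                        include_intercept=False)
    model = GLMGam(endog, exog=np.ones((len(endog), 1)), smoother=smoother,
                   alpha=list(alphas), family=family_obj, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return smoother, res


def _gcv(res, n) -> float:
    edf = float(np.sum(res.edf))
    if n <= edf + 1e-9:
        return np.inf
    return n * res.deviance / (n - edf) ** 2


def _select_alphas(endog, offset, Xraw, basis_df, family_obj, n_sweeps: int = 1) -> list[float]:
    """Per-smooth GCV grid search by coordinate descent.

    A single sweep over a coarse log-spaced grid: the GCV optimum over the
    penalty weight is broad, so locating its order of magnitude per smooth
    is what matters for the fit.
    """
    k = Xraw.shape[1]
    alphas = [10.0] * k
    n = len(endog)
    best_gcv = np.inf
    for _ in range(n_sweeps):
        for j in range(k):
            best_a = alphas[j]
            for a in _ALPHA_GRID:
                trial = list(alphas)
                trial[j] = a
                try:
                    _, res = _gam_fit(endog, offset, Xraw, basis_df, family_obj, trial)
                except Exception:
                    continue
                g = _gcv(res, n)
                if g < best_gcv - 1e-12:
                    best_gcv, best_a = g, a
            alphas[j] = best_a
    return alphas


def _term_pvalues(res, smoother, n_terms) -> tuple[list[float], list[float]]:
    """Approximate Wald test per smooth: β'V⁻β on ~edf degrees of freedom."""
    V = res.cov_params()
    params = np.asarray(res.params)
    edf = np.asarray(res.edf)
    pvals, edfs = [], []
    for j in range(n_terms):
        # smoother.mask spans the basis columns only; +1 for the intercept
        cols = 1 + np.flatnonzero(smoother.mask[j])
        beta = params[cols]
        Vj = V[np.ix_(cols, cols)]
        stat = float(beta @ np.linalg.pinv(Vj, rcond=1e-10) @ beta)
        df_j = max(float(np.sum(edf[cols])), 1e-6)
        pvals.append(float(stats.chi2.sf(stat, max(round(df_j), 1))))
        edfs.append(df_j)
    return pvals, edfs


def fit_dsm(
    abundances: list[SegmentAbundance] | pd.DataFrame,
    covariate_table: pd.DataFrame,
    family: str = "tweedie",
    smooth_terms: list[str] | None = None,
    basis_df: int = 10,
    season: str = "",
    alphas: list[float] | None = None,
    dispersion: float | None = None,
) -> DSMFit:
    """Fit the additive density model to HT-corrected segment abundances.

    ``covariate_table`` is indexed by segment id (collinearity-filtered
    columns); ``smooth_terms`` defaults to every column.  The Tweedie power
    is profiled over a fixed grid (1.1 … 1.9) by series log-likelihood; NB
    theta by outer profile likelihood.  Pass ``dispersion`` to pin either.
    """
    if isinstance(abundances, pd.DataFrame):
        ab = abundances
    else:
        ab = pd.DataFrame([{"segment_id": a.segment_id, "n": a.n, "nhat": a.nhat,
                            "area_m2": a.area_m2} for a in abundances])
    ab = ab.set_index("segment_id") if "segment_id" in ab.columns else ab
    covars = covariate_table.loc[ab.index]
    terms = list(smooth_terms) if smooth_terms is not None else list(covars.columns)
    endog = ab["nhat"].to_numpy(dtype=float)
    if family == "negative_binomial" and np.any(endog != np.round(endog)):
        warnings.warn("negative binomial response rounded to nearest integer", stacklevel=2)
        endog = np.round(endog)
    offset = np.log(ab["area_m2"].to_numpy(dtype=float))
    n = len(endog)

    if not terms:
        return _intercept_only_fit(endog, offset, family, season, covars, dispersion)

    Xraw = covars[terms].to_numpy(dtype=float)
    if n <= basis_df * len(terms) + 1:
        raise ValueError("fewer segments than coefficients")

    # -- dispersion profiling at a reference smoothing, then final fit -----
    if family == "tweedie":
        ref_fam = _make_family("tweedie", dispersion if dispersion is not None else 1.5)
        sel_alphas = list(alphas) if alphas is not None else _select_alphas(endog, offset, Xraw, basis_df, ref_fam)
        if dispersion is None:
            best_p, best_ll = None, -np.inf
            for p_tw in TWEEDIE_POWER_GRID:
                fam = _make_family("tweedie", p_tw)
                try:
                    _, res = _gam_fit(endog, offset, Xraw, basis_df, fam, sel_alphas)
                except Exception:
                    continue
                ll, _ = _tweedie_llf(endog, res, p_tw)
                if np.isfinite(ll) and ll > best_ll:
                    best_p, best_ll = p_tw, ll
            if best_p is None:
                raise RuntimeError("tweedie power profiling failed to converge")
            dispersion = float(best_p)
        n_disp_params = 2  # power and phi
    else:
        ref_fam = _make_family("negative_binomial", dispersion if dispersion is not None else 1.0)
        sel_alphas = list(alphas) if alphas is not None else _select_alphas(endog, offset, Xraw, basis_df, ref_fam)
        if dispersion is None:
            best_t, best_ll = None, -np.inf
            for a_nb in NB_ALPHA_GRID:
                fam = _make_family("negative_binomial", 1.0 / a_nb)
                try:
                    _, res = _gam_fit(endog, offset, Xraw, basis_df, fam, sel_alphas)
                except Exception:
                    continue
                ll = float(np.sum(fam.loglike_obs(endog, res.fittedvalues, scale=1.0)))
                if np.isfinite(ll) and ll > best_ll:
                    best_t, best_ll = 1.0 / a_nb, ll
            if best_t is None:
                raise RuntimeError("negative binomial theta profiling failed")
            dispersion = float(best_t)
        n_disp_params = 1  # theta

    fam = _make_family(family, dispersion)
    smoother, res = _gam_fit(endog, offset, Xraw, basis_df, fam, sel_alphas)
    if not res.converged:
        warnings.warn("penalized IRLS did not fully converge", stacklevel=2)

    pvals, edfs = _term_pvalues(res, smoother, len(terms))
    if family == "tweedie":
        llf, scale = _tweedie_llf(endog, res, dispersion)
    else:
        llf = float(np.sum(fam.loglike_obs(endog, res.fittedvalues, scale=1.0)))
        scale = 1.0
    edf_total = 1.0 + float(sum(edfs))
    aic = -2.0 * llf + 2.0 * (edf_total + n_disp_params)
    pct_dev = 100.0 * (1.0 - res.deviance / res.null_deviance)

    fit = DSMFit(
        family=family, dispersion=float(dispersion), scale=scale,
        terms=[TermInfo(t, basis_df, e, p) for t, e, p in zip(terms, edfs, pvals)],
        params=np.asarray(res.params), cov_params=np.asarray(res.cov_params()),
        loglik=llf, aic=aic, pct_deviance=float(pct_dev),
        converged=bool(res.converged), season=season, n=n,
        _endog=endog, _offset=offset, _covars=covars, _smoother=smoother,
        _alphas=sel_alphas, _basis_df=basis_df,
        _train_range={t: (float(covars[t].min()), float(covars[t].max())) for t in terms},
        _results=res,
    )
    return fit


def _tweedie_llf(endog, res, p_tw) -> tuple[float, float]:
    """Series (Dunn–Smyth) Tweedie log-likelihood, phi profiled by ML."""
    from scipy.optimize import minimize_scalar

    fam = sm.families.Tweedie(var_power=p_tw)
    mu = np.asarray(res.fittedvalues)

    def nll(log_phi: float) -> float:
        with np.errstate(all="ignore"):
            ll = fam.loglike_obs(endog, mu, scale=np.exp(log_phi))
        s = np.sum(ll)
        return -s if np.isfinite(s) else 1e12

    opt = minimize_scalar(nll, bounds=(-6.0, 6.0), method="bounded",
                          options={"xatol": 1e-6})
    return -float(opt.fun), float(np.exp(opt.x))


def _intercept_only_fit(endog, offset, family, season, covars, dispersion) -> DSMFit:
    disp = dispersion if dispersion is not None else (1.5 if family == "tweedie" else 1.0)
    fam = _make_family(family, disp)
    y = np.round(endog) if family == "negative_binomial" else endog
    model = sm.GLM(y, np.ones((len(y), 1)), family=fam, offset=offset)
    res = model.fit()
    if family == "tweedie":
        llf, scale = _tweedie_llf(y, res, disp)
        k_extra = 2
    else:
        llf = float(np.sum(fam.loglike_obs(y, res.fittedvalues, scale=1.0)))
        scale = 1.0
        k_extra = 1
    fit = DSMFit(
        family=family, dispersion=float(disp), scale=scale, terms=[],
        params=np.asarray(res.params), cov_params=np.asarray(res.cov_params()),
        loglik=llf, aic=-2.0 * llf + 2.0 * (1 + k_extra),
        pct_deviance=0.0, converged=True, season=season, n=len(y),
        _endog=y, _offset=offset, _covars=covars, _results=res,
    )
    return fit


def backward_select(fit: DSMFit, alpha: float = 0.05) -> tuple[DSMFit, list[str]]:
    """Backward stepwise term selection on approximate p-values.

    Repeatedly removes the smooth with the largest p-value above ``alpha``
    (ties broken towards the larger edf) and refits, until every remaining
    smooth is significant or only the intercept is left.  Returns the final
    fit and the removal sequence.
    """
    removed: list[str] = []
    current = fit
    while current.terms:
        worst = max(current.terms, key=lambda t: (t.p_value, t.edf))
        if worst.p_value <= alpha:
            break
        keep = [t.name for t in current.terms if t.name != worst.name]
        keep_alphas = [a for t, a in zip(current.terms, current._alphas) if t.name != worst.name]
        try:
            refit = fit_dsm(
                pd.DataFrame({"segment_id": current._covars.index,
                              "nhat": current._endog,
                              "area_m2": np.exp(current._offset)}),
                current._covars, family=current.family,
                smooth_terms=keep, basis_df=current._basis_df,
                season=current.season, dispersion=current.dispersion,
                alphas=keep_alphas or None,
            )
        except Exception as exc:  # refit failure: keep the previous model
            warnings.warn(f"backward-selection refit failed ({exc}); keeping previous model",
                          stacklevel=2)
            return current, removed
        removed.append(worst.name)
        current = refit
    return current, removed


def compare_dsm(fits: list) -> pd.DataFrame:
    """Model-comparison table (per season): AIC, ΔAIC vs best, %deviance.

    Accepts fitted :class:`DSMFit` objects or any records with ``season``,
    ``family``, ``formula``, ``aic`` and ``pct_deviance`` attributes, so a
    published AIC table can be re-expressed directly.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for f in fits:
        rows.append({
            "season": getattr(f, "season", ""),
            "family": f.family,
            "formula": getattr(f, "formula", ""),
            "aic": float(f.aic),
            "pct_deviance": float(getattr(f, "pct_deviance", np.nan)),
        })
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out.groupby("season")["aic"].transform("min")
    out["best"] = out["delta_aic"] == 0.0
    return out


def qq_points(fit: DSMFit) -> pd.DataFrame:
    """Theoretical-normal vs ordered deviance-residual quantiles."""
    r = np.sort(fit.deviance_residuals())
    n = len(r)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical": theo, "deviance_residual": r})
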