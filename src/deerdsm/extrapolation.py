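"""Extrapolation diagnostics: ExDet classes and the percentage of data nearby.

Predicting over a whole state from 102 km of transects means most grid
cells lie in environmental conditions the survey never visited.  Two
diagnostics quantify this:

* **ExDet** classifies each prediction point against the reference
  (training-segment) covariate cloud.  Per covariate j with reference range
  [minⱼ, maxⱼ],

      UDⱼ = min(xⱼ − minⱼ, maxⱼ − xⱼ, 0) / (maxⱼ − minⱼ),   NT1 = Σⱼ UDⱼ.

  NT1 < 0 ⇒ *univariate* extrapolation (outside some covariate's range).
  Otherwise NT2 = D²(x)/max_ref D² (Mahalanobis w.r.t. the reference mean
  and covariance): NT2 > 1 ⇒ *combinatorial* (novel combination within
  univariate ranges), else *analogue*.  The most influential covariate is
  the one with the most negative UDⱼ (univariate) or the largest
  leave-one-out reduction of D² (combinatorial).

* **%N** is the share of reference points whose Gower distance to the
  prediction point is below the mean Gower distance among all reference
  pairs — a measure of how much survey data locally supports a prediction.

Cells that extrapolate and are poorly supported are discarded before any
downstream use of the prediction surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .predict import PredictionCell

__all__ = [
    "ExDetResult",
    "NearbyResult",
    "exdet_classify",
    "percent_data_nearby",
    "apply_discard_rule",
    "class_summary",
]


@dataclass
class ExDetResult:
    nt1: np.ndarray
    nt2: np.ndarray
    classes: np.ndarray          # analogue | combinatorial | univariate
    mic: np.ndarray              # most-influential covariate label per target


@dataclass
class NearbyResult:
    pct_nearby: np.ndarray
    threshold: float             # mean Gower distance among reference pairs


def _as_matrix(df: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(df, pd.DataFrame):
        return df.to_numpy(dtype=float), list(df.columns)
    arr = np.asarray(df, dtype=float)
    return arr, [f"v{j}" for j in range(arr.shape[1])]


def exdet_classify(
    reference: pd.DataFrame | np.ndarray,
    target: pd.DataFrame | np.ndarray,
    ridge: float = 1e-8,
) -> ExDetResult:
    """ExDet classification of target points against reference covariates."""
    R, names = _as_matrix(reference)
    T, tnames = _as_matrix(target)
    if R.shape[1] != T.shape[1]:
        raise ValueError("reference and target must share the covariate set")
    rmin = R.min(axis=0)
    rmax = R.max(axis=0)
    rng = rmax - rmin
    if np.any(rng <= 0):
        bad = [names[j] for j in np.flatnonzero(rng <= 0)]
        raise ValueError(f"degenerate reference range for covariates {bad}")

    ud = np.minimum.reduce([T - rmin, rmax - T, np.zeros_like(T)]) / rng
    nt1 = ud.sum(axis=1)

    mean = R.mean(axis=0)
    cov = np.cov(R, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        icov = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular reference covariance; ridge regularized", stacklevel=2)
        icov = np.linalg.inv(cov + ridge * np.eye(cov.shape[0]) * np.trace(cov))
    d2_ref = np.einsum("ij,jk,ik->i", R - mean, icov, R - mean)
    d2_max = float(d2_ref.max())
    d2_t = np.einsum("ij,jk,ik->i", T - mean, icov, T - mean)
    nt2 = d2_t / d2_max

    classes = np.where(nt1 < 0, "univariate",
                       np.where(nt2 > 1, "combinatorial", "analogue")).astype(object)

    mic = np.empty(len(T), dtype=object)
    for i in range(len(T)):
        if nt1[i] < 0:
            mic[i] = names[int(np.argmin(ud[i]))]
        elif nt2[i] > 1:
            # leave-one-covariate-out reduction of D², largest = most influential
            contrib = np.empty(T.shape[1])
            for j in range(T.shape[1]):
                keep = np.arange(T.shape[1]) != j
                covk = cov[np.ix_(keep, keep)]
                try:
                    icovk = np.linalg.inv(covk)
                except np.linalg.LinAlgError:
                    icovk = np.linalg.inv(covk + ridge * np.eye(covk.shape[0]) * np.trace(covk))
                d2k = float((T[i, keep] - mean[keep]) @ icovk @ (T[i, keep] - mean[keep]))
                contrib[j] = d2_t[i] - d2k
            mic[i] = names[int(np.argmax(contrib))]
        else:
            mic[i] = ""
    return ExDetResult(nt1=nt1, nt2=nt2, classes=np.asarray(classes), mic=np.asarray(mic))


def percent_data_nearby(
    reference: pd.DataFrame | np.ndarray,
    target: pd.DataFrame | np.ndarray,
) -> NearbyResult:
    """%N per target: share of reference points within the Gower radius.

    Gower distance = mean over covariates of |xⱼ − yⱼ|/rangeⱼ (range taken
    from the reference); the radius is the mean Gower distance over all
    reference pairs.  Zero-range covariates are excluded with a warning.
    """
    R, names = _as_matrix(reference)
    T, _ = _as_matrix(target)
    if len(R) < 2:
        raise ValueError("need at least 2 reference points")
    rng = R.max(axis=0) - R.min(axis=0)
    keep = rng > 0
    if not keep.all():
        bad = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"zero-range covariates excluded from Gower distance: {bad}", stacklevel=2)
    if not keep.any():
        raise ValueError("all covariates have zero range")
    Rk = R[:, keep] / rng[keep]
    Tk = T[:, keep] / rng[keep]
    k = Rk.shape[1]
    # mean Gower distance among all reference pairs
    dref = np.abs(Rk[:, None, :] - Rk[None, :, :]).sum(axis=2) / k
    n = len(Rk)
    iu = np.triu_indices(n, 1)
    threshold = float(dref[iu].mean())
    dtr = np.abs(Tk[:, None, :] - Rk[None, :, :]).sum(axis=2) / k
    pct = 100.0 * (dtr <= threshold).mean(axis=1)
    return NearbyResult(pct_nearby=pct, threshold=threshold)


def apply_discard_rule(
    cells: list[PredictionCell],
    nearby_threshold: float = 5.0,
    strict: bool = True,
) -> np.ndarray:
    """Mark unreliable prediction cells invalid.

    ``strict`` (default) keeps only cells that are analogue or
    combinatorial *and* have %N ≥ threshold — the rule actually carried
    into validation.  With ``strict=False`` only univariate cells with
    %N < threshold are discarded (the looser phrasing of the same rule).
    Returns the boolean validity mask and sets each cell's ``valid`` flag.
    """
    mask = np.empty(len(cells), dtype=bool)
    for i, c in enumerate(cells):
        if not c.exdet_class:
            raise ValueError(f"cell {c.cell_id} has no extrapolation class")
        if strict:
            ok = c.exdet_class in ("analogue", "combinatorial") and c.pct_nearby >= nearby_threshold
        else:
            ok = not (c.exdet_class == "univariate" and c.pct_nearby < nearby_threshold)
        c.valid = bool(ok)
        mask[i] = ok
    return mask


def class_summary(cells: list[PredictionCell]) -> pd.DataFrame:
    """Percentage of cells per extrapolation class, with counts."""
    classes = pd.Series([c.exdet_class for c in cells])
    counts = classes.value_counts()
    return pd.DataFrame({
        "class": counts.index,
        "n_cells": counts.values,
        "pct": 100.0 * counts.values / len(cells),
    }).reset_index(drop=True)
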