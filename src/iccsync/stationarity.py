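"""Stationarity and weak-dependence screening of voxel time courses.

The asymptotic variance of the agreement index rests on two conditions:
the per-subject time courses are (trend-)stationary, and they are
rho-mixing — the maximal absolute lagged correlation between X_{k} and
X_{k+v} vanishes as the lag v grows.  This module screens both:

* KPSS tests each series against the null of trend-stationarity
  (rejection flags a unit root / nonstationarity);
* ADF tests the complementary null of a unit root (rejection supports
  stationarity);
* a lagged-correlation profile tracks max |rho(X_k, X_{k+v})| over
  voxels and subjects across a grid of lags.

Rejections are aggregated across subjects: a voxel counts as
consistently nonstationary when the KPSS test rejects in at least a
given fraction of subjects (50/60/70% are the conventional report
points), optionally after per-subject weak-FDR correction of the
voxelwise p-values.  Screening is reported, never used to excise voxels
from the ICC maps.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss

from .surrogates import by_fdr

__all__ = [
    "stationarity_tests",
    "lagged_corr_profile",
    "consistency_aggregate",
    "screen_report",
]

DEFAULT_LAG_GRID = tuple(range(10, 231, 10))


def stationarity_tests(x: np.ndarray) -> tuple[float, float, float, float]:
    """KPSS (trend-stationary null) and ADF (unit-root null) on one series.

    Returns ``(kpss_stat, kpss_p, adf_stat, adf_p)``.  KPSS regresses on
    a deterministic trend; ADF includes a constant with AIC-selected lag
    order.  p-values are interpolated within the published critical-value
    tables, so they saturate at the table edges (0.01 / 0.10 for KPSS).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if x.size < 20:
        raise ValueError(f"series too short for stationarity testing: n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant series")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        kpss_stat, kpss_p, *_ = kpss(x, regression="ct", nlags="auto")
    adf_stat, adf_p, *_ = adfuller(x, regression="c", autolag="AIC")
    return float(kpss_stat), float(kpss_p), float(adf_stat), float(adf_p)


def lagged_corr_profile(
    all_voxel_matrices: np.ndarray, lag_grid=DEFAULT_LAG_GRID
) -> np.ndarray:
    """max over (voxel, subject) of |lag-v autocorrelation|, per lag v.

    A profile decreasing toward 0 with v supports the rho-mixing
    condition behind the delta-method variance.
    """
    lag_grid = np.asarray(lag_grid, dtype=int)
    if lag_grid.size == 0:
        raise ValueError("empty lag grid")
    if np.any(np.diff(lag_grid) <= 0):
        raise ValueError("lag grid must be strictly increasing")
    X = np.asarray(all_voxel_matrices, dtype=float)
    if X.ndim == 2:
        X = X[None]
    V, n, M = X.shape
    if lag_grid.max() >= n - 3:
        raise ValueError(f"max lag {lag_grid.max()} too close to series length {n}")
    series = np.moveaxis(X, 1, 2).reshape(V * M, n)
    out = np.empty(lag_grid.size)
    for j, lag in enumerate(lag_grid):
        a = series[:, :-lag]
        b = series[:, lag:]
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a * b).sum(axis=1) / denom
        out[j] = np.nanmax(np.abs(r))
    return out


def consistency_aggregate(
    reject_matrix: np.ndarray, subject_fraction: float
) -> float:
    """Fraction of voxels rejected in at least ceil(fraction * M) subjects.

    ``reject_matrix`` is boolean, voxels x subjects.
    """
    if not 0 < subject_fraction <= 1:
        raise ValueError("subject_fraction must lie in (0, 1]")
    R = np.asarray(reject_matrix, dtype=bool)
    if R.ndim != 2:
        raise ValueError("reject_matrix must be voxels x subjects")
    n_vox, M = R.shape
    if n_vox == 0:
        return 0.0
    need = math.ceil(subject_fraction * M)
    return float(np.mean(R.sum(axis=1) >= need))


def screen_report(
    all_voxel_matrices: np.ndarray,
    alpha: float = 0.05,
    fractions: tuple[float, ...] = (0.5, 0.6, 0.7),
    fdr: bool = True,
) -> dict:
    """Run the KPSS/ADF screen over all voxels and subjects.

    Returns a dict with per-(voxel, subject) statistic and p arrays, raw
    and (optionally) per-subject weak-FDR-corrected KPSS rejection
    matrices, and the aggregated proportions at each subject fraction.
    """
    X = np.asarray(all_voxel_matrices, dtype=float)
    V, n, M = X.shape
    kpss_stat = np.empty((V, M))
    kpss_p = np.empty((V, M))
    adf_stat = np.empty((V, M))
    adf_p = np.empty((V, M))
    for v in range(V):
        for i in range(M):
            kpss_stat[v, i], kpss_p[v, i], adf_stat[v, i], adf_p[v, i] = (
                stationarity_tests(X[v, :, i])
            )
    reject_raw = kpss_p < alpha
    report = {
        "kpss_stat": kpss_stat,
        "kpss_p": kpss_p,
        "adf_stat": adf_stat,
        "adf_p": adf_p,
        "kpss_reject": reject_raw,
        "adf_accept": adf_p >= alpha,
        "proportions": {f: consistency_aggregate(reject_raw, f) for f in fractions},
    }
    if fdr:
        reject_fdr = np.empty_like(reject_raw)
        for i in range(M):
            _, reject_fdr[:, i] = by_fdr(kpss_p[:, i].clip(min=np.finfo(float).tiny), alpha)
        report["kpss_reject_fdr"] = reject_fdr
        report["proportions_fdr"] = {
            f: consistency_aggregate(reject_fdr, f) for f in fractions
        }
    return report
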