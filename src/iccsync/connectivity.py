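"""Pairwise connectivity, hemispheric summaries, and cortisol association.

Connectivity between two ROI entries is the Pearson correlation of their
subject-level mean time courses over a chosen window (full scan or one
condition block), Fisher Z-transformed (atanh) to stabilize its
distribution, and standardized by multiplying by sqrt(window length) —
the division-by-nominal-standard-error convention 1/sqrt(n).  Group
significance of each pair uses a one-sample Student's t on the subjects'
Z values against zero, with weak (Benjamini–Yekutieli) FDR over the
family of all pairs.

Z values are averaged within left-, right-, and inter-hemispheric pair
scopes per subject, and those summaries are related to pre-/post-scan
salivary cortisol through partial correlation controlling demographic
covariates (age, sex, trait anxiety, stress-symptom score).

The Student's t treats subjects as independent replicates; temporal
autocorrelation within a scan inflates the effective information per
subject and is deliberately not corrected here — the Z values are
summaries per subject, and between-subject variability carries the
inference.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .surrogates import by_fdr

__all__ = [
    "pairwise_connectivity",
    "group_connectivity_test",
    "hemispheric_summaries",
    "partial_correlation",
    "cortisol_association",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "STAI_trait", "SQ_ISMA")


def pairwise_connectivity(
    subject_tcs: dict[str, np.ndarray],
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-subject Fisher-Z connectivity for every ROI-entry pair.

    Parameters
    ----------
    subject_tcs : mapping entry name -> (M, n) array
        Subject-level mean time courses per ROI entry.
    window : (start, stop) half-open volume range, optional
        Restrict the correlation to a condition block (e.g. ``(0, 120)``
        for the first condition, ``(120, 240)`` for the second); default
        is the full scan.

    Returns a tidy frame with columns subject, roi_a, roi_b, r, z,
    z_std where z = atanh(r) and z_std = z * sqrt(window length).
    Pairs with a constant series in the window, or |r| = 1, are skipped
    with a warning.
    """
    names = list(subject_tcs)
    if len(names) < 2:
        raise ValueError("need at least two ROI entries")
    arrs = {k: np.asarray(v, dtype=float) for k, v in subject_tcs.items()}
    M, n = next(iter(arrs.values())).shape
    for k, v in arrs.items():
        if v.shape != (M, n):
            raise ValueError(f"entry {k!r} has shape {v.shape}, expected {(M, n)}")
    if window is None:
        window = (0, n)
    lo, hi = window
    if not (0 <= lo < hi <= n):
        raise ValueError(f"window {window} outside [0, {n}]")
    n_window = hi - lo
    rows = []
    for a, b in combinations(names, 2):
        ta, tb = arrs[a][:, lo:hi], arrs[b][:, lo:hi]
        for s in range(M):
            xa, xb = ta[s], tb[s]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                logger.warning("pair (%s, %s) subject %d: constant series; skipped", a, b, s)
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            if abs(r) >= 1.0:
                logger.warning("pair (%s, %s) subject %d: |r| = 1; skipped", a, b, s)
                continue
            z = float(np.arctanh(r))
            rows.append(
                {
                    "subject": s,
                    "roi_a": a,
                    "roi_b": b,
                    "r": r,
                    "z": z,
                    "z_std": z * np.sqrt(n_window),
                    "n_window": n_window,
                }
            )
    return pd.DataFrame(rows)


def group_connectivity_test(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair one-sample t-test of Fisher Z against 0, with weak FDR.

    Pairs with fewer than 3 subjects are skipped.  Returns one row per
    pair: mean_z, mean_z_std, t, p (two-sided), fdr_reject.
    """
    out = []
    for (a, b), grp in table.groupby(["roi_a", "roi_b"], sort=True):
        z = grp["z"].to_numpy()
        if z.size < 3:
            logger.warning("pair (%s, %s): only %d subjects; skipped", a, b, z.size)
            continue
        if np.allclose(z, z[0]):
            t, p = (0.0, 1.0) if z[0] == 0 else (np.inf * np.sign(z[0]), 0.0)
        else:
            t, p = stats.ttest_1samp(z, 0.0)
        out.append(
            {
                "roi_a": a,
                "roi_b": b,
                "n_subjects": z.size,
                "mean_z": z.mean(),
                "mean_z_std": grp["z_std"].mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    res = pd.DataFrame(out)
    if res.empty:
        raise ValueError("no testable pairs")
    _, reject = by_fdr(res["p"].clip(lower=np.finfo(float).tiny).to_numpy(), alpha)
    res["fdr_reject"] = reject
    return res


def hemispheric_summaries(
    table: pd.DataFrame, hemisphere: dict[str, str]
) -> pd.DataFrame:
    """Per-subject mean z_std within left, right, and inter-hemisphere scopes.

    ``hemisphere`` maps ROI entry name to "L" or "R"; entries without a
    label (midline) are excluded from all scopes.  Scope of a pair:
    both-L -> left, both-R -> right, mixed -> inter.
    """
    def scope(a: str, b: str) -> str | None:
        ha, hb = hemisphere.get(a), hemisphere.get(b)
        if ha not in ("L", "R") or hb not in ("L", "R"):
            return None
        if ha == hb:
            return "left" if ha == "L" else "right"
        return "inter"

    t = table.copy()
    t["scope"] = [scope(a, b) for a, b in zip(t["roi_a"], t["roi_b"])]
    t = t.dropna(subset=["scope"])
    if t.empty:
        raise ValueError("no pairs with hemisphere labels")
    present = set(t["scope"])
    for s in ("left", "right", "inter"):
        if s not in present:
            logger.warning("scope %r has no pairs", s)
    return (
        t.groupby(["subject", "scope"])["z_std"].mean().unstack("scope")
    )


def partial_correlation(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of y and x controlling covariates.

    Both variables are residualized on [1, covariates] by least squares;
    the correlation of the residuals is tested with a t statistic on
    N - 2 - c degrees of freedom (c covariates).  With no covariates
    this reduces to the plain Pearson correlation and its usual test.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    N = y.size
    if x.size != N:
        raise ValueError("y and x must have equal length")
    if covariates is None:
        Z = np.ones((N, 1))
        c = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != N:
            raise ValueError("covariate rows must match N")
        Z = np.column_stack([np.ones(N), C])
        c = C.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    df = N - 2 - c
    if df < 1:
        raise ValueError(f"not enough observations: N={N}, covariates={c}")
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    denom = np.sqrt((ry**2).sum() * (rx**2).sum())
    if denom == 0:
        raise ValueError("a variable is fully explained by the covariates")
    r = float((ry * rx).sum() / denom)
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def cortisol_association(
    summaries: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    cortisol_cols: tuple[str, ...] = ("pre_cortisol", "post_cortisol"),
) -> pd.DataFrame:
    """Partial correlations between connectivity summaries and cortisol.

    ``summaries`` is indexed by subject with one column per scope (as
    returned by :func:`hemispheric_summaries`); ``subjects`` carries the
    demographic covariates and cortisol levels, indexed alike.  Returns
    one row per (scope, cortisol measure) with the summary mean/sd and
    the partial r and p.
    """
    subjects = subjects.loc[summaries.index]
    C = subjects[list(covariates)].to_numpy(dtype=float)
    rows = []
    for scope in summaries.columns:
        vals = summaries[scope].to_numpy(dtype=float)
        for cort in cortisol_cols:
            r, p = partial_correlation(subjects[cort].to_numpy(dtype=float), vals, C)
            rows.append(
                {
                    "scope": scope,
                    "cortisol": cort,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                    "partial_r": r,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
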