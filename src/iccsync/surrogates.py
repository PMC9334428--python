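"""Surrogate-based significance for ICC maps and weak FDR control.

The null hypothesis is *absence of inter-subject synchronization*.  It is
emulated by Fourier phase randomization: each subject's time course at
each voxel keeps its amplitude spectrum (hence its autocorrelation up to
circularity) while its phases are redrawn independently, destroying any
alignment across subjects.  Recomputing the standardized agreement value
t_A on many such surrogate datasets yields an empirical null pooled
across in-mask voxels; observed t_A values are converted to empirical
p-values against that pool and thresholded with the Benjamini–Yekutieli
step-up rule, whose C(K) = sum_{i<=K} 1/i constant gives weak control of
the false discovery rate under arbitrary dependence between voxels.

A single pooled null (one brain-wide critical value) is used rather than
per-voxel nulls: with the default 50 surrogates per voxel, per-voxel
tails would rest on far too few values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .icc import icc_map

__all__ = [
    "SurrogateNull",
    "FDRConfig",
    "VoxelStatMap",
    "phase_randomize",
    "build_null",
    "empirical_pvalues",
    "by_fdr",
    "stat_maps",
]


@dataclass(frozen=True)
class SurrogateNull:
    """Pooled surrogate distribution of t_A values.

    ``null_t`` holds n_surrogates x K values (K in-mask voxels);
    ``critical_value`` is its empirical (1 - tail_prob) quantile.
    """

    n_surrogates: int
    null_t: np.ndarray
    critical_value: float
    tail_prob: float = 0.05
    rng_seed: int | None = None


@dataclass(frozen=True)
class FDRConfig:
    """Benjamini–Yekutieli step-up configuration for K tests at level alpha."""

    alpha: float
    K: int
    C_K: float
    critical_values: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class VoxelStatMap:
    """Brain-shaped statistic volumes plus the supra-threshold mask."""

    A_map: np.ndarray
    se_map: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    suprathreshold_mask: np.ndarray


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier phase-randomized surrogate of a real series.

    The amplitude spectrum (and hence mean and periodogram) is preserved
    exactly; phases of the non-DC, non-Nyquist bins are redrawn iid
    uniform(0, 2pi) with conjugate symmetry implied by the real FFT.  For
    even length the real-valued Nyquist bin has no free phase; its sign
    is randomized instead so the surrogate stays real.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 4:
        raise ValueError(f"series too short for phase randomization: n={n}")
    F = np.fft.rfft(x, axis=-1)
    nbins = F.shape[-1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=F.shape)
    rot = np.exp(1j * phases)
    rot[..., 0] = 1.0
    if n % 2 == 0:
        rot[..., nbins - 1] = rng.choice([-1.0, 1.0], size=F.shape[:-1])
    return np.fft.irfft(F * rot, n=n, axis=-1)


def build_null(
    all_voxel_matrices: np.ndarray,
    n_surrogates: int = 50,
    rng: np.random.Generator | int | None = None,
    tail_prob: float = 0.05,
) -> SurrogateNull:
    """Pooled surrogate null of t_A over all in-mask voxels.

    Parameters
    ----------
    all_voxel_matrices : (V, n, M) ndarray
        Every in-mask voxel's time-by-subject matrix.
    n_surrogates : int
        Surrogate replicates (default 50).
    rng : Generator or int seed
        Master randomness source; per-surrogate phase draws are taken
        from this single stream so one seed fixes the whole null.

    For each replicate every subject's series at every voxel is phase
    randomized independently and the full ICC chain is recomputed; the
    resulting t values are pooled across voxels and replicates.
    """
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    X = np.asarray(all_voxel_matrices, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"expected (V, n, M), got {X.shape}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    V, n, M = X.shape
    # randomize along time: move the time axis last for the FFT helper
    Xt = np.moveaxis(X, 1, 2)  # (V, M, n)
    pool = np.empty((n_surrogates, V))
    for s in range(n_surrogates):
        surr = np.moveaxis(phase_randomize(Xt, gen), 2, 1)  # back to (V, n, M)
        pool[s] = icc_map(surr)["t"]
    null_t = pool.ravel()
    null_t = null_t[np.isfinite(null_t)]
    crit = float(np.quantile(null_t, 1.0 - tail_prob))
    return SurrogateNull(
        n_surrogates=n_surrogates,
        null_t=null_t,
        critical_value=crit,
        tail_prob=tail_prob,
        rng_seed=seed,
    )


def empirical_pvalues(t_obs: np.ndarray, null: SurrogateNull) -> np.ndarray:
    """Upper-tail empirical p-values against the pooled null.

    p = (1 + #{null >= t_obs}) / (1 + N): the add-one correction keeps
    p strictly positive for finite pools.
    """
    null_t = np.sort(np.asarray(null.null_t))
    if null_t.size == 0:
        raise ValueError("empty surrogate null")
    t_obs = np.asarray(t_obs, dtype=float)
    n_ge = null_t.size - np.searchsorted(null_t, t_obs, side="left")
    return (1.0 + n_ge) / (1.0 + null_t.size)


def by_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[FDRConfig, np.ndarray]:
    """Benjamini–Yekutieli step-up over K p-values.

    Finds the largest rank i with p_(i) <= (i/K) * alpha / C(K),
    C(K) = sum_{j=1..K} 1/j, and rejects the i smallest p-values (all
    hypotheses tied at the boundary value included).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    K = p.size
    C_K = float(np.sum(1.0 / np.arange(1, K + 1)))
    crit = np.arange(1, K + 1) / K * (alpha / C_K)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    passing = np.flatnonzero(p_sorted <= crit)
    reject = np.zeros(K, dtype=bool)
    if passing.size:
        threshold = p_sorted[passing[-1]]
        reject = p <= threshold  # ties at the boundary all rejected
    return FDRConfig(alpha=alpha, K=K, C_K=C_K, critical_values=crit), reject


def stat_maps(
    all_voxel_matrices: np.ndarray,
    mask: np.ndarray,
    n_surrogates: int = 50,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[VoxelStatMap, SurrogateNull, FDRConfig]:
    """Full voxelwise inference: ICC maps, surrogate null, p-values, FDR.

    Parameters
    ----------
    all_voxel_matrices : (V, n, M) ndarray
        In-mask voxel data, ordered as ``mask`` enumerates True voxels
        (C order).
    mask : boolean ndarray
        Brain mask; V must equal ``mask.sum()``.

    Returns the brain-shaped statistic volumes (NaN outside the mask)
    together with the surrogate null and FDR configuration.
    """
    mask = np.asarray(mask, dtype=bool)
    X = np.asarray(all_voxel_matrices, dtype=float)
    if X.shape[0] != int(mask.sum()):
        raise ValueError(
            f"{X.shape[0]} voxel matrices but mask selects {int(mask.sum())} voxels"
        )
    stats = icc_map(X)
    null = build_null(X, n_surrogates=n_surrogates, rng=rng)
    p = empirical_pvalues(stats["t"], null)
    cfg, reject = by_fdr(p, alpha=alpha)

    def _vol(values, fill=np.nan, dtype=float):
        out = np.full(mask.shape, fill, dtype=dtype)
        out[mask] = values
        return out

    vm = VoxelStatMap(
        A_map=_vol(stats["A"]),
        se_map=_vol(stats["se_A"]),
        t_map=_vol(stats["t"]),
        p_map=_vol(p),
        suprathreshold_mask=_vol(reject, fill=False, dtype=bool),
    )
    return vm, null, cfg
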