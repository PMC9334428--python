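"""ICC agreement/consistency indices and their asymptotic variances.

A single voxel contributes an n-by-M matrix X of BOLD intensities: n time
points (rows) observed in M subjects (columns).  Two intraclass
correlation indices summarize how synchronized the M time courses are:

* the *consistency* index C-hat (ICC(C,M) = Shrout–Fleiss ICC(3,M)),
  which ignores between-subject differences in mean intensity, and
* the *agreement* index A-hat (ICC(A,M) = Shrout–Fleiss ICC(2,M)), which
  penalizes them.

Both are written in terms of two moment matrices: S, the M-by-M zero-lag
cross-covariance of the subject columns taken over time, and V, the
n-by-n covariance of the time rows taken across subjects.  The ratio

    Gamma = (1'V1 / n^2) / (1'S1 / M^2)

measures between-subject mean heterogeneity relative to the shared
covariance mass and drives the gap between A-hat and C-hat:

    A-hat ~= C-hat * (M-1) / ((M-1) + Gamma) + O(1/(nM)).

Under stationarity and rho-mixing of the time courses, the delta method
gives an asymptotic variance for C-hat via the half-vectorization
(duplication/elimination) calculus,

    Var(C-hat) = (2/n) eta' K_M (Sigma x Sigma) K_M' eta,   Sigma -> S,

with eta the derivative of ICC(C,M) with respect to vech(Sigma), and

    Var(A-hat) ~= Var(C-hat) * ((M-1) / ((M-1) + Gamma))^2,

yielding the standardized value t_A = A-hat / sqrt(Var(A-hat)) used for
voxelwise significance mapping.

Covariances use population-style divisors (S over n, V over M); with
these divisors A-hat and C-hat equal the ANOVA-based ICC(2,M) and
ICC(3,M) exactly, not just asymptotically.

Both a scalar per-voxel path (:func:`icc_estimate`) and a vectorized
many-voxel path (:func:`icc_map`) are provided; they compute identical
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateVoxelError",
    "NumericalFailure",
    "MomentMatrices",
    "GammaRatio",
    "SymmetryTransforms",
    "ICCEstimate",
    "moment_matrices",
    "gamma_ratio",
    "icc_agreement",
    "icc_consistency",
    "icc_variances",
    "t_statistic",
    "icc_estimate",
    "icc_map",
]

#: variances this far below zero are treated as rounding and clipped to 0;
#: anything more negative raises :class:`NumericalFailure`
_VAR_CLIP_TOL = 1e-12


class DegenerateVoxelError(ValueError):
    """Raised for voxel data that cannot support an ICC estimate.

    Triggers: fewer than 4 time points, fewer than 2 subjects, an
    all-constant subject column, or zero total covariance mass (1'S1 = 0).
    """


class NumericalFailure(ArithmeticError):
    """Raised when a computed variance is negative beyond rounding tolerance."""


@dataclass(frozen=True)
class MomentMatrices:
    """Column- and row-wise covariance summaries of one voxel's data.

    Attributes
    ----------
    S : (M, M) ndarray
        Zero-lag cross-covariance of subject time courses over time
        (divisor n).
    V : (n, n) ndarray
        Covariance of time rows across subjects (divisor M).
    trace_S, quad_S, quad_V : float
        tr(S), 1'S1 and 1'V1 respectively.
    """

    S: np.ndarray
    V: np.ndarray
    trace_S: float
    quad_S: float
    quad_V: float


@dataclass(frozen=True)
class GammaRatio:
    """The sample ratio Gamma estimating gamma = sigma_r^2 / sigma_c^2.

    ``sigma_r2`` is the mean element of V (between-subject mean
    heterogeneity); ``sigma_c2`` is the mean element of S (shared
    covariance mass).
    """

    Gamma: float
    sigma_r2: float
    sigma_c2: float


@dataclass(frozen=True)
class ICCEstimate:
    """Full per-voxel ICC summary (agreement, consistency, variances, t)."""

    A_hat: float
    A_approx: float
    C_hat: float
    Gamma: float
    eta: np.ndarray
    var_C: float
    var_A: float
    t_A: float
    remainder_bound: float


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D (n, M) matrix, got shape {X.shape}")
    return X


def moment_matrices(X: np.ndarray) -> MomentMatrices:
    """Compute S (column-wise) and V (row-wise) covariance matrices.

    Parameters
    ----------
    X : (n, M) array_like
        Time points by subjects, n >= 4 and M >= 2, no constant column.
    """
    X = _as_matrix(X)
    n, M = X.shape
    if n < 4:
        raise DegenerateVoxelError(f"need n >= 4 time points, got {n}")
    if M < 2:
        raise DegenerateVoxelError(f"need M >= 2 subjects, got {M}")
    col_var = X.var(axis=0)
    if np.any(col_var <= 0):
        bad = np.flatnonzero(col_var <= 0)
        raise DegenerateVoxelError(
            f"constant time course(s) for subject column(s) {bad.tolist()}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    S = (Xc.T @ Xc) / n
    Xr = X - X.mean(axis=1, keepdims=True)
    V = (Xr @ Xr.T) / M
    S = (S + S.T) / 2.0
    V = (V + V.T) / 2.0
    return MomentMatrices(
        S=S,
        V=V,
        trace_S=float(np.trace(S)),
        quad_S=float(S.sum()),
        quad_V=float(V.sum()),
    )


def gamma_ratio(m: MomentMatrices, n: int, M: int) -> GammaRatio:
    """The Gamma ratio (1'V1/n^2) / (1'S1/M^2)."""
    if m.quad_S <= 0:
        raise DegenerateVoxelError("1'S1 <= 0: no shared covariance mass")
    sigma_r2 = m.quad_V / n**2
    sigma_c2 = m.quad_S / M**2
    return GammaRatio(Gamma=sigma_r2 / sigma_c2, sigma_r2=sigma_r2, sigma_c2=sigma_c2)


def icc_consistency(m: MomentMatrices, M: int) -> float:
    """Consistency index ICC(C,M) = ICC(3,M): off-diagonal mass of S.

    Insensitive to per-subject mean shifts because S is built from
    column-centered data.
    """
    if m.quad_S <= 0:
        raise DegenerateVoxelError("1'S1 <= 0: no shared covariance mass")
    return (M / (M - 1)) * (m.quad_S - m.trace_S) / m.quad_S


def icc_agreement(
    m: MomentMatrices, g: GammaRatio, n: int, M: int
) -> tuple[float, float, float]:
    """Agreement index A-hat, its large-n approximation, and their gap.

    Returns ``(A_hat, A_approx, remainder_bound)`` where ``A_approx`` is
    the limit form C-hat * (M-1)/((M-1)+Gamma) and ``remainder_bound`` is
    |A_hat - A_approx|, an O(1/(nM)) quantity.
    """
    if m.quad_S <= 0:
        raise DegenerateVoxelError("1'S1 <= 0: no shared covariance mass")
    quad_S, tr_S, Gamma = m.quad_S, m.trace_S, g.Gamma
    numerator = (M / (M - 1)) * (quad_S - tr_S)
    bracket = (
        1.0
        + (n - 1) * Gamma / (n * (M - 1))
        - (M / (n * (M - 1))) * tr_S / quad_S
        + 1.0 / (n * (M - 1))
    )
    A_hat = numerator / (quad_S * bracket)
    C_hat = icc_consistency(m, M)
    A_approx = C_hat * (M - 1) / ((M - 1) + Gamma)
    return A_hat, A_approx, abs(A_hat - A_approx)


class SymmetryTransforms:
    """Half-vectorization calculus for symmetric M-by-M matrices.

    Provides vech/vec maps and the elimination matrix K_M (vech(A) =
    K_M vec(A)) and duplication matrix G_M (vec(A) = G_M vech(A)).  The
    dense matrices are materialized only on request — the variance
    formula itself is evaluated through O(M^2) index arithmetic.
    """

    def __init__(self, M: int):
        if M < 2:
            raise ValueError("M >= 2 required")
        self.M = M
        # lower-triangular (row, col) index pairs in vech order
        # (column-major over the lower triangle: (0,0),(1,0),...,(M-1,0),(1,1),...)
        self._rows, self._cols = np.tril_indices(M)
        order = np.lexsort((self._rows, self._cols))
        self._rows = self._rows[order]
        self._cols = self._cols[order]

    @property
    def size(self) -> int:
        return self.M * (self.M + 1) // 2

    def vech(self, A: np.ndarray) -> np.ndarray:
        """Stack the lower triangle of A column by column."""
        return np.asarray(A)[self._rows, self._cols]

    def unvech(self, v: np.ndarray) -> np.ndarray:
        """Symmetric matrix whose lower triangle is v (vech inverse)."""
        A = np.zeros((self.M, self.M))
        A[self._rows, self._cols] = v
        A[self._cols, self._rows] = v
        return A

    def elimination_matrix(self) -> np.ndarray:
        """Dense K_M with vech(A) = K_M vec(A) for symmetric A.

        Taken as the Moore–Penrose inverse of the duplication matrix,
        K_M = (G_M' G_M)^{-1} G_M', which satisfies both defining
        identities (vech = K vec on symmetric matrices and K G = I) and
        makes the quadratic form in the variance formula agree with the
        standard asymptotic covariance of sample covariances.  (The 0/1
        elimination matrix satisfies the same identities but averages
        the two copies of each off-diagonal element with weight (1, 0)
        instead of (1/2, 1/2), which breaks that agreement.)
        """
        G = self.duplication_matrix()
        return np.linalg.solve(G.T @ G, G.T)

    def duplication_matrix(self) -> np.ndarray:
        """Dense G_M with vec(A) = G_M vech(A), shape (M^2, M(M+1)/2)."""
        G = np.zeros((self.M**2, self.size))
        for h, (i, j) in enumerate(zip(self._rows, self._cols)):
            G[j * self.M + i, h] = 1.0
            G[i * self.M + j, h] = 1.0
        return G

    def dup_transpose_apply(self, R: np.ndarray) -> np.ndarray:
        """G_M' vec(R) without forming G_M: entry (i>=j) is R[i,j] + R[j,i]
        off the diagonal and R[i,i] on it."""
        v = R[self._rows, self._cols] + R[self._cols, self._rows]
        v[self._rows == self._cols] = R.diagonal()[self._rows[self._rows == self._cols]]
        return v

    def elim_transpose_unvec(self, eta: np.ndarray) -> np.ndarray:
        """Matrix form of K_M' eta (K_M the MP inverse of G_M).

        K_M' eta = G_M (G_M' G_M)^{-1} eta spreads each off-diagonal
        vech component of eta over its two symmetric positions with
        weight 1/2, so the result is the symmetric matrix whose vech-
        with-doubled-off-diagonals is eta.
        """
        W = np.zeros((self.M, self.M))
        off = self._rows != self._cols
        W[self._rows[off], self._cols[off]] = eta[off] / 2.0
        W[self._cols[off], self._rows[off]] = eta[off] / 2.0
        W[self._rows[~off], self._cols[~off]] = eta[~off]
        return W


def icc_variances(
    m: MomentMatrices,
    g: GammaRatio,
    n: int,
    M: int,
    tf: SymmetryTransforms | None = None,
) -> tuple[np.ndarray, float, float]:
    """Delta-method variance of C-hat and the induced variance of A-hat.

    Evaluates

        eta' = M / ((M-1)(1'Sigma 1)^2)
               * [ -(1'Sigma 1) vec'(I_M) + tr(Sigma) (1' x 1') ] G_M
        Var(C-hat) = (2/n) eta' K_M (Sigma x Sigma) K_M' eta
        Var(A-hat) = Var(C-hat) * ((M-1)/((M-1)+Gamma))^2

    with the population Sigma evaluated at the sample S.  The M^2-by-M^2
    Kronecker product is never materialized: with W the matrix form of
    K_M' eta, the quadratic form equals tr(W' Sigma W Sigma).

    Returns ``(eta, var_C, var_A)``.
    """
    if tf is None:
        tf = SymmetryTransforms(M)
    Sigma = m.S
    a = m.quad_S
    t = m.trace_S
    if a <= 0:
        raise DegenerateVoxelError("1'S1 <= 0: no shared covariance mass")
    coef = M / ((M - 1) * a**2)
    # row vector in vec space: -(1'S1) vec'(I) + tr(S) (1' x 1') = vec'(R)
    R = -a * np.eye(M) + t * np.ones((M, M))
    eta = coef * tf.dup_transpose_apply(R)
    W = tf.elim_transpose_unvec(eta)
    var_C = (2.0 / n) * float(np.trace(W.T @ Sigma @ W @ Sigma))
    if var_C < 0:
        if var_C < -_VAR_CLIP_TOL:
            raise NumericalFailure(f"negative Var(C-hat) = {var_C:g}")
        var_C = 0.0
    shrink = ((M - 1) / ((M - 1) + g.Gamma)) ** 2
    var_A = var_C * shrink
    return eta, var_C, var_A


def t_statistic(A_hat: float, var_A: float) -> float:
    """Standardized agreement value t_A = A_hat / sqrt(Var(A-hat))."""
    if var_A <= 0:
        raise NumericalFailure(f"Var(A-hat) must be positive, got {var_A:g}")
    return A_hat / np.sqrt(var_A)


def icc_estimate(X: np.ndarray) -> ICCEstimate:
    """Run the full per-voxel chain on an (n, M) matrix."""
    X = _as_matrix(X)
    n, M = X.shape
    m = moment_matrices(X)
    g = gamma_ratio(m, n, M)
    A_hat, A_approx, remainder = icc_agreement(m, g, n, M)
    C_hat = icc_consistency(m, M)
    eta, var_C, var_A = icc_variances(m, g, n, M)
    t_A = t_statistic(A_hat, var_A)
    return ICCEstimate(
        A_hat=A_hat,
        A_approx=A_approx,
        C_hat=C_hat,
        Gamma=g.Gamma,
        eta=eta,
        var_C=var_C,
        var_A=var_A,
        t_A=t_A,
        remainder_bound=remainder,
    )


def icc_map(X: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized ICC chain over many voxels at once.

    Parameters
    ----------
    X : (V, n, M) ndarray
        V voxels' time-by-subject matrices.

    Returns
    -------
    dict of (V,) arrays with keys ``A``, ``C``, ``Gamma``, ``var_C``,
    ``var_A``, ``se_A`` and ``t``.  Degenerate voxels (zero covariance
    mass) are returned as NaN rather than raising, so that whole-brain
    maps survive isolated bad voxels.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"expected (V, n, M), got shape {X.shape}")
    V, n, M = X.shape
    if n < 4 or M < 2:
        raise DegenerateVoxelError(f"need n >= 4 and M >= 2, got n={n}, M={M}")

    Xc = X - X.mean(axis=1, keepdims=True)
    S = np.einsum("vnm,vnk->vmk", Xc, Xc, optimize=True) / n
    tr_S = np.einsum("vmm->v", S)
    quad_S = S.sum(axis=(1, 2))

    # 1'V1 = (n^2 / M) * sum_i (colmean_i - grandmean)^2, avoiding the n-by-n V
    col_means = X.mean(axis=1)
    quad_V = (n**2 / M) * ((col_means - col_means.mean(axis=1, keepdims=True)) ** 2).sum(
        axis=1
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        ok = quad_S > 0
        quad_S_safe = np.where(ok, quad_S, np.nan)
        Gamma = (quad_V / n**2) / (quad_S_safe / M**2)
        C = (M / (M - 1)) * (quad_S_safe - tr_S) / quad_S_safe
        bracket = (
            1.0
            + (n - 1) * Gamma / (n * (M - 1))
            - (M / (n * (M - 1))) * tr_S / quad_S_safe
            + 1.0 / (n * (M - 1))
        )
        A = (M / (M - 1)) * (quad_S_safe - tr_S) / (quad_S_safe * bracket)

        # symmetric derivative matrix: off-diag coef*tr(S), diag coef*(tr(S)-1'S1)
        coef = M / ((M - 1) * quad_S_safe**2)
        W = np.broadcast_to((coef * tr_S)[:, None, None], S.shape).copy()
        dg = np.arange(M)
        W[:, dg, dg] = (coef * (tr_S - quad_S_safe))[:, None]
        prod = W @ S @ W @ S
        var_C = (2.0 / n) * np.einsum("vmm->v", prod)
        var_C = np.where((var_C < 0) & (var_C > -_VAR_CLIP_TOL), 0.0, var_C)
        if np.any(var_C < 0):
            raise NumericalFailure("negative Var(C-hat) beyond rounding tolerance")
        var_A = var_C * ((M - 1) / ((M - 1) + Gamma)) ** 2
        se_A = np.sqrt(var_A)
        t = A / se_A

    return {
        "A": A,
        "C": C,
        "Gamma": Gamma,
        "var_C": var_C,
        "var_A": var_A,
        "se_A": se_A,
        "t": t,
    }
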