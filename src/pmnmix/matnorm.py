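"""The matrix normal distribution: density, sampling, and maximum likelihood.

A random p x q matrix X follows the matrix normal law N_{p,q}(M, U, V) when
vec(X) ~ N_{pq}(vec(M), V (x) U), with M the mean matrix, U the p x p row
covariance and V the q x q column covariance ((x) denotes the Kronecker
product).  The Kronecker-separable covariance is never materialized here:
all densities and fits work with the small factors through their Cholesky
decompositions.

Only V (x) U is identified: (aU, V/a) gives the same distribution for any
a > 0.  The scale is pinned by :func:`normalize_scale`, which rescales the
pair so that trace(U) = p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import (
    ConvergenceError,
    DefinitenessError,
    RankDeficiencyError,
    ShapeError,
)

__all__ = [
    "MatrixNormalParams",
    "MatrixSampleSet",
    "matnorm_logpdf",
    "matnorm_logpdf_stack",
    "sample_matnorm",
    "fit_matnorm_mle",
    "normalize_scale",
]

_SYM_TOL = 1e-10


def _check_spd(A: np.ndarray, name: str) -> np.ndarray:
    """Validate symmetry and positive definiteness; return the Cholesky factor."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"{name} must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=_SYM_TOL * max(1.0, np.abs(A).max())):
        raise DefinitenessError(f"{name} is not symmetric", matrix_name=name)
    try:
        return linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as exc:
        raise DefinitenessError(
            f"{name} is not positive definite", matrix_name=name
        ) from exc


@dataclass
class MatrixNormalParams:
    """Parameters (M, U, V) of one matrix normal distribution.

    Parameters
    ----------
    M : (p, q) ndarray
        Mean matrix.
    U : (p, p) ndarray
        Row covariance, symmetric positive definite.
    V : (q, q) ndarray
        Column covariance, symmetric positive definite.
    U_inv, V_inv : ndarray, optional
        Row/column precision matrices.  Populated by the penalized fits
        (where the precision, not the covariance, is the sparse object);
        computed on demand otherwise.
    """

    M: np.ndarray
    U: np.ndarray
    V: np.ndarray
    U_inv: np.ndarray | None = field(default=None, repr=False)
    V_inv: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.M.ndim != 2:
            raise ShapeError(f"M must be 2-D, got shape {self.M.shape}")
        p, q = self.M.shape
        self._chol_U = _check_spd(self.U, "U")
        self._chol_V = _check_spd(self.V, "V")
        if self.U.shape != (p, p):
            raise ShapeError(
                f"U has shape {self.U.shape}, expected ({p}, {p}) to match M"
            )
        if self.V.shape != (q, q):
            raise ShapeError(
                f"V has shape {self.V.shape}, expected ({q}, {q}) to match M"
            )

    @property
    def p(self) -> int:
        return self.M.shape[0]

    @property
    def q(self) -> int:
        return self.M.shape[1]

    @property
    def chol_U(self) -> np.ndarray:
        """Lower Cholesky factor of U."""
        return self._chol_U

    @property
    def chol_V(self) -> np.ndarray:
        """Lower Cholesky factor of V."""
        return self._chol_V

    def precision_U(self) -> np.ndarray:
        """U^{-1}, reusing a cached sparse estimate when available."""
        if self.U_inv is None:
            self.U_inv = _chol_inverse(self._chol_U)
        return self.U_inv

    def precision_V(self) -> np.ndarray:
        """V^{-1}, reusing a cached sparse estimate when available."""
        if self.V_inv is None:
            self.V_inv = _chol_inverse(self._chol_V)
        return self.V_inv


def _chol_inverse(L: np.ndarray) -> np.ndarray:
    """Inverse of A = L L^T from its lower Cholesky factor, symmetrized."""
    inv = linalg.cho_solve((L, True), np.eye(L.shape[0]))
    return (inv + inv.T) / 2.0


@dataclass
class MatrixSampleSet:
    """A stack of n real matrices of common size p x q."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError(
                f"sample stack must be 3-D (n, p, q), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ShapeError("sample set must contain at least one matrix")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    @property
    def q(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i):
        return self.data[i]

    def vectorized(self) -> np.ndarray:
        """(n, pq) array of column-stacked (vec) samples."""
        return self.data.transpose(0, 2, 1).reshape(self.n, self.p * self.q)


def matnorm_logpdf(X: np.ndarray, params: MatrixNormalParams) -> float:
    """Log-density of one p x q matrix under N_{p,q}(M, U, V).

    Evaluates
    ``-(pq/2) log 2*pi - (p/2) log|V| - (q/2) log|U|
    - (1/2) tr(V^{-1} (X-M)^T U^{-1} (X-M))``
    through Cholesky factorizations of the small factors.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (params.p, params.q):
        raise ShapeError(
            f"X has shape {X.shape}, expected ({params.p}, {params.q})"
        )
    return float(matnorm_logpdf_stack(X[None, :, :], params)[0])


def matnorm_logpdf_stack(X: np.ndarray, params: MatrixNormalParams) -> np.ndarray:
    """Vectorized log-density for a stack of matrices, shape (n, p, q) -> (n,)."""
    if isinstance(X, MatrixSampleSet):
        X = X.data
    X = np.asarray(X, dtype=float)
    n, p, q = X.shape
    if (p, q) != (params.p, params.q):
        raise ShapeError(
            f"samples are {p} x {q}, parameters are {params.p} x {params.q}"
        )
    Lu, Lv = params.chol_U, params.chol_V
    logdet_U = 2.0 * np.sum(np.log(np.diag(Lu)))
    logdet_V = 2.0 * np.sum(np.log(np.diag(Lv)))
    D = X - params.M
    # tr(V^-1 D^T U^-1 D) = || Lu^-1 D Lv^-T ||_F^2
    A = linalg.solve_triangular(
        Lu, np.ascontiguousarray(D.transpose(1, 0, 2)).reshape(p, n * q),
        lower=True, check_finite=False,
    ).reshape(p, n, q)
    B = linalg.solve_triangular(
        Lv, np.ascontiguousarray(A.transpose(2, 1, 0)).reshape(q, n * p),
        lower=True, check_finite=False,
    ).reshape(q, n, p)
    quad = np.einsum("qnp,qnp->n", B, B)
    return (
        -0.5 * p * q * np.log(2.0 * np.pi)
        - 0.5 * p * logdet_V
        - 0.5 * q * logdet_U
        - 0.5 * quad
    )


def sample_matnorm(
    params: MatrixNormalParams,
    n: int,
    seed: int | np.random.Generator = 0,
) -> MatrixSampleSet:
    """Draw n i.i.d. matrices via X = M + A Z B^T with A A^T = U, B B^T = V."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, params.p, params.q))
    X = params.M + params.chol_U @ Z @ params.chol_V.T
    return MatrixSampleSet(X)


def normalize_scale(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the (aU, V/a) scale indeterminacy: return (cU, V/c), c = p/tr(U).

    Leaves the Kronecker product V (x) U unchanged while pinning
    trace(U) = p, so reported row covariances are on a common scale.
    """
    _check_spd(U, "U")
    _check_spd(V, "V")
    p = U.shape[0]
    c = p / np.trace(U)
    return c * U, V / c


def fit_matnorm_mle(
    samples: MatrixSampleSet | np.ndarray,
    tol: float = 0.01,
    max_iter: int = 100,
) -> MatrixNormalParams:
    """Maximum likelihood fit of (M, U, V) by the flip-flop algorithm.

    M is the sample mean.  U and V have no closed form; they are obtained by
    alternating the two conditional MLE updates (U given V, then V given the
    new U) until the relative Frobenius change of both factors drops below
    ``tol`` (default 0.01).  The returned pair is scale-normalized with
    trace(U) = p.

    Raises
    ------
    RankDeficiencyError
        If an intermediate scatter matrix is singular (too few samples, or
        degenerate data); increase n or add a ridge.
    ConvergenceError
        If ``max_iter`` alternations do not meet the criterion.
    """
    if isinstance(samples, np.ndarray):
        samples = MatrixSampleSet(samples)
    X = samples.data
    n, p, q = X.shape
    M = X.mean(axis=0)
    D = X - M
    V = np.eye(q)
    U = np.eye(p)
    for _ in range(max_iter):
        U_new = _flip_flop_U(D, V, n, q)
        V_new = _flip_flop_V(D, U_new, n, p)
        rel_U = np.linalg.norm(U_new - U, "fro") / max(np.linalg.norm(U, "fro"), 1e-300)
        rel_V = np.linalg.norm(V_new - V, "fro") / max(np.linalg.norm(V, "fro"), 1e-300)
        U, V = U_new, V_new
        if rel_U < tol and rel_V < tol:
            U, V = normalize_scale(U, V)
            return MatrixNormalParams(M=M, U=U, V=V)
    raise ConvergenceError(
        f"flip-flop did not converge in {max_iter} iterations",
        last=(M, U, V),
    )


def _spd_scatter(S: np.ndarray, what: str) -> np.ndarray:
    S = (S + S.T) / 2.0
    try:
        linalg.cholesky(S, lower=True)
    except linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            f"{what} scatter matrix is singular; provide more samples "
            "or add a ridge"
        ) from exc
    return S


def _flip_flop_U(D: np.ndarray, V: np.ndarray, n: int, q: int) -> np.ndarray:
    Lv = _check_spd(V, "V")
    # sum_i D_i V^-1 D_i^T = || D_i Lv^-T ||  accumulated as A A^T
    A = linalg.solve_triangular(
        Lv, np.ascontiguousarray(D.transpose(2, 0, 1)).reshape(q, -1),
        lower=True, check_finite=False,
    ).reshape(q, n, D.shape[1])
    S = np.tensordot(A, A, axes=((0, 1), (0, 1))) / (n * q)
    return _spd_scatter(S, "row (U)")


def _flip_flop_V(D: np.ndarray, U: np.ndarray, n: int, p: int) -> np.ndarray:
    Lu = _check_spd(U, "U")
    A = linalg.solve_triangular(
        Lu, np.ascontiguousarray(D.transpose(1, 0, 2)).reshape(p, -1),
        lower=True, check_finite=False,
    ).reshape(p, n, D.shape[2])
    S = np.tensordot(A, A, axes=((0, 1), (0, 1))) / (n * p)
    return _spd_scatter(S, "column (V)")
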