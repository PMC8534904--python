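"""EM algorithms for (penalized) matrix normal mixture models.

The unpenalized matrix normal mixture model (MNMM) is a G-component mixture
of matrix normal distributions fitted by EM: the E-step computes posterior
membership probabilities tau_ij, and the M-step updates the weights,
component means, and row/column covariance factors by weighted flip-flop
updates.

The penalized model (PMNMM) adds three lasso penalties to the mixture
log-likelihood,

    Lp = sum_i log sum_j pi_j f(X_i | M_j, U_j, V_j)
         - lambda1 * sum_j |M_j|_1
         - lambda2 * sum_j |U_j^{-1}|_1
         - lambda3 * sum_j |V_j^{-1}|_1,

so the M-step becomes: a closed-form soft-threshold update for each mean
matrix, and two graphical-lasso problems per component for the sparse row
and column precisions.  Iteration stops by an Aitken-accelerated criterion
on the penalized log-likelihood.  Multiple restarts from K-means
initializations guard against local maxima.

Setting lambda2 = lambda3 = 0 recovers the mean-only penalized model, and
all-zero penalties recover the plain MNMM fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .exceptions import (
    ConvergenceError,
    DegenerateSampleError,
    EmptyClusterError,
    FitFailureError,
    RankDeficiencyError,
    ShapeError,
    SingularityError,
)
from .matnorm import (
    MatrixNormalParams,
    MatrixSampleSet,
    _chol_inverse,
    fit_matnorm_mle,
    matnorm_logpdf_stack,
    normalize_scale,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyConfig",
    "EMTrace",
    "MixtureModel",
    "e_step",
    "update_weights",
    "update_means_penalized",
    "weighted_scatter_U",
    "weighted_scatter_V",
    "solve_penalized_precision",
    "kkt_residual",
    "update_precisions",
    "penalized_loglik",
    "aitken_should_stop",
    "init_kmeans",
    "fit_pmnmm",
    "predict_labels",
]

#: responsibilities are floored at this value before row normalization
_TAU_FLOOR = 1e-300


@dataclass(frozen=True)
class PenaltyConfig:
    """Lasso penalty weights (lambda1 on means, lambda2/lambda3 on precisions)."""

    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def astuple(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)


@dataclass
class EMTrace:
    """Per-iteration diagnostics of one EM run."""

    loglik_history: list[float] = field(default_factory=list)
    aitken_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    restart_index: int = 0


@dataclass
class MixtureModel:
    """A fitted (or initial) matrix normal mixture."""

    weights: np.ndarray
    components: list[MatrixNormalParams]
    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)
    trace: EMTrace = field(default_factory=EMTrace)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.components) != self.weights.size:
            raise ShapeError("weights length must equal the number of components")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be positive and sum to 1")

    @property
    def G(self) -> int:
        return len(self.components)

    @property
    def p(self) -> int:
        return self.components[0].p

    @property
    def q(self) -> int:
        return self.components[0].q


def _as_stack(samples) -> np.ndarray:
    if isinstance(samples, MatrixSampleSet):
        return samples.data
    return np.asarray(samples, dtype=float)


def _log_densities(X: np.ndarray, model: MixtureModel) -> np.ndarray:
    """(n, G) matrix of log pi_j + log f(X_i | component j)."""
    cols = [
        np.log(model.weights[j]) + matnorm_logpdf_stack(X, model.components[j])
        for j in range(model.G)
    ]
    return np.column_stack(cols)


def e_step(samples, model: MixtureModel) -> np.ndarray:
    """Posterior membership probabilities tau (n, G), rows summing to 1.

    Computed in log space with per-row max subtraction so that the
    pq-dimensional densities (which underflow raw floating point for
    20 x 20 matrices) remain usable.
    """
    X = _as_stack(samples)
    logd = _log_densities(X, model)
    bad = ~np.isfinite(logd.max(axis=1))
    if np.any(bad):
        row = int(np.nonzero(bad)[0][0])
        raise DegenerateSampleError(
            f"all component densities underflowed for sample {row}", row=row
        )
    tau = np.exp(logd - logd.max(axis=1, keepdims=True))
    tau = np.maximum(tau, _TAU_FLOOR)
    return tau / tau.sum(axis=1, keepdims=True)


def update_weights(tau: np.ndarray) -> np.ndarray:
    """Mixing weights: column means of the responsibilities."""
    return np.asarray(tau, dtype=float).mean(axis=0)


def _soft_threshold(A: np.ndarray, T: np.ndarray) -> np.ndarray:
    return np.sign(A) * np.maximum(np.abs(A) - T, 0.0)


def update_means_penalized(
    samples,
    tau: np.ndarray,
    model: MixtureModel,
    lambda1: float,
) -> list[np.ndarray]:
    """Soft-thresholded mean update for every component.

    For component j the weighted mean ``Mhat_j = sum_i tau_ij X_i / sum_i
    tau_ij`` is shrunk elementwise by the threshold matrix
    ``(lambda1 / sum_i tau_ij) * U_j 1_{pxq} V_j``.  Negative threshold
    entries (possible when U or V has negative off-diagonal row/column sums)
    are clamped to zero, i.e. no shrinkage for those entries.
    """
    X = _as_stack(samples)
    means = []
    for j in range(model.G):
        w = tau[:, j]
        sw = w.sum()
        if sw <= 0:
            raise EmptyClusterError(f"component {j} has zero total responsibility")
        Mhat = np.einsum("i,ipq->pq", w, X) / sw
        if lambda1 > 0:
            comp = model.components[j]
            T = np.outer(comp.U.sum(axis=1), comp.V.sum(axis=0)) * (lambda1 / sw)
            np.maximum(T, 0.0, out=T)
            Mhat = _soft_threshold(Mhat, T)
        means.append(Mhat)
    return means


def weighted_scatter_U(samples, tau_col, M, V_inv) -> np.ndarray:
    """Weighted, V^{-1}-whitened row scatter (p x p), divisor q * sum(tau)."""
    X = _as_stack(samples)
    w = np.asarray(tau_col, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise EmptyClusterError("zero total responsibility in scatter")
    D = X - M
    q = D.shape[2]
    A = (D * w[:, None, None]) @ V_inv
    S = np.tensordot(A, D, axes=((0, 2), (0, 2))) / (q * sw)
    return (S + S.T) / 2.0


def weighted_scatter_V(samples, tau_col, M, U_inv) -> np.ndarray:
    """Weighted, U^{-1}-whitened column scatter (q x q), divisor p * sum(tau)."""
    X = _as_stack(samples)
    w = np.asarray(tau_col, dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise EmptyClusterError("zero total responsibility in scatter")
    D = X - M
    p = D.shape[1]
    A = U_inv @ (D * w[:, None, None])
    S = np.tensordot(A, D, axes=((0, 1), (0, 1))) / (p * sw)
    return (S + S.T) / 2.0


def solve_penalized_precision(
    S: np.ndarray,
    rho: float,
    penalize_diagonal: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Sparse precision: argmax_Theta log|Theta| - tr(S Theta) - rho |Theta|_1.

    Backed by the graphical lasso.  With ``penalize_diagonal`` (the default)
    the L1 penalty covers every entry of Theta; this is solved exactly as an
    off-diagonal-penalty problem on ``S + rho I``, whose KKT conditions
    coincide with the fully penalized ones.  ``rho = 0`` returns the plain
    inverse of S (which must then be nonsingular).

    The KKT residual of the returned solution is checked against 1e-4; a
    violating solve is retried at tighter tolerance and raises
    :class:`ConvergenceError` if it still fails.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ShapeError(f"scatter must be square, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ShapeError("scatter must be symmetric")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    d = S.shape[0]
    if rho == 0.0:
        try:
            L = linalg.cholesky(S, lower=True)
        except linalg.LinAlgError as exc:
            raise SingularityError(
                "unpenalized precision requested but the scatter is singular"
            ) from exc
        return _chol_inverse(L)

    target = S + rho * np.eye(d) if penalize_diagonal else S
    theta = None
    for attempt_tol in (tol, tol * 1e-2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                _, theta = graphical_lasso(
                    target, alpha=rho, tol=attempt_tol,
                    enet_tol=attempt_tol, max_iter=max_iter,
                )
            except FloatingPointError as exc:
                raise ConvergenceError(
                    f"graphical lasso failed on a {d} x {d} scatter: {exc}",
                    last=theta,
                ) from exc
        theta = (theta + theta.T) / 2.0
        if kkt_residual(theta, S, rho, penalize_diagonal) <= 1e-4:
            return theta
    raise ConvergenceError(
        "graphical lasso KKT residual above 1e-4 after retries", last=theta
    )


def kkt_residual(
    theta: np.ndarray,
    S: np.ndarray,
    rho: float,
    penalize_diagonal: bool = True,
) -> float:
    """Max stationarity violation of a graphical-lasso solution.

    With W = Theta^{-1}: penalized nonzero entries must satisfy
    W = S + rho * sign(Theta); penalized zero entries |W - S| <= rho;
    unpenalized entries W = S.
    """
    W = np.linalg.inv(theta)
    d = theta.shape[0]
    pen = np.ones((d, d), dtype=bool)
    if not penalize_diagonal:
        np.fill_diagonal(pen, False)
    nz = theta != 0.0
    res = np.abs(W - S)  # unpenalized entries
    res[pen & nz] = np.abs(W - S - rho * np.sign(theta))[pen & nz]
    res[pen & ~nz] = np.maximum(np.abs(W - S) - rho, 0.0)[pen & ~nz]
    return float(res.max())


def update_precisions(
    samples,
    tau: np.ndarray,
    model: MixtureModel,
    lambda2: float,
    lambda3: float,
    penalize_diagonal: bool = True,
) -> list[MatrixNormalParams]:
    """Graphical-lasso M-step for every component's (U^{-1}, V^{-1}).

    For each component j (means assumed already updated this M-step):
    the row precision solves the graphical lasso on the V^{-1}-whitened row
    scatter with penalty ``2 lambda2 / (q sum_i tau_ij)``; the column
    precision then solves on the column scatter whitened by the *new* row
    precision, with penalty ``2 lambda3 / (p sum_i tau_ij)``.  The stored
    covariances are the inverses, scale-normalized to trace(U) = p.
    """
    X = _as_stack(samples)
    p, q = model.p, model.q
    out = []
    for j in range(model.G):
        comp = model.components[j]
        w = tau[:, j]
        sw = w.sum()
        if sw <= 0:
            raise EmptyClusterError(f"component {j} has zero total responsibility")
        S_U = weighted_scatter_U(X, w, comp.M, comp.precision_V())
        U_inv = solve_penalized_precision(
            S_U, 2.0 * lambda2 / (q * sw), penalize_diagonal
        )
        S_V = weighted_scatter_V(X, w, comp.M, U_inv)
        V_inv = solve_penalized_precision(
            S_V, 2.0 * lambda3 / (p * sw), penalize_diagonal
        )
        U = _chol_inverse(linalg.cholesky(U_inv, lower=True))
        V = _chol_inverse(linalg.cholesky(V_inv, lower=True))
        c = p / np.trace(U)
        out.append(
            MatrixNormalParams(
                M=comp.M, U=c * U, V=V / c, U_inv=U_inv / c, V_inv=V_inv * c
            )
        )
    return out


def penalized_loglik(samples, model: MixtureModel) -> float:
    """Mixture log-likelihood minus the three L1 penalty terms.

    With all penalties zero this is the plain MNMM log-likelihood.
    """
    X = _as_stack(samples)
    ll = float(logsumexp(_log_densities(X, model), axis=1).sum())
    lam1, lam2, lam3 = model.penalties.astuple()
    for comp in model.components:
        if lam1 > 0:
            ll -= lam1 * np.abs(comp.M).sum()
        if lam2 > 0:
            ll -= lam2 * np.abs(comp.precision_U()).sum()
        if lam3 > 0:
            ll -= lam3 * np.abs(comp.precision_V()).sum()
    return ll


def aitken_should_stop(
    loglik_history, epsilon: float = 1e-3
) -> tuple[bool, float | None]:
    """Aitken-accelerated EM stopping rule.

    With l(t) the current penalized log-likelihood, the acceleration
    coefficient a(t) = (l(t) - l(t-1)) / (l(t-1) - l(t-2)) extrapolates the
    sequence to its limit l_hat(t) = l(t-1) + (l(t) - l(t-1)) / (1 - a(t));
    iteration stops when 0 <= l_hat(t) - l(t) <= epsilon, i.e. when the
    extrapolated remaining improvement is below ``epsilon`` log-likelihood
    units.  The tolerance is absolute: a relative-to-|l| version is
    scale-dependent (|l| grows with n and pq, making the rule looser
    exactly when the fit is hardest) and fires long before the
    responsibilities stabilize.

    Degenerate cases: fewer than three values -> continue; an exactly flat
    step (zero denominator in a(t)) -> stop; a(t) >= 1 means the increments
    are not contracting, so no finite limit can be extrapolated -> continue.
    """
    h = list(loglik_history)
    if len(h) < 3:
        return False, None
    l2, l1, l0 = h[-3], h[-2], h[-1]
    denom = l1 - l2
    if denom == 0.0:
        return True, l0
    a = (l0 - l1) / denom
    if a >= 1.0:
        return False, None
    l_hat = l1 + (l0 - l1) / (1.0 - a)
    return bool(0.0 <= l_hat - l0 <= epsilon), l_hat


def init_kmeans(
    samples,
    G: int,
    seed: int = 0,
    penalties: PenaltyConfig | None = None,
    random_start: bool = False,
) -> MixtureModel:
    """K-means initialization: cluster vectorized samples, fit per-cluster MLEs.

    With ``random_start`` the partition comes from a single K-means run with
    random initial centers (a deliberately diverse start for multi-start EM);
    otherwise from the best of 10 k-means++ runs.  Clusters too small (or too
    degenerate) for the flip-flop MLE fall back to a diagonal initialization
    U = s I_p, V = I_q with s the cluster's mean elementwise variance.
    """
    if isinstance(samples, np.ndarray):
        samples = MatrixSampleSet(samples)
    n, p, q = samples.n, samples.p, samples.q
    if n < G:
        raise ValueError(f"need at least G={G} samples, got {n}")
    if random_start:
        km = KMeans(n_clusters=G, n_init=1, init="random", random_state=seed)
    else:
        km = KMeans(n_clusters=G, n_init=10, random_state=seed)
    labels = km.fit(samples.vectorized()).labels_
    weights = np.bincount(labels, minlength=G) / n
    if np.any(weights == 0):  # pragma: no cover - kmeans rarely empties a cluster
        weights = (np.bincount(labels, minlength=G) + 1.0) / (n + G)
    components = []
    for j in range(G):
        Xj = samples.data[labels == j]
        try:
            comp = fit_matnorm_mle(Xj)
        except (RankDeficiencyError, ConvergenceError, ValueError):
            M = Xj.mean(axis=0) if len(Xj) else samples.data.mean(axis=0)
            s = float(Xj.var()) if len(Xj) > 1 else float(samples.data.var())
            comp = MatrixNormalParams(M=M, U=max(s, 1e-6) * np.eye(p), V=np.eye(q))
        components.append(comp)
    return MixtureModel(
        weights=weights,
        components=components,
        penalties=penalties or PenaltyConfig(),
    )


def _em_run(
    samples: MatrixSampleSet,
    model: MixtureModel,
    epsilon: float,
    max_iter: int,
    tau_floor_count: float,
    penalize_diagonal: bool,
) -> tuple[MixtureModel, np.ndarray]:
    """One EM run from a given initialization; raises on degenerate paths.

    Returns the fitted model and the final per-component responsibility
    mass (used by the caller to rank degenerate against healthy restarts).
    """
    lam1, lam2, lam3 = model.penalties.astuple()
    trace = EMTrace()
    tau = None
    for t in range(max_iter):
        tau = e_step(samples, model)
        if np.any(tau.sum(axis=0) < tau_floor_count):
            raise EmptyClusterError(
                f"a component's total responsibility fell below "
                f"{tau_floor_count:.1f} at iteration {t}"
            )
        weights = update_weights(tau)
        means = update_means_penalized(samples, tau, model, lam1)
        model = MixtureModel(
            weights=weights,
            components=[
                replace(c, M=m, U_inv=c.U_inv, V_inv=c.V_inv)
                for c, m in zip(model.components, means)
            ],
            penalties=model.penalties,
        )
        comps = update_precisions(
            samples, tau, model, lam2, lam3, penalize_diagonal
        )
        model = MixtureModel(
            weights=weights, components=comps, penalties=model.penalties
        )
        lp = penalized_loglik(samples, model)
        trace.loglik_history.append(lp)
        stop, l_hat = aitken_should_stop(trace.loglik_history, epsilon)
        if l_hat is not None:
            trace.aitken_history.append(l_hat)
        trace.n_iter = t + 1
        if stop:
            trace.converged = True
            break
    model.trace = trace
    return model, tau.sum(axis=0)


def fit_pmnmm(
    samples,
    G: int,
    penalties: PenaltyConfig | tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_restarts: int = 5,
    seed: int = 0,
    epsilon: float = 1e-3,
    max_iter: int = 200,
    penalize_diagonal: bool = True,
) -> MixtureModel:
    """Fit the penalized matrix normal mixture by multi-start EM.

    Each restart draws a fresh K-means initialization (restart seeds are
    derived deterministically from ``seed``), runs EM with the Aitken
    stopping rule, and the restart with the highest final penalized
    log-likelihood wins.  The first restart initializes from the best of 10
    k-means++ runs; later restarts use single random-center K-means runs so
    the starts actually explore different basins.

    Restarts whose final solution leaves some component with responsibility
    mass below max(p, q) + 1 samples are flagged as degenerate (the classic
    tiny-component likelihood inflation of Gaussian mixtures) and lose to
    any healthy restart regardless of log-likelihood; they are returned
    only when every restart ends degenerate.  Restarts that collapse
    outright (singular scatter, failed precision solve, vanishing
    responsibilities) are logged and discarded; if every restart fails a
    :class:`FitFailureError` summarizes the causes.
    """
    if isinstance(samples, np.ndarray):
        samples = MatrixSampleSet(samples)
    if not isinstance(penalties, PenaltyConfig):
        penalties = PenaltyConfig(*penalties)
    if samples.n < G:
        raise ValueError(f"need at least G={G} samples, got {samples.n}")
    p, q = samples.p, samples.q
    # mid-run floor: rank requirement for the whitened scatters,
    # sum(tau) * q > p and sum(tau) * p > q, plus one sample of slack
    tau_floor_count = float(max(p / q, q / p) + 1.0)
    # final-solution mass below this marks a degenerate tiny component
    degenerate_mass = float(max(p, q) + 1)
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best: MixtureModel | None = None
    best_healthy = False
    failures: list[str] = []
    for r in range(n_restarts):
        try:
            init = init_kmeans(
                samples, G, seed=int(restart_seeds[r]),
                penalties=penalties, random_start=(r > 0),
            )
            fitted, mass = _em_run(
                samples, init, epsilon, max_iter, tau_floor_count, penalize_diagonal
            )
        except (
            EmptyClusterError,
            RankDeficiencyError,
            SingularityError,
            ConvergenceError,
            DegenerateSampleError,
        ) as exc:
            logger.warning("restart %d failed: %s", r, exc)
            failures.append(f"restart {r}: {exc}")
            continue
        fitted.trace.restart_index = r
        healthy = bool(np.all(mass >= degenerate_mass))
        better = best is None or (
            (healthy, fitted.trace.loglik_history[-1])
            > (best_healthy, best.trace.loglik_history[-1])
        )
        if better:
            best, best_healthy = fitted, healthy
    if best is None:
        raise FitFailureError(
            "all EM restarts failed: " + "; ".join(failures)
        )
    if not best_healthy:
        logger.warning(
            "every restart converged to a degenerate tiny-component solution"
        )
    return best


def predict_labels(samples, model: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """MAP component labels (ties broken toward the lower index) and tau."""
    tau = e_step(samples, model)
    return tau.argmax(axis=1), tau
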