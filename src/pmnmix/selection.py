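"""Hyperparameter selection for penalized matrix normal mixtures.

The model has four hyperparameters (G, lambda1, lambda2, lambda3).  They are
chosen by K-fold cross-validation of the penalized log-likelihood: for each
candidate tuple, the model is fitted on K-1 folds and the penalized
log-likelihood of the held-out fold is computed with the trained parameters;
the tuple with the largest mean held-out score wins.  Ties are broken toward
larger penalties (the sparser model).

Also provides the parameter-count formulas contrasting the vectorized
Gaussian mixture (one pq x pq covariance per component) with the
mean-penalized and fully penalized matrix normal mixtures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import PenaltyConfig, fit_pmnmm, penalized_loglik
from .exceptions import PmnmixError
from .matnorm import MatrixSampleSet

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "kfold_split",
    "cv_score",
    "grid_search",
    "count_parameters",
]


def kfold_split(n: int, K: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded random partition of range(n) into K folds of near-equal size."""
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError(f"K={K} folds require at least {K} samples, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, K)]


def cv_score(
    samples,
    G: int,
    penalties: PenaltyConfig | tuple[float, float, float],
    K: int = 4,
    seed: int = 0,
    **fit_options,
) -> float:
    """Mean held-out penalized log-likelihood over K folds.

    Each fold's fit uses a fresh K-means initialization seeded from ``seed``.
    A failed fold fit yields a score of -inf (logged, never raised) so a bad
    grid point cannot crash a search.
    """
    if isinstance(samples, np.ndarray):
        samples = MatrixSampleSet(samples)
    if not isinstance(penalties, PenaltyConfig):
        penalties = PenaltyConfig(*penalties)
    folds = kfold_split(samples.n, K, seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(K) % (2**31)
    scores = []
    all_idx = np.arange(samples.n)
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        try:
            model = fit_pmnmm(
                samples.data[train_idx], G, penalties,
                seed=int(fold_seeds[k]), **fit_options,
            )
            scores.append(penalized_loglik(samples.data[test_idx], model))
        except PmnmixError as exc:
            logger.warning("fold %d fit failed (%s); scoring -inf", k, exc)
            return float("-inf")
    return float(np.mean(scores))


@dataclass
class CVResult:
    """Grid-search outcome: every tuple's CV score and the selected tuple."""

    grid: list[tuple[int, float, float, float]]
    scores: list[float]
    best: tuple[int, float, float, float]
    K: int
    seed: int = 0
    fold_scores: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per (G, lambda1, lambda2, lambda3) with its mean CV score."""
        df = pd.DataFrame(
            self.grid, columns=["G", "lambda1", "lambda2", "lambda3"]
        )
        df["cv_score"] = self.scores
        df["selected"] = [g == self.best for g in self.grid]
        return df


def grid_search(
    samples,
    G_values,
    lambda1_grid,
    lambda2_grid,
    lambda3_grid,
    K: int = 4,
    seed: int = 0,
    **fit_options,
) -> CVResult:
    """Exhaustive CV over the Cartesian product of the four grids.

    The selected tuple maximizes the mean held-out penalized log-likelihood;
    exact ties go to the larger (lambda1, lambda2, lambda3) lexicographically.
    """
    grid = [
        (int(G), float(l1), float(l2), float(l3))
        for G, l1, l2, l3 in itertools.product(
            G_values, lambda1_grid, lambda2_grid, lambda3_grid
        )
    ]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    scores = [
        cv_score(samples, G, (l1, l2, l3), K=K, seed=seed, **fit_options)
        for (G, l1, l2, l3) in grid
    ]
    best = max(
        zip(grid, scores),
        key=lambda t: (t[1], t[0][1], t[0][2], t[0][3]),
    )[0]
    return CVResult(grid=grid, scores=scores, best=best, K=K, seed=seed)


def count_parameters(
    model_kind: str,
    G: int,
    p: int,
    q: int,
    r: int = 0,
    r_star: int = 0,
) -> int:
    """Free-parameter count of the competing model families.

    ``vectorized-GMM``:   G*pq(pq+1)/2 + G*pq + G - 1
    ``mean-penalized``:   G*p(p+1)/2 + G*q(q+1)/2 + G*pq + G - 1 - r
    ``full-penalized``:   G*p(p+1)/2 + G*q(q+1)/2 + G*pq + G - 1 - r_star

    where r counts mean entries shrunk exactly to zero
    (0 <= r <= G*pq) and r_star additionally counts zeroed precision entries
    (r <= r_star <= G*p(p+1)/2 + G*q(q+1)/2 + G*pq).
    """
    pq = p * q
    cov_factors = G * p * (p + 1) // 2 + G * q * (q + 1) // 2
    if model_kind == "vectorized-GMM":
        return G * pq * (pq + 1) // 2 + G * pq + G - 1
    if model_kind == "mean-penalized":
        if not 0 <= r <= G * pq:
            raise ValueError(f"r must be in [0, {G * pq}], got {r}")
        return cov_factors + G * pq + G - 1 - r
    if model_kind == "full-penalized":
        if not 0 <= r <= G * pq:
            raise ValueError(f"r must be in [0, {G * pq}], got {r}")
        if not r <= r_star <= cov_factors + G * pq:
            raise ValueError(
                f"r_star must be in [{r}, {cov_factors + G * pq}], got {r_star}"
            )
        return cov_factors + G * pq + G - 1 - r_star
    raise ValueError(
        "model_kind must be one of 'vectorized-GMM', 'mean-penalized', "
        f"'full-penalized', got {model_kind!r}"
    )
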