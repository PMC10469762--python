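"""Edge significance: permutation nulls and Brown's p-value merging.

Correlation-based estimators get empirical two-sided p-values from a
permutation null in which every feature's counts are shuffled
independently across samples (all cross-feature association destroyed,
marginals preserved).  The per-method p-value matrices are then merged
into a single matrix per edge with Brown's method — Fisher's combined
statistic psi = -2 sum_i log p_i referred to a scaled chi-squared whose
scale c and degrees of freedom 2f are moment-matched to the empirical
covariance of the -2 log p vectors across edges, which accounts for the
fact that the methods were run on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .counts import CountTable
from .inference import CORRELATION_METHODS, InferenceConfig, correlation_matrix

__all__ = ["PermutationResult", "BrownResult", "permutation_pvalues", "brown_merge"]

#: p-values are clipped into [P_FLOOR, 1] before taking logs.
P_FLOOR = 1e-300


@dataclass
class PermutationResult:
    """Empirical permutation p-values for one correlation method."""

    pvalues: np.ndarray
    n_permutations: int
    method: str
    seed: Optional[int]

    @property
    def min_attainable(self) -> float:
        return 1.0 / (self.n_permutations + 1)


@dataclass
class BrownResult:
    """Brown-merged p-values with the fitted scale and dof.

    ``merged_p`` is the q x q matrix of combined p-values; ``psi`` holds
    the per-edge Fisher statistics; ``c`` and ``f`` are the fitted scale
    and dof parameter (the chi-squared reference has 2f degrees of
    freedom); ``k`` is the number of merged methods.
    """

    merged_p: np.ndarray
    psi: np.ndarray
    c: float
    f: float
    k: int


def permutation_pvalues(
    table: CountTable,
    config: InferenceConfig,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Two-sided empirical p-values against an independent-shuffle null.

    Each permutation replicate shuffles every feature's counts
    independently across samples and recomputes the full correlation
    matrix with the method's own transform.  The p-value uses the add-one
    rule p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1), so the
    smallest attainable value is 1/(n_permutations + 1).

    Only correlation-based methods are supported: direct-association
    estimators regularize internally and carry no permutation null.
    """
    if config.method not in CORRELATION_METHODS:
        raise ValueError(
            "permutation null applies to correlation methods only, got "
            f"{config.method!r}"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = table.counts
    obs = np.abs(correlation_matrix(x, config))
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    perm = np.empty_like(x)
    for _ in range(n_permutations):
        for row in range(x.shape[0]):
            perm[row] = x[row, rng.permutation(x.shape[1])]
        r = np.abs(correlation_matrix(perm, config))
        exceed += r >= obs
    p = (1.0 + exceed) / (n_permutations + 1.0)
    np.fill_diagonal(p, 1.0)
    p = np.minimum(p, 1.0)
    return PermutationResult(p, n_permutations, config.method, seed)


def _offdiag_upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def brown_merge(pvalue_matrices: Sequence[np.ndarray]) -> BrownResult:
    """Merge k per-method p-value matrices into one with Brown's method.

    Per edge j, psi_j = -2 sum_i log p_j^i.  Under independence psi is
    chi-squared with 2k dof (Fisher); correlation between methods inflates
    its variance, which Brown absorbs into a scaled chi-squared c *
    chi2_{2f}.  Moment matching with mu = E[psi] = 2k and sigma^2 =
    Var[psi] = 4k + 2 sum_{i<i'} cov(-2 log p^i, -2 log p^i') gives c =
    sigma^2 / (2 mu) and f = mu^2 / sigma^2; the covariances are estimated
    empirically across the off-diagonal edges.  k = 1 returns the input
    unchanged.
    """
    mats = [np.asarray(m, dtype=float) for m in pvalue_matrices]
    if not mats:
        raise ValueError("brown_merge needs at least one p-value matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all p-value matrices must share one shape")
    for m in mats:
        if (m <= 0).any():
            raise ValueError(
                "p-values must be strictly positive; clip zeros at machine "
                "epsilon upstream before merging"
            )
        if (m > 1).any():
            raise ValueError("p-values must be <= 1")
    k = len(mats)
    logs = [-2.0 * np.log(np.clip(m, P_FLOOR, 1.0)) for m in mats]
    psi = np.sum(logs, axis=0)
    if k == 1:
        merged = mats[0].copy()
        return BrownResult(merged, psi, c=1.0, f=1.0, k=1)

    y = np.vstack([_offdiag_upper(l) for l in logs])  # k x n_edges
    mu = 2.0 * k
    sigma2 = 4.0 * k
    if y.shape[1] >= 2:
        cov = np.cov(y)
        iu = np.triu_indices(k, k=1)
        sigma2 += 2.0 * cov[iu].sum()
    sigma2 = max(sigma2, 1e-12)
    c = sigma2 / (2.0 * mu)
    f = mu * mu / sigma2
    merged = stats.chi2.sf(psi / c, 2.0 * f)
    merged = np.clip(merged, 0.0, 1.0)
    np.fill_diagonal(merged, 1.0)
    return BrownResult(merged, psi, c=float(c), f=float(f), k=k)
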