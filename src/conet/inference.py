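"""Network inference: compositional correlation and direct association.

Implements a representative in-process set of estimators producing
:class:`~conet.network.AssociationNetwork` objects from a count table:

``pearson`` / ``spearman``
    Classical correlations, by default on relative abundances.  Known to
    produce spurious edges on compositional data; kept for comparison and
    excluded from the default consensus set.
``sparcc``
    Basis correlations under the sparsity assumption: pairwise log-ratio
    variances t_ij = Var(log x_i/x_j) on pseudo-count fractions, basis
    variances by a linear solve, with iterative exclusion of the most
    strongly correlated pairs.
``rho``
    Proportionality rho = 1 - Var(clr_i - clr_j) / (Var(clr_i) +
    Var(clr_j)) on clr-transformed data.
``clr_sparse``
    Direct association: sparse inverse covariance (graphical lasso) on clr
    data; weights are signed partial correlations at selected edges.
    Conditional-independence selection avoids reporting indirect
    correlations, and regularization replaces a permutation null, so these
    networks carry no p-values.

New estimators can be registered by name via :data:`METHOD_REGISTRY`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .counts import CountTable
from .network import AssociationNetwork

__all__ = [
    "InferenceConfig",
    "correlate",
    "direct_association",
    "infer_network",
    "CORRELATION_METHODS",
    "METHOD_REGISTRY",
]

CORRELATION_METHODS = ("pearson", "spearman", "sparcc", "rho")

#: Default method set combined by the consensus stage.  Pearson and
#: Spearman are deliberately excluded (spurious edges on compositions).
DEFAULT_CONSENSUS_METHODS = ("sparcc", "rho", "clr_sparse")


@dataclass(frozen=True)
class InferenceConfig:
    """Parameters of one network-inference run.

    Attributes
    ----------
    method
        One of ``pearson``, ``spearman``, ``sparcc``, ``rho``,
        ``clr_sparse``.
    sparcc_exclusion_threshold
        |r| above which the most correlated pair is iteratively excluded
        from the basis-variance estimation (published default 0.1).
    sparcc_iterations
        Maximum exclusion iterations (published default 20).
    sparcc_resamples
        When > 0, average correlations over this many Dirichlet resamples
        of the fractions instead of the single deterministic
        (count+1)/(total+q) estimate.
    sparse_penalty
        Graphical-lasso regularization strength for ``clr_sparse``.
    input_transform
        Transform handed to Pearson/Spearman: ``relative`` (default),
        ``clr`` or ``none``.  sparcc/rho/clr_sparse define their own.
    pseudocount
        Added before log transforms where zeros are possible.
    seed
        Seed for the optional Dirichlet resampling.
    """

    method: str = "sparcc"
    sparcc_exclusion_threshold: float = 0.1
    sparcc_iterations: int = 20
    sparcc_resamples: int = 0
    sparse_penalty: float = 0.1
    input_transform: str = "relative"
    pseudocount: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.sparse_penalty <= 0:
            raise ValueError("sparse_penalty must be > 0")
        if self.sparcc_iterations < 1:
            raise ValueError("sparcc_iterations must be >= 1")
        if not 0 < self.sparcc_exclusion_threshold < 1:
            raise ValueError("sparcc_exclusion_threshold must be in (0, 1)")
        if self.input_transform not in ("relative", "clr", "none"):
            raise ValueError(f"unknown input_transform {self.input_transform!r}")


# -- low-level estimators on a features x samples matrix ----------------------

def _zero_constant_rows(corr: np.ndarray, variances: np.ndarray, method: str) -> np.ndarray:
    const = variances <= 0
    if const.any():
        warnings.warn(
            f"{method}: {const.sum()} constant feature(s); their correlations set to 0",
            stacklevel=3,
        )
        corr[const, :] = 0.0
        corr[:, const] = 0.0
    return corr


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    v = x.var(axis=1)
    ok = v > 0
    corr = np.zeros((x.shape[0], x.shape[0]))
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = np.corrcoef(x[ok])
        sub = np.nan_to_num(sub, nan=0.0)
        corr[np.ix_(ok, ok)] = sub
    if (~ok).any():
        corr = _zero_constant_rows(corr, v, "pearson")
    np.fill_diagonal(corr, 0.0)
    return np.clip(corr, -1.0, 1.0)


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    return _pearson_matrix(ranks)


def _clr_rows(x: np.ndarray, pseudocount: float) -> np.ndarray:
    """clr per sample (column) of pseudo-count fractions."""
    shifted = x + pseudocount
    frac = shifted / shifted.sum(axis=0)
    logs = np.log(frac)
    return logs - logs.mean(axis=0)


def _rho_matrix(x: np.ndarray, pseudocount: float) -> np.ndarray:
    z = _clr_rows(x, pseudocount)
    cov = np.cov(z)
    v = np.diag(cov).copy()
    denom = v[:, None] + v[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 2.0 * cov / denom
    rho = np.nan_to_num(rho, nan=0.0)
    rho = _zero_constant_rows(rho, v, "rho")
    np.fill_diagonal(rho, 0.0)
    return np.clip(rho, -1.0, 1.0)


def _sparcc_fractions(x: np.ndarray, rng: Optional[np.random.Generator]) -> np.ndarray:
    if rng is None:
        # deterministic posterior-mean estimate of the composition
        return (x + 1.0) / (x.sum(axis=0) + x.shape[0])
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        out[:, j] = rng.dirichlet(x[:, j] + 1.0)
    return out


def _sparcc_basis(x: np.ndarray, exclusion_threshold: float, n_iter: int,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One SparCC basis-correlation estimate.

    The variation matrix T (t_ij = Var(log f_i/f_j)) is computed from the
    covariance of the log fractions; basis variances solve
    M w = t with M = (q-2) I + 1 1^T under the sparsity assumption, and
    the most correlated pair above the exclusion threshold is iteratively
    removed from M (one pair per iteration, published procedure).
    """
    q = x.shape[0]
    if q < 2:
        raise ValueError("sparcc needs at least 2 features")
    logf = np.log(_sparcc_fractions(x, rng))
    cov = np.cov(logf)
    v = np.diag(cov)
    t_mat = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t_mat, 0.0)

    m_mat = np.ones((q, q)) + np.diag(np.full(q, float(q - 2)))
    t_row = t_mat.sum(axis=1)
    excluded: set[tuple[int, int]] = set()

    def solve_corr() -> np.ndarray:
        w = np.linalg.solve(m_mat, t_row)
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        r = (w[:, None] + w[None, :] - t_mat) / denom
        np.fill_diagonal(r, 0.0)
        return np.clip(r, -1.0, 1.0)

    corr = solve_corr()
    for _ in range(n_iter):
        masked = np.abs(corr).copy()
        for (i, j) in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # keep the linear system well posed: never drop a feature's last pairs
        if m_mat[i, i] <= 2 or m_mat[j, j] <= 2:
            break
        excluded.add((min(i, j), max(i, j)))
        m_mat[i, i] -= 1
        m_mat[j, j] -= 1
        m_mat[i, j] = m_mat[j, i] = 0.0
        t_row[i] -= t_mat[i, j]
        t_row[j] -= t_mat[i, j]
        corr = solve_corr()
    return corr


def _sparcc_matrix(x: np.ndarray, config: "InferenceConfig") -> np.ndarray:
    if config.sparcc_resamples > 0:
        rng = np.random.default_rng(config.seed)
        acc = np.zeros((x.shape[0], x.shape[0]))
        for _ in range(config.sparcc_resamples):
            acc += _sparcc_basis(
                x, config.sparcc_exclusion_threshold, config.sparcc_iterations, rng
            )
        corr = acc / config.sparcc_resamples
        np.fill_diagonal(corr, 0.0)
        return np.clip(corr, -1.0, 1.0)
    return _sparcc_basis(
        x, config.sparcc_exclusion_threshold, config.sparcc_iterations, None
    )


def correlation_matrix(x: np.ndarray, config: InferenceConfig) -> np.ndarray:
    """Correlation-type weight matrix for a features x samples count matrix.

    This is the kernel shared by :func:`correlate` and the permutation
    null: it applies the method's own transform to the (possibly permuted)
    raw counts.
    """
    method = config.method
    if method in ("pearson", "spearman"):
        if config.input_transform == "relative":
            totals = x.sum(axis=0)
            totals = np.where(totals > 0, totals, 1.0)
            y = x / totals
        elif config.input_transform == "clr":
            y = _clr_rows(x, config.pseudocount)
        else:
            y = x
        return _pearson_matrix(y) if method == "pearson" else _spearman_matrix(y)
    if method == "sparcc":
        return _sparcc_matrix(x, config)
    if method == "rho":
        return _rho_matrix(x, config.pseudocount)
    raise ValueError(f"{method!r} is not a correlation method")


# -- public operations --------------------------------------------------------

def _check_table(table: CountTable, min_samples: int = 4) -> None:
    if table.n_samples < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples, got {table.n_samples}"
        )
    if table.n_features < 2:
        raise ValueError("need at least 2 features")


def _node_info(table: CountTable) -> tuple[list[str], dict[str, str]]:
    if table.lineages is not None:
        nodes = [str(l) for l in table.lineages]
        if len(set(nodes)) != len(nodes):  # fall back to feature ids
            nodes = table.feature_ids
    else:
        nodes = table.feature_ids
    return nodes, {n: n for n in nodes}


def correlate(table: CountTable, config: InferenceConfig) -> AssociationNetwork:
    """Pairwise correlation network (pearson, spearman, sparcc or rho)."""
    if config.method not in CORRELATION_METHODS:
        raise ValueError(
            f"correlate supports {CORRELATION_METHODS}, got {config.method!r}"
        )
    _check_table(table)
    corr = correlation_matrix(table.counts, config)
    nodes, lineages = _node_info(table)
    return AssociationNetwork(config.method, nodes, corr, lineages=lineages)


def direct_association(table: CountTable, config: InferenceConfig) -> AssociationNetwork:
    """Sparse conditional-independence network on clr-transformed data.

    The graphical lasso is fit to the empirical correlation matrix of the
    clr data at ``config.sparse_penalty``; selected edges get weight
    -kappa_ij / sqrt(kappa_ii kappa_jj) (signed partial correlation), all
    others 0.  No p-values are attached: the penalty is the selection.
    """
    if config.method != "clr_sparse":
        raise ValueError(f"direct_association supports 'clr_sparse', got {config.method!r}")
    _check_table(table)
    from sklearn.covariance import graphical_lasso

    z = _clr_rows(table.counts, config.pseudocount)
    cov = np.cov(z)
    v = np.diag(cov).copy()
    d = np.sqrt(np.clip(v, 1e-12, None))
    corr = cov / np.outer(d, d)
    corr = _zero_constant_rows(corr, v, "clr_sparse")
    np.fill_diagonal(corr, 1.0)
    # the clr covariance is exactly singular (features sum to 0); identity
    # shrinkage restores definiteness, escalated only if the solver stalls
    precision = None
    last_exc: Exception | None = None
    ladder = (
        (0.01, "cd"), (0.01, "lars"), (0.05, "cd"), (0.05, "lars"),
        (0.1, "cd"), (0.1, "lars"), (0.2, "cd"),
    )
    for eps, mode in ladder:
        shrunk = (1.0 - eps) * corr + eps * np.eye(corr.shape[0])
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("error", category=UserWarning)
                warnings.simplefilter("ignore", category=RuntimeWarning)
                _, precision = graphical_lasso(
                    shrunk, alpha=config.sparse_penalty, max_iter=300, mode=mode
                )
            break
        except (
            FloatingPointError,
            OverflowError,
            ValueError,
            np.linalg.LinAlgError,
            UserWarning,
        ) as exc:
            last_exc = exc
            precision = None
    if precision is None:
        raise RuntimeError(
            f"graphical lasso did not converge at penalty "
            f"{config.sparse_penalty}; try a larger penalty"
        ) from last_exc
    dk = np.sqrt(np.clip(np.diag(precision), 1e-12, None))
    partial = -precision / np.outer(dk, dk)
    np.fill_diagonal(partial, 0.0)
    partial[np.abs(partial) < 1e-10] = 0.0
    partial = np.clip((partial + partial.T) / 2.0, -1.0, 1.0)
    nodes, lineages = _node_info(table)
    return AssociationNetwork("clr_sparse", nodes, partial, lineages=lineages)


#: method name -> callable(table, config) -> AssociationNetwork
METHOD_REGISTRY: dict[str, Callable[[CountTable, InferenceConfig], AssociationNetwork]] = {
    "pearson": correlate,
    "spearman": correlate,
    "sparcc": correlate,
    "rho": correlate,
    "clr_sparse": direct_association,
}


def infer_network(table: CountTable, config: InferenceConfig) -> AssociationNetwork:
    """Dispatch to the registered estimator for ``config.method``."""
    try:
        fn = METHOD_REGISTRY[config.method]
    except KeyError:
        raise ValueError(
            f"unknown method {config.method!r}; known: {sorted(METHOD_REGISTRY)}"
        ) from None
    return fn(table, config)
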