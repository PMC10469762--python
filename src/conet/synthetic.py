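"""Synthetic benchmark generators with known ground-truth interactions.

Two generators emulate the data regimes commonly used to benchmark
microbial network inference:

* generalized Lotka-Volterra (gLV) dynamics on a Klemm-Eguiluz interaction
  graph — community time courses integrated to their endpoint, converted
  to sequencing-style counts by multinomial read sampling;
* the Normal-to-Anything (NorTA) copula — multivariate normal draws with a
  correlation structure derived from a target graph topology, pushed
  through count-distribution quantile functions (Poisson, negative
  binomial, or zero-inflated negative binomial margins).

Every dataset carries the generating interaction support as ground truth
and is bit-reproducible under its seed.  The species/sample grids used in
benchmark sweeps are exposed as ``N_GRID`` and ``S_GRID``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp

from .counts import CountTable

__all__ = [
    "BenchmarkDataset",
    "klemm_eguiluz_graph",
    "simulate_glv",
    "norta_counts",
    "margin_ks_pvalues",
    "N_GRID",
    "S_GRID",
    "TOPOLOGIES",
    "MARGINS",
]

#: Species- and sample-count grids spanned by benchmark sweeps.
N_GRID = (10, 25, 50, 100, 150, 200)
S_GRID = (50, 100, 200, 500)

TOPOLOGIES = ("band", "cluster", "scale_free", "erdos_renyi", "hub", "block")
MARGINS = ("poisson", "negbinom", "zinb")


@dataclass
class BenchmarkDataset:
    """A synthetic count table plus its generating interaction matrix."""

    table: CountTable
    truth: np.ndarray
    generator: str
    params: dict
    seed: int

    @property
    def truth_support(self) -> np.ndarray:
        """Symmetric 0/1 support (union symmetrization, zero diagonal)."""
        sup = (self.truth != 0) | (self.truth.T != 0)
        sup = sup.astype(int)
        np.fill_diagonal(sup, 0)
        return sup


# -- Klemm-Eguiluz graphs -----------------------------------------------------

def klemm_eguiluz_graph(
    n_nodes: int,
    clique_size: int,
    mu: float,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Clique-seeded growing graph with node activation/deactivation.

    Growth starts from a fully connected clique of ``clique_size`` active
    nodes.  Each subsequent node attaches to every active node, but each
    attachment is rewired, with probability ``mu``, to a random non-active
    node chosen proportionally to degree.  The new node then becomes
    active and deactivates one active node with probability inversely
    proportional to degree.  The result is a highly clustered, scale-free
    undirected simple graph; at ``mu = 0`` the construction yields exactly
    ``clique_size*(clique_size-1)/2 + (n_nodes-clique_size)*clique_size``
    edges and is connected.
    """
    if clique_size < 2:
        raise ValueError("clique_size must be >= 2")
    if clique_size > n_nodes:
        raise ValueError("clique_size cannot exceed n_nodes")
    if not 0 <= mu <= 1:
        raise ValueError("mu must be in [0, 1]")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    m = clique_size
    for i in range(m):
        for j in range(i + 1, m):
            adj[i, j] = adj[j, i] = 1
    active = list(range(m))
    degree = adj.sum(axis=1)

    for v in range(m, n_nodes):
        targets = []
        for a in active:
            t = a
            if rng.random() < mu:
                pool = [
                    u
                    for u in range(v)
                    if u not in active and u != v and not adj[v, u] and u not in targets
                ]
                if pool:
                    wts = degree[pool].astype(float)
                    wts = wts + 1e-12  # isolated candidates stay reachable
                    t = int(rng.choice(pool, p=wts / wts.sum()))
            if t not in targets:
                targets.append(t)
        for t in targets:
            if not adj[v, t]:
                adj[v, t] = adj[t, v] = 1
                degree[v] += 1
                degree[t] += 1
        # deactivate one active node, probability ~ 1/degree
        inv = 1.0 / degree[active]
        drop = active[int(rng.choice(len(active), p=inv / inv.sum()))]
        active.remove(drop)
        active.append(v)
    return adj


# -- gLV simulation -----------------------------------------------------------

def simulate_glv(
    adjacency: np.ndarray,
    n_samples: int,
    interaction_strength_max: float = 0.2,
    self_limitation: float = -0.5,
    growth_rate_range: tuple[float, float] = (0.0, 1.0),
    growth_rate_jitter_sigma: float = 0.3,
    init_poisson_lambda: float = 100.0,
    t_end: float = 100.0,
    read_depth: int = 25000,
    seed: Optional[int] = None,
    max_retries: int = 5,
    interaction_matrix: Optional[np.ndarray] = None,
    growth_rates: Optional[np.ndarray] = None,
) -> BenchmarkDataset:
    """Endpoint abundances of gLV dynamics on an interaction graph.

    ``interaction_matrix`` and ``growth_rates`` override the random draws
    with explicit A and b (useful for controlled experiments); an explicit
    b disables the per-sample redraw.

    dx_i/dt = x_i (b_i + sum_j a_ij x_j) with a_ii = ``self_limitation``
    (< 0), off-diagonal a_ij drawn on the adjacency support with magnitude
    uniform in (0, ``interaction_strength_max``] and a 50/50 positive or
    negative sign, and growth rates b_i uniform in
    ``growth_rate_range``.  Each sample integrates an independent Poisson
    initial condition (shifted by +1 so no species starts extinct) to
    ``t_end``; the endpoint composition is turned into counts by
    multinomial sampling at ``read_depth`` reads.  Samples whose
    trajectories blow up are re-drawn up to ``max_retries`` times.

    Per sample, each growth rate receives a multiplicative log-normal
    jitter of scale ``growth_rate_jitter_sigma`` (mean-preserving),
    modeling environmental variation across samples: each sample relaxes
    to its own equilibrium x* = -A^-1 b_s, so the cross-sample abundance
    covariance is shaped by the interaction matrix.  With zero jitter the
    weakly-interacting community has one globally attracting equilibrium
    and endpoints differ only by read-sampling noise, leaving nothing for
    inference to recover.  Endpoint abundances below 1e-6 are treated as
    extinct.

    The returned truth matrix is the signed off-diagonal interaction
    matrix (possibly asymmetric; evaluation uses its union support).
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(adjacency != adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if self_limitation >= 0:
        raise ValueError("self_limitation must be negative")
    if read_depth <= 0 or t_end <= 0:
        raise ValueError("read_depth and t_end must be positive")
    n = adjacency.shape[0]
    rng = np.random.default_rng(seed)

    if interaction_matrix is not None:
        a = np.asarray(interaction_matrix, dtype=float).copy()
        if a.shape != adjacency.shape:
            raise ValueError("interaction_matrix shape must match adjacency")
    else:
        a = np.zeros((n, n))
        rows, cols = np.nonzero(adjacency)
        off = rows != cols
        rows, cols = rows[off], cols[off]
        mags = rng.uniform(0.0, interaction_strength_max, size=rows.size)
        signs = rng.choice([-1.0, 1.0], size=rows.size)
        a[rows, cols] = mags * signs
        np.fill_diagonal(a, self_limitation)
    if growth_rates is not None:
        b_base = np.asarray(growth_rates, dtype=float)
        growth_rate_jitter_sigma = 0.0
    else:
        b_base = rng.uniform(*growth_rate_range, size=n)

    overflow = 1e7
    sigma = growth_rate_jitter_sigma

    counts = np.zeros((n, n_samples))
    for s in range(n_samples):
        if sigma > 0:
            b = b_base * np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2.0)
        else:
            b = b_base

        def rhs(_t, x, b=b):
            return x * (b + a @ x)

        for attempt in range(max_retries + 1):
            x0 = rng.poisson(init_poisson_lambda, size=n).astype(float) + 1.0
            sol = solve_ivp(
                rhs, (0.0, t_end), x0, method="LSODA", rtol=1e-6, atol=1e-8
            )
            if sol.success and np.all(np.abs(sol.y[:, -1]) < overflow):
                x_end = np.clip(sol.y[:, -1], 0.0, None)
                x_end[x_end < 1e-6] = 0.0  # numerically extinct
                break
        else:
            raise RuntimeError(
                f"gLV trajectory diverged for sample {s} after "
                f"{max_retries} retries"
            )
        total = x_end.sum()
        if total > 0:
            counts[:, s] = rng.multinomial(read_depth, x_end / total)

    table = CountTable(
        counts,
        [f"sp{i}" for i in range(n)],
        [f"S{j}" for j in range(n_samples)],
    )
    truth = a.copy()
    np.fill_diagonal(truth, 0.0)
    params = {
        "interaction_strength_max": interaction_strength_max,
        "self_limitation": self_limitation,
        "growth_rate_range": tuple(growth_rate_range),
        "growth_rate_jitter_sigma": growth_rate_jitter_sigma,
        "init_poisson_lambda": init_poisson_lambda,
        "t_end": t_end,
        "read_depth": read_depth,
        "n_samples": n_samples,
    }
    return BenchmarkDataset(table, truth, "glv", params, -1 if seed is None else seed)


# -- NorTA copula counts ------------------------------------------------------

def _topology_adjacency(topology: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """0/1 symmetric adjacency for one of the benchmark topologies.

    Average degree is kept around 2 (roughly n edges), matching sparse
    microbial interaction graphs.
    """
    import networkx as nx

    if topology == "band":
        g = nx.path_graph(n)
        adj = nx.to_numpy_array(g, dtype=int)
    elif topology == "scale_free":
        g = nx.barabasi_albert_graph(n, 1, seed=int(rng.integers(2**31)))
        adj = nx.to_numpy_array(g, dtype=int)
    elif topology == "erdos_renyi":
        g = nx.gnm_random_graph(n, n, seed=int(rng.integers(2**31)))
        adj = nx.to_numpy_array(g, dtype=int)
    elif topology == "hub":
        n_hubs = max(1, n // 20)
        adj = np.zeros((n, n), dtype=int)
        members = np.array_split(np.arange(n), n_hubs)
        for grp in members:
            hub = grp[0]
            for u in grp[1:]:
                adj[hub, u] = adj[u, hub] = 1
    elif topology == "cluster":
        n_groups = max(1, n // 10)
        adj = np.zeros((n, n), dtype=int)
        for grp in np.array_split(np.arange(n), n_groups):
            size = len(grp)
            if size < 2:
                continue
            target = 2 * size  # ~2 within-group edges per node
            pairs = [(grp[i], grp[j]) for i in range(size) for j in range(i + 1, size)]
            take = min(target, len(pairs))
            chosen = rng.choice(len(pairs), size=take, replace=False)
            for idx in chosen:
                u, v = pairs[idx]
                adj[u, v] = adj[v, u] = 1
    elif topology == "block":
        n_blocks = max(2, n // 25)
        labels = rng.integers(0, n_blocks, size=n)
        p_in, p_out = 0.3, 0.01
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                p = p_in if labels[i] == labels[j] else p_out
                if rng.random() < p:
                    adj[i, j] = adj[j, i] = 1
    else:
        raise ValueError(f"unknown topology {topology!r}; expected one of {TOPOLOGIES}")
    return adj


def _graph_to_correlation(
    adj: np.ndarray,
    rng: np.random.Generator,
    condition_target: float,
    partial_strength: float = 0.3,
) -> np.ndarray:
    """Target correlation matrix whose precision support is ``adj``.

    Edges get precision entries of magnitude ``partial_strength`` with
    random sign; the diagonal is loaded just enough to make the matrix
    positive definite with condition number <= ``condition_target``.
    """
    n = adj.shape[0]
    omega = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = adj[iu] != 0
    vals = partial_strength * rng.choice([-1.0, 1.0], size=int(mask.sum()))
    omega[iu[0][mask], iu[1][mask]] = vals
    omega = omega + omega.T
    eig = np.linalg.eigvalsh(omega)
    lo, hi = eig[0], eig[-1]
    d = max((hi - condition_target * lo) / (condition_target - 1.0), -lo + 1e-3)
    omega += d * np.eye(n)
    if np.linalg.eigvalsh(omega)[0] <= 0:
        raise RuntimeError("precision matrix not positive definite after loading")
    sigma = np.linalg.inv(omega)
    dsd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(dsd, dsd)
    np.fill_diagonal(corr, 1.0)
    return corr


def _margin_dist(margin: str, margin_params: Optional[dict]):
    """Frozen scipy distribution (or ppf callable) for a count margin."""
    p = dict(margin_params or {})
    if margin == "poisson":
        mu = p.pop("mu", 50.0)
        dist = stats.poisson(mu)
        return dist.ppf, dist.cdf, {"mu": mu}
    if margin == "negbinom":
        mean = p.pop("mean", 50.0)
        dispersion = p.pop("dispersion", 0.5)  # var = mean + dispersion * mean^2
        size = 1.0 / dispersion
        prob = size / (size + mean)
        dist = stats.nbinom(size, prob)
        return dist.ppf, dist.cdf, {"mean": mean, "dispersion": dispersion}
    if margin == "zinb":
        mean = p.pop("mean", 50.0)
        dispersion = p.pop("dispersion", 0.5)
        pi0 = p.pop("zero_inflation", 0.3)
        size = 1.0 / dispersion
        prob = size / (size + mean)
        nb = stats.nbinom(size, prob)

        def ppf(u):
            u = np.asarray(u, dtype=float)
            inner = np.clip((u - pi0) / (1.0 - pi0), 0.0, 1.0)
            vals = nb.ppf(inner)
            return np.where(u <= pi0, 0.0, vals)

        def cdf(x):
            return pi0 + (1.0 - pi0) * nb.cdf(x)

        return ppf, cdf, {"mean": mean, "dispersion": dispersion, "zero_inflation": pi0}
    raise ValueError(f"unknown margin {margin!r}; expected one of {MARGINS}")


def margin_ks_pvalues(dataset: BenchmarkDataset) -> np.ndarray:
    """Per-feature KS p-values of NorTA counts against the target margin.

    The statistic compares the empirical CDF with the target CDF at the
    observed atoms (both right-continuous); the asymptotic Kolmogorov
    p-value is conservative for discrete margins.  Useful as a
    margin-consistency check: NorTA preserves margins regardless of the
    correlation structure.
    """
    if dataset.generator != "norta":
        raise ValueError("margin check applies to NorTA datasets")
    from scipy.special import kolmogorov

    params = dict(dataset.params.get("margin_params", {}))
    _ppf, cdf, _ = _margin_dist(dataset.params["margin"], params)
    out = []
    for row in dataset.table.counts:
        n = row.size
        vals, counts = np.unique(row, return_counts=True)
        ecdf = np.cumsum(counts) / n
        d = np.abs(ecdf - cdf(vals)).max()
        out.append(float(kolmogorov(np.sqrt(n) * d)))
    return np.asarray(out)


def norta_counts(
    topology: str,
    n_nodes: int,
    n_samples: int,
    margin: str = "negbinom",
    margin_params: Optional[dict] = None,
    condition_target: float = 5.0,
    seed: Optional[int] = None,
) -> BenchmarkDataset:
    """NorTA copula counts with a graph-structured correlation target.

    Builds the requested topology, derives a correlation matrix from a
    diagonally loaded precision matrix on its support, draws z ~ MVN(0,
    Sigma), maps u = Phi(z) and returns counts F^-1(u) under the chosen
    margin.  Margins are preserved exactly regardless of Sigma; the truth
    network is the topology's support.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    adj = _topology_adjacency(topology, n_nodes, rng)
    corr = _graph_to_correlation(adj, rng, condition_target)
    chol = np.linalg.cholesky(corr)
    z = chol @ rng.standard_normal((n_nodes, n_samples))
    u = stats.norm.cdf(z)
    # keep quantiles strictly inside (0, 1)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    ppf, _cdf, used_params = _margin_dist(margin, margin_params)
    counts = np.asarray(ppf(u), dtype=float)
    table = CountTable(
        counts,
        [f"sp{i}" for i in range(n_nodes)],
        [f"S{j}" for j in range(n_samples)],
    )
    params = {
        "topology": topology,
        "margin": margin,
        "margin_params": used_params,
        "condition_target": condition_target,
        "n_nodes": n_nodes,
        "n_samples": n_samples,
    }
    return BenchmarkDataset(
        table, adj.astype(float), "norta", params, -1 if seed is None else seed
    )
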