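"""End-to-end benchmark protocol: generate -> infer -> filter -> consensus
-> score.

This module wires the synthetic generators, the inference methods, the
permutation/Brown significance machinery and the consensus algorithms
into the standard evaluation loop used to measure consensus precision and
sensitivity against known interaction networks.  The same functions back
the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consensus import ConsensusNetwork, scaled_sum, simple_voting
from .counts import filter_counts
from .evaluation import EvaluationResult, precision_sensitivity, truth_edge_set
from .inference import (
    CORRELATION_METHODS,
    DEFAULT_CONSENSUS_METHODS,
    InferenceConfig,
    infer_network,
)
from .network import AssociationNetwork, NetworkStack, align_networks, threshold_network
from .significance import brown_merge, permutation_pvalues
from .synthetic import BenchmarkDataset, klemm_eguiluz_graph, norta_counts, simulate_glv

__all__ = [
    "inferred_stack",
    "consensus_for_dataset",
    "evaluate_consensus",
    "benchmark_suite",
    "default_norta_datasets",
    "default_glv_datasets",
]


def inferred_stack(
    dataset: BenchmarkDataset,
    methods: Sequence[str] = DEFAULT_CONSENSUS_METHODS,
    weight_min: float = 0.1,
    p_max: float = 0.05,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    sparse_penalty: float = 0.1,
    prefilter: bool = True,
) -> NetworkStack:
    """Infer, attach Brown-merged p-values, threshold, and align.

    The count table is first passed through the relaxed count filter
    (prevalence 2/S, mean relative abundance 0.001, observation sum 10),
    as the workflow always does before inference: near-extinct taxa
    otherwise produce degenerate, perfectly collinear log-ratio rows.
    Correlation-based methods then get permutation p-values which are
    merged across those methods with Brown's method; the merged matrix is
    written back into every correlation network before the weight/p-value
    threshold is applied.  Direct-association networks are filtered on
    weight alone.
    """
    table = dataset.table
    if prefilter:
        table = filter_counts(
            table,
            prevalence_min=min(1.0, 2.0 / table.n_samples),
            abundance_min=0.001,
            obs_sum_min=10,
            sample_sum_min=0,
        )
    seeds = np.random.SeedSequence(0 if seed is None else seed).spawn(len(methods))
    nets: list[AssociationNetwork] = []
    perm_p: list[np.ndarray] = []
    corr_idx: list[int] = []
    for i, method in enumerate(methods):
        config = InferenceConfig(method=method, sparse_penalty=sparse_penalty)
        net = infer_network(table, config)
        if method in CORRELATION_METHODS:
            stage_seed = int(seeds[i].generate_state(1)[0] % (2**31))
            res = permutation_pvalues(table, config, n_permutations, stage_seed)
            perm_p.append(res.pvalues)
            corr_idx.append(len(nets))
        nets.append(net)
    if perm_p:
        merged = brown_merge(perm_p).merged_p
        for i in corr_idx:
            nets[i].pvalues = merged.copy()
    filtered = [threshold_network(n, weight_min, p_max) for n in nets]
    return align_networks(filtered)


def consensus_for_dataset(
    stack: NetworkStack, theta: float, algorithm: str = "ss"
) -> ConsensusNetwork:
    if algorithm.lower() == "ss":
        return scaled_sum(stack, theta)
    if algorithm.lower() == "sv":
        return simple_voting(stack, theta)
    raise ValueError(f"unknown consensus algorithm {algorithm!r}")


def evaluate_consensus(
    dataset: BenchmarkDataset,
    consensus: ConsensusNetwork,
    sign_aware: bool = False,
) -> EvaluationResult:
    truth = truth_edge_set(dataset.truth, dataset.table.feature_ids)
    return precision_sensitivity(consensus, truth, sign_aware=sign_aware)


def default_norta_datasets(
    n_replicates: int,
    seed: int,
    topologies: Sequence[str] = ("band", "cluster", "scale_free"),
    n_nodes: int = 50,
    n_samples: int = 500,
    margin: str = "negbinom",
) -> list[BenchmarkDataset]:
    """Seeded NorTA benchmark collection cycling through topologies."""
    out = []
    for r in range(n_replicates):
        topo = topologies[r % len(topologies)]
        out.append(
            norta_counts(
                topo,
                n_nodes,
                n_samples,
                margin=margin,
                seed=int(seed + 1000 * r),
            )
        )
    return out


def default_glv_datasets(
    n_replicates: int,
    seed: int,
    n_nodes: int = 50,
    n_samples: int = 100,
    clique_size: int = 3,
    mu: float = 0.3,
) -> list[BenchmarkDataset]:
    """Seeded gLV benchmark collection on Klemm-Eguiluz graphs."""
    out = []
    for r in range(n_replicates):
        s = int(seed + 1000 * r)
        adj = klemm_eguiluz_graph(n_nodes, clique_size, mu, seed=s)
        out.append(simulate_glv(adj, n_samples, seed=s + 1))
    return out


def benchmark_suite(
    datasets: Sequence[BenchmarkDataset],
    thetas: Sequence[float] = (0.333, 1.0),
    methods: Sequence[str] = DEFAULT_CONSENSUS_METHODS,
    algorithm: str = "ss",
    weight_min: float = 0.1,
    p_max: float = 0.05,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> dict[float, list[EvaluationResult]]:
    """Consensus evaluation over datasets at each theta.

    Returns theta -> one :class:`EvaluationResult` per dataset.  The
    inference stage runs once per dataset; the theta sweep reuses the
    aligned stack.
    """
    results: dict[float, list[EvaluationResult]] = {float(t): [] for t in thetas}
    base = np.random.SeedSequence(0 if seed is None else seed)
    for i, ds in enumerate(datasets):
        ds_seed = int(base.spawn(1)[0].generate_state(1)[0] % (2**31)) + i
        stack = inferred_stack(
            ds,
            methods=methods,
            weight_min=weight_min,
            p_max=p_max,
            n_permutations=n_permutations,
            seed=ds_seed,
        )
        for t in thetas:
            cons = consensus_for_dataset(stack, float(t), algorithm)
            results[float(t)].append(evaluate_consensus(ds, cons))
    return results


def reproduction_summary(
    seed: int,
    n_norta: int = 12,
    n_glv: int = 10,
    thetas: Sequence[float] = (0.0, 0.333, 0.5, 0.667, 1.0),
    n_permutations: int = 1000,
) -> dict:
    """Scaled-sum consensus precision/sensitivity on fresh benchmarks.

    Generates seeded NorTA datasets (band/cluster/scale-free topologies,
    N = 50, S = 500, negative-binomial margins) and gLV datasets on
    Klemm-Eguiluz graphs (N = 50, S = 100), runs the default method set
    {sparcc, rho, clr_sparse} with weight threshold 0.1 and merged
    p-value cutoff 0.05, and evaluates the scaled-sum consensus along the
    theta grid.  Returns per-generator mean precision and sensitivity per
    theta.
    """
    norta = default_norta_datasets(n_norta, seed=seed)
    glv = default_glv_datasets(n_glv, seed=seed + 500)
    out: dict = {"theta_grid": [float(t) for t in thetas]}
    for name, datasets, sub_seed in (("norta", norta, seed + 1), ("glv", glv, seed + 2)):
        res = benchmark_suite(
            datasets, thetas=thetas, n_permutations=n_permutations, seed=sub_seed
        )
        out[name] = {
            "precision": {t: mean_precision(r) for t, r in res.items()},
            "sensitivity": {t: mean_sensitivity(r) for t, r in res.items()},
            "n_datasets": len(datasets),
        }
    return out


def mean_precision(results: Sequence[EvaluationResult]) -> float:
    """Mean precision over datasets, skipping empty predictions."""
    vals = [r.precision for r in results if not np.isnan(r.precision)]
    return float(np.mean(vals)) if vals else float("nan")


def mean_sensitivity(results: Sequence[EvaluationResult]) -> float:
    vals = [r.sensitivity for r in results if not np.isnan(r.sensitivity)]
    return float(np.mean(vals)) if vals else float("nan")
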