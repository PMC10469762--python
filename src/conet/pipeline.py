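"""End-to-end pipeline: filter -> infer -> p-values -> threshold ->
consensus -> evaluate, from one config.

The configuration (a TOML file or a :class:`RunConfig`) fully determines
a run; a single seed fans out to per-stage seeds through a documented
counter scheme (stage k uses ``SeedSequence(seed, spawn_key=(k,))``), so
any stage can be reproduced in isolation and two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .benchmarks import consensus_for_dataset
from .counts import CountTable, filter_counts, group_taxa, read_biom, read_tsv, write_tsv
from .evaluation import precision_sensitivity
from .inference import CORRELATION_METHODS, InferenceConfig, METHOD_REGISTRY, infer_network
from .network import align_networks, threshold_network
from .significance import brown_merge, permutation_pvalues

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("conet")

_STAGES = ("filter", "infer", "pvalues", "consensus")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    k = _STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Defaults follow the recommended workflow settings: stringent count
    filtering (prevalence 0.05, mean relative abundance 0.01, observation
    sum 100, sample sum 500), 1000 permutations, weight threshold 0.1,
    p-value cutoff 0.05, and scaled-sum consensus at theta = 0.333
    (simple voting's recommended theta is 1.0).
    """

    input_path: str = ""
    taxonomy_path: Optional[str] = None
    truth_path: Optional[str] = None
    output_dir: str = "conet_out"
    input_format: str = "tsv"  # tsv | biom
    group_level: Optional[str] = None
    filter_enabled: bool = True
    prevalence_min: float = 0.05
    abundance_min: float = 0.01
    obs_sum_min: float = 100.0
    sample_sum_min: float = 500.0
    methods: tuple[str, ...] = ("sparcc", "rho", "clr_sparse")
    sparse_penalty: float = 0.1
    n_permutations: int = 1000
    weight_min: float = 0.1
    p_max: float = 0.05
    consensus_algorithm: str = "ss"
    theta: float = 0.333
    sv_theta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for m in self.methods:
            if m not in METHOD_REGISTRY:
                raise ValueError(
                    f"unknown method {m!r}; known: {sorted(METHOD_REGISTRY)}"
                )
        if self.consensus_algorithm.lower() not in ("ss", "sv"):
            raise ValueError("consensus_algorithm must be 'ss' or 'sv'")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_truth_edges(path) -> dict[frozenset, int]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: dict[frozenset, int] = {}
    for _, row in df.iterrows():
        w = float(row.iloc[2]) if len(row) > 2 else 1.0
        out[frozenset((str(row.iloc[0]), str(row.iloc[1])))] = int(np.sign(w)) or 1
    return out


def run_pipeline(config: RunConfig, table: Optional[CountTable] = None) -> dict:
    """Execute every stage, writing intermediates to ``config.output_dir``.

    Returns ``{"consensus": ConsensusNetwork, "per_method_networks":
    {...}, "report": {...}}``.  A ``table`` argument bypasses file input
    (used by library callers); stage failures propagate annotated with
    the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": [],
    }
    try:
        # -- load + filter ---------------------------------------------------
        stage = "filter"
        if table is None:
            if config.input_format == "biom":
                table = read_biom(config.input_path)
            else:
                table = read_tsv(config.input_path, config.taxonomy_path)
        logger.info("loaded table: %d features x %d samples", table.n_features, table.n_samples)
        if config.filter_enabled:
            table = filter_counts(
                table,
                config.prevalence_min,
                config.abundance_min,
                config.obs_sum_min,
                config.sample_sum_min,
            )
        if config.group_level:
            table = group_taxa(table, config.group_level)
        write_tsv(table, out / "filtered_counts.tsv")
        report["stages"].append({"stage": stage, "features": table.n_features,
                                 "samples": table.n_samples})

        # -- infer -----------------------------------------------------------
        stage = "infer"
        nets = []
        for method in config.methods:
            cfg = InferenceConfig(
                method=method,
                sparse_penalty=config.sparse_penalty,
                seed=stage_seed(config.seed, "infer"),
            )
            nets.append(infer_network(table, cfg))
            logger.info("inferred %s network", method)

        # -- p-values + merging ----------------------------------------------
        stage = "pvalues"
        perm_p = []
        corr_idx = []
        for i, net in enumerate(nets):
            if net.method in CORRELATION_METHODS:
                cfg = InferenceConfig(method=net.method, sparse_penalty=config.sparse_penalty)
                res = permutation_pvalues(
                    table, cfg, config.n_permutations,
                    stage_seed(config.seed, "pvalues") + i,
                )
                perm_p.append(res.pvalues)
                corr_idx.append(i)
        if perm_p:
            merged = brown_merge(perm_p)
            for i in corr_idx:
                nets[i].pvalues = merged.merged_p.copy()
            np.savetxt(out / "merged_pvalues.tsv", merged.merged_p, delimiter="\t")
            report["stages"].append({"stage": stage, "brown_c": merged.c,
                                     "brown_f": merged.f, "k": merged.k})
        for net in nets:
            net.to_json(out / f"network_{net.method}.json")

        # -- threshold + consensus -------------------------------------------
        stage = "consensus"
        filtered = [threshold_network(n, config.weight_min, config.p_max) for n in nets]
        stack = align_networks(filtered)
        theta = config.theta if config.consensus_algorithm.lower() == "ss" else config.sv_theta
        consensus = consensus_for_dataset(stack, theta, config.consensus_algorithm)
        consensus.to_json(out / "consensus.json")
        report["stages"].append({
            "stage": stage,
            "algorithm": consensus.algorithm,
            "theta": consensus.theta,
            "w": consensus.w,
            "n_edges": len(consensus.edges),
        })

        # -- evaluate ----------------------------------------------------------
        if config.truth_path:
            truth = _load_truth_edges(config.truth_path)
            ev = precision_sensitivity(consensus, truth)
            report["evaluation"] = {
                "tp": ev.tp, "fp": ev.fp, "fn": ev.fn,
                "precision": None if np.isnan(ev.precision) else ev.precision,
                "sensitivity": None if np.isnan(ev.sensitivity) else ev.sensitivity,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return {
        "consensus": consensus,
        "per_method_networks": {n.method: n for n in nets},
        "report": report,
    }
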