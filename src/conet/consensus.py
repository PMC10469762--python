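"""Consensus networks: simple voting (SV) and scaled sum (SS).

Both algorithms combine w pre-filtered association networks aligned on a
shared node set.  For every taxon pair they decide inclusion from the
per-network evidence and, when included, report a multigraph-style edge
that keeps every method's weight alongside the consensus score:

Simple voting
    M_j = max(#negative weights, #positive weights) over the w networks;
    edge j enters the consensus iff M_j >= floor(theta * w) (and is
    present in at least one network).
Scaled sum
    Each network is rescaled by its maximum absolute weight so
    max|S^i| = 1; s_j = sum_i S^i_j; edge j enters iff |s_j| > (w-1) *
    theta.  Strengths count, and opposite-signed evidence cancels.

theta = 0 (or <= 1/w for SV) yields the union of the input edge sets,
theta = 1 the sign-consistent intersection; edge sets are nested as theta
grows, which is what trades sensitivity for precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import NetworkStack

__all__ = ["ConsensusEdge", "ConsensusNetwork", "simple_voting", "scaled_sum"]


@dataclass
class ConsensusEdge:
    """One consensus edge with its full multigraph annotation."""

    source: str
    target: str
    per_method_weights: dict[str, float]
    score: float
    sign: int
    merged_p: Optional[float] = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.source, self.target))


@dataclass
class ConsensusNetwork:
    """Consensus over w networks at threshold theta."""

    nodes: list[str]
    edges: list[ConsensusEdge]
    theta: float
    w: int
    algorithm: str  # "SV" or "SS"

    def edge_set(self) -> set[frozenset]:
        return {e.pair for e in self.edges}

    def edge_signs(self) -> dict[frozenset, int]:
        return {e.pair: e.sign for e in self.edges}

    def to_dict(self) -> dict:
        return {
            "nodes": [{"id": n, "lineage": n} for n in self.nodes],
            "links": [
                {
                    "source": e.source,
                    "target": e.target,
                    "weights": {m: w for m, w in sorted(e.per_method_weights.items())},
                    "score": e.score,
                    "sign": e.sign,
                    "merged_pvalue": e.merged_p,
                }
                for e in sorted(self.edges, key=lambda e: (e.source, e.target))
            ],
            "metadata": {
                "algorithm": self.algorithm,
                "theta": self.theta,
                "w": self.w,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _consensus_edges(
    stack: NetworkStack,
    include: np.ndarray,
    score: np.ndarray,
    sign: np.ndarray,
    merged_p: Optional[np.ndarray],
) -> list[ConsensusEdge]:
    edges = []
    nodes = stack.nodes
    weights = [net.weights for net in stack.networks]
    methods = stack.methods
    q = stack.q
    for i in range(q):
        for j in range(i + 1, q):
            if not include[i, j]:
                continue
            per_method = {
                m: float(w[i, j]) for m, w in zip(methods, weights) if w[i, j] != 0
            }
            a, b = sorted((nodes[i], nodes[j]))
            edges.append(
                ConsensusEdge(
                    a,
                    b,
                    per_method,
                    float(score[i, j]),
                    int(sign[i, j]),
                    None if merged_p is None else float(merged_p[i, j]),
                )
            )
    return edges


def _majority_sign(signs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-edge summary sign for SV: majority sign; ties broken by the
    sign of the largest-|weight| method."""
    n_pos = (signs > 0).sum(axis=0)
    n_neg = (signs < 0).sum(axis=0)
    out = np.sign(n_pos - n_neg).astype(int)
    ties = (n_pos == n_neg) & (n_pos > 0)
    if ties.any():
        flat = np.abs(weights).argmax(axis=0)
        strongest = np.sign(
            np.take_along_axis(weights, flat[None, ...], axis=0)[0]
        ).astype(int)
        out[ties] = strongest[ties]
    return out


def simple_voting(stack: NetworkStack, theta: float) -> ConsensusNetwork:
    """Voting consensus: keep edges whose dominant sign is reported by at
    least ``floor(theta * w)`` networks (and by at least one)."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    w = stack.w
    arr = np.stack([net.weights for net in stack.networks])  # w x q x q
    signs = np.sign(arr)
    m = np.maximum((signs > 0).sum(axis=0), (signs < 0).sum(axis=0))
    cutoff = max(int(np.floor(theta * w)), 1)
    include = m >= cutoff
    sign = _majority_sign(signs, arr)
    merged_p = _stack_merged_p(stack)
    edges = _consensus_edges(stack, include, m.astype(float), sign, merged_p)
    return ConsensusNetwork(list(stack.nodes), edges, float(theta), w, "SV")


def scaled_sum(stack: NetworkStack, theta: float) -> ConsensusNetwork:
    """Scaled-sum consensus: rescale each network to unit maximum absolute
    weight, sum per edge, keep edges with |s_j| > (w - 1) * theta."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    w = stack.w
    scaled = []
    for net in stack.networks:
        peak = np.abs(net.weights).max(initial=0.0)
        if peak == 0:
            warnings.warn(
                f"network {net.method!r} has no edges; it contributes 0 to "
                "every scaled sum",
                stacklevel=2,
            )
            scaled.append(net.weights)
        else:
            scaled.append(net.weights / peak)
    s = np.sum(scaled, axis=0)
    include = (np.abs(s) > (w - 1) * theta) & (s != 0)
    sign = np.sign(s).astype(int)
    merged_p = _stack_merged_p(stack)
    edges = _consensus_edges(stack, include, s, sign, merged_p)
    return ConsensusNetwork(list(stack.nodes), edges, float(theta), w, "SS")


def _stack_merged_p(stack: NetworkStack) -> Optional[np.ndarray]:
    """The merged p-value annotation shared by the stack's correlation
    networks, if any network carries p-values.

    The pipeline writes the Brown-merged matrix into every correlation
    network before thresholding, so taking the elementwise minimum over
    the available matrices recovers it (p = 1 padding never wins).
    """
    mats = [net.pvalues for net in stack.networks if net.pvalues is not None]
    if not mats:
        return None
    return np.minimum.reduce(mats)
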