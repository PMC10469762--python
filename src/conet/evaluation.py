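"""Benchmark scoring: edge-recovery precision/sensitivity and Bray-Curtis.

Predicted networks are compared with a ground-truth interaction support as
sets of undirected taxon pairs: TP are predicted edges present in the
truth, FP predicted edges absent from it, FN true edges missed.
Precision = TP/(TP+FP) and sensitivity = TP/(TP+FN); an empty prediction
has undefined precision, reported as NaN rather than 0 so aggregation can
skip instead of penalize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
from scipy.spatial import distance as _sp_distance

from .consensus import ConsensusNetwork
from .network import AssociationNetwork

__all__ = ["EvaluationResult", "precision_sensitivity", "bray_curtis", "truth_edge_set"]


@dataclass
class EvaluationResult:
    """TP/FP/FN counts and the derived precision and sensitivity."""

    tp: int
    fp: int
    fn: int
    sign_aware: bool = False

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return math.nan
        return self.tp / (self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return math.nan
        return self.tp / (self.tp + self.fn)


def truth_edge_set(
    truth_matrix: np.ndarray, nodes: Iterable[str]
) -> dict[frozenset, int]:
    """Undirected edge support (pair -> sign) from an interaction matrix.

    The support is symmetrized by union; the sign of an asymmetric pair is
    the sign of the entry with the larger magnitude.
    """
    nodes = list(nodes)
    t = np.asarray(truth_matrix, dtype=float)
    out: dict[frozenset, int] = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = t[i, j], t[j, i]
            if a != 0 or b != 0:
                val = a if abs(a) >= abs(b) else b
                out[frozenset((nodes[i], nodes[j]))] = int(np.sign(val))
    return out


def _predicted_edges(
    predicted: Union[AssociationNetwork, ConsensusNetwork]
) -> dict[frozenset, int]:
    if isinstance(predicted, ConsensusNetwork):
        return predicted.edge_signs()
    out = {}
    for a, b, w, _ in predicted.edges():
        out[frozenset((a, b))] = int(np.sign(w))
    return out


def precision_sensitivity(
    predicted: Union[AssociationNetwork, ConsensusNetwork],
    truth: Union[Mapping[frozenset, int], Iterable[frozenset]],
    sign_aware: bool = False,
) -> EvaluationResult:
    """Score a predicted network against a ground-truth edge set.

    ``truth`` is either a mapping pair -> sign or a bare collection of
    pairs (then ``sign_aware`` must be False).  Self-loops are ignored;
    comparison is sign-blind by default, and with ``sign_aware`` a
    predicted edge counts as TP only when its summary sign matches the
    truth sign.
    """
    if isinstance(truth, Mapping):
        truth_map = {frozenset(p): int(s) for p, s in truth.items()}
    else:
        truth_map = {frozenset(p): 0 for p in truth}
        if sign_aware:
            raise ValueError("sign_aware evaluation needs signed truth edges")
    truth_map = {p: s for p, s in truth_map.items() if len(p) == 2}
    if not truth_map:
        raise ValueError("empty truth edge set: nothing to evaluate")
    pred = {p: s for p, s in _predicted_edges(predicted).items() if len(p) == 2}

    tp = fp = 0
    for pair, sign in pred.items():
        if pair in truth_map and (not sign_aware or sign == truth_map[pair]):
            tp += 1
        else:
            fp += 1
    fn = len([p for p in truth_map if p not in pred])
    if sign_aware:
        # sign-flipped detections count as both a FP and a missed true edge
        fn = len(truth_map) - tp
    return EvaluationResult(tp=tp, fp=fp, fn=fn, sign_aware=sign_aware)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) between two
    non-negative composition vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_distance.braycurtis(u, v))
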