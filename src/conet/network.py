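"""Association networks: the shared data model for inference and consensus.

An :class:`AssociationNetwork` is one inference method's symmetric, signed,
weighted network over taxon keys (lineage-prefix strings), with optional
per-edge p-values.  A :class:`NetworkStack` aligns several such networks to
a common node set so that edge ``j`` means the same taxon pair in every
network — the representation the consensus and variance-attribution stages
operate on.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AssociationNetwork",
    "NetworkStack",
    "align_networks",
    "threshold_network",
    "overlap_counts",
]

_SYM_TOL = 1e-12


class AssociationNetwork:
    """Symmetric weighted signed network inferred by one method.

    Invariants enforced at construction: weights symmetric (tolerance
    1e-12) with an exactly zero diagonal; p-values, when present,
    symmetric and within [0, 1]; node keys unique.
    """

    def __init__(
        self,
        method: str,
        nodes: Sequence[str],
        weights,
        pvalues=None,
        metadata: Optional[Mapping[str, str]] = None,
        lineages: Optional[Mapping[str, str]] = None,
    ) -> None:
        nodes = [str(n) for n in nodes]
        if len(set(nodes)) != len(nodes):
            raise ValueError("node keys must be unique")
        q = len(nodes)
        w = np.array(weights, dtype=float)
        if w.shape != (q, q):
            raise ValueError(f"weights shape {w.shape} does not match {q} nodes")
        if np.abs(w - w.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("weights must be symmetric within 1e-12")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        p = None
        if pvalues is not None:
            p = np.array(pvalues, dtype=float)
            if p.shape != (q, q):
                raise ValueError("pvalues shape must match weights")
            if np.abs(p - p.T).max(initial=0.0) > _SYM_TOL:
                raise ValueError("pvalues must be symmetric")
            p = (p + p.T) / 2.0
            if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
                raise ValueError("pvalues must lie in [0, 1]")
        self.method = str(method)
        self.nodes = nodes
        self.weights = w
        self.pvalues = p
        self.metadata = dict(metadata or {})
        # optional node -> full lineage string, for serialization
        self.lineages = dict(lineages or {})

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> Iterable[tuple[str, str, float, Optional[float]]]:
        """Yield nonzero undirected edges once, source < target."""
        q = self.n_nodes
        for i in range(q):
            for j in range(i + 1, q):
                if self.weights[i, j] != 0:
                    p = None if self.pvalues is None else float(self.pvalues[i, j])
                    a, b = sorted((self.nodes[i], self.nodes[j]))
                    yield a, b, float(self.weights[i, j]), p

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _, _ in self.edges()}

    def copy(self) -> "AssociationNetwork":
        return AssociationNetwork(
            self.method,
            self.nodes,
            self.weights.copy(),
            None if self.pvalues is None else self.pvalues.copy(),
            dict(self.metadata),
            dict(self.lineages),
        )

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        links = []
        for a, b, wt, p in self.edges():
            links.append(
                {"source": a, "target": b, "weight": wt, "pvalue": p, "method": self.method}
            )
        return {
            "nodes": [{"id": n, "lineage": self.lineages.get(n, n)} for n in self.nodes],
            "links": links,
            "metadata": {"method": self.method, **self.metadata},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssociationNetwork":
        nodes = [str(n["id"]) for n in d["nodes"]]
        lineages = {str(n["id"]): str(n.get("lineage", n["id"])) for n in d["nodes"]}
        idx = {n: i for i, n in enumerate(nodes)}
        q = len(nodes)
        w = np.zeros((q, q))
        links = d.get("links", [])
        has_p = any(l.get("pvalue") is not None for l in links)
        p = np.ones((q, q)) if has_p else None
        if p is not None:
            np.fill_diagonal(p, 1.0)
        method = str(d.get("metadata", {}).get("method", links[0]["method"] if links else ""))
        for l in links:
            i, j = idx[str(l["source"])], idx[str(l["target"])]
            w[i, j] = w[j, i] = float(l["weight"])
            if p is not None and l.get("pvalue") is not None:
                p[i, j] = p[j, i] = float(l["pvalue"])
        meta = {k: v for k, v in d.get("metadata", {}).items() if k != "method"}
        return cls(method, nodes, w, p, meta, lineages)

    @classmethod
    def from_json(cls, source) -> "AssociationNetwork":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def to_gml(self, path) -> None:
        """Export to GML via networkx (weights as edge attributes)."""
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, lineage=self.lineages.get(n, n))
        for a, b, wt, p in self.edges():
            attrs = {"weight": wt}
            if p is not None:
                attrs["pvalue"] = p
            g.add_edge(a, b, **attrs)
        nx.write_gml(g, path)

    def to_edgelist_tsv(self, path) -> None:
        """Write a 3-column TSV edge list (source, target, weight)."""
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for a, b, wt, _ in self.edges():
                fh.write(f"{a}\t{b}\t{wt!r}\n")


class NetworkStack:
    """w association networks aligned to one shared, ordered node set."""

    def __init__(self, networks: Sequence[AssociationNetwork]) -> None:
        if not networks:
            raise ValueError("a NetworkStack needs at least one network")
        nodes = networks[0].nodes
        for net in networks[1:]:
            if net.nodes != nodes:
                raise ValueError("all stacked networks must share the node ordering")
        self.networks = list(networks)
        self.nodes = list(nodes)

    @property
    def w(self) -> int:
        return len(self.networks)

    @property
    def q(self) -> int:
        return len(self.nodes)

    @property
    def methods(self) -> list[str]:
        return [n.method for n in self.networks]

    @property
    def flattened(self) -> np.ndarray:
        """q^2 x w matrix; column i is network i's weight matrix with its
        columns stacked into one vector."""
        return np.column_stack(
            [net.weights.reshape(-1, order="F") for net in self.networks]
        )

    def network(self, i: int) -> AssociationNetwork:
        return self.networks[i]

    def unflatten(self, i: int) -> np.ndarray:
        return self.flattened[:, i].reshape((self.q, self.q), order="F")


def align_networks(nets: Sequence[AssociationNetwork]) -> NetworkStack:
    """Expand networks onto the sorted union of their node sets.

    Nodes absent from a network are added as isolated components: zero
    weight rows/columns and, when the network carries p-values, p = 1
    (maximally non-significant, so padding can never pass a significance
    filter).
    """
    if not nets:
        raise ValueError("align_networks requires at least one network")
    union = sorted(set().union(*(set(n.nodes) for n in nets)))
    idx = {n: i for i, n in enumerate(union)}
    q = len(union)
    lineages: dict[str, str] = {}
    for net in nets:
        lineages.update(net.lineages)
    aligned = []
    for net in nets:
        w = np.zeros((q, q))
        pos = [idx[n] for n in net.nodes]
        w[np.ix_(pos, pos)] = net.weights
        p = None
        if net.pvalues is not None:
            p = np.ones((q, q))
            p[np.ix_(pos, pos)] = net.pvalues
            np.fill_diagonal(p, 1.0)
        aligned.append(
            AssociationNetwork(net.method, union, w, p, dict(net.metadata), lineages)
        )
    return NetworkStack(aligned)


def threshold_network(
    net: AssociationNetwork, weight_min: float = 0.1, p_max: float = 0.05
) -> AssociationNetwork:
    """Zero out weak and non-significant edges.

    Edges with |weight| < ``weight_min`` are removed; when p-values are
    present, edges with p > ``p_max`` are removed too.  Networks without
    p-values (direct-association methods) are filtered on weight only.
    """
    if weight_min < 0:
        raise ValueError("weight_min must be non-negative")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    out = net.copy()
    mask = np.abs(out.weights) < weight_min
    if out.pvalues is not None:
        mask |= out.pvalues > p_max
    out.weights[mask] = 0.0
    np.fill_diagonal(out.weights, 0.0)
    return out


def overlap_counts(stack: NetworkStack) -> dict:
    """Count shared and total nodes and edges across a stack.

    A node participates in a network iff it has at least one nonzero
    incident edge; an edge exists iff its weight is nonzero.  The
    ``per_subset_counts`` entry tallies, for every set of methods sharing
    an edge, the number of edges present in exactly that subset
    (UpSet-plot style).
    """
    node_sets = []
    edge_sets = []
    for net in stack.networks:
        active = np.flatnonzero(np.abs(net.weights).sum(axis=0) > 0)
        node_sets.append({net.nodes[i] for i in active})
        edge_sets.append(net.edge_set())
    node_union = set().union(*node_sets)
    node_inter = set.intersection(*node_sets) if node_sets else set()
    edge_union = set().union(*edge_sets)
    edge_inter = set.intersection(*edge_sets) if edge_sets else set()
    per_subset: dict[tuple[str, ...], int] = {}
    methods = stack.methods
    for e in edge_union:
        subset = tuple(m for m, es in zip(methods, edge_sets) if e in es)
        per_subset[subset] = per_subset.get(subset, 0) + 1
    return {
        "node_intersection": len(node_inter),
        "node_union": len(node_union),
        "edge_intersection": len(edge_inter),
        "edge_union": len(edge_union),
        "per_subset_counts": per_subset,
    }
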