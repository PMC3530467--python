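"""Edge-weighted analyte networks.

Each gene's differential q-value is mapped to a significance score

    s_i = log10(q_i) / log10(q_min)

where q_min is the smallest q-value among network genes, so s = 1 at the most
significant gene and s = 0 at q = 1.  An edge's weight is the mean of its two
endpoint scores, bounded in [0, 1].  The transform is a replaceable strategy:
any monotone map built from (q_i, q_j, q_min) can be swapped in without
touching the module search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .diffstats import Q_FLOOR


def node_significance(q: float, q_min: float, q_floor: float = Q_FLOOR) -> float:
    """Normalized log-significance in [0, 1]; 1 at q = q_min, 0 at q = 1."""
    if not (q_floor <= q_min <= q <= 1.0):
        raise ValueError(f"require q_floor <= q_min <= q <= 1, got q={q}, q_min={q_min}")
    if q_min == 1.0:
        return 0.0
    return math.log10(q) / math.log10(q_min)


def mean_edge_weight(s_i: float, s_j: float) -> float:
    return 0.5 * (s_i + s_j)


def geometric_edge_weight(s_i: float, s_j: float) -> float:
    """Alternative strategy: geometric mean of the endpoint scores."""
    return math.sqrt(s_i * s_j)


@dataclass
class WeightedNetwork:
    """An interaction backbone plus per-gene q-values and derived edge weights.

    ``graph`` carries a ``weight`` attribute on every edge.  Fast array views
    used by the module search are built lazily and cached.
    """

    graph: nx.Graph
    analyte: str
    node_q: dict[str, float]
    q_min: float
    node_sig: dict[str, float]
    _arrays: "GraphArrays | None" = field(default=None, repr=False, compare=False)

    @property
    def arrays(self) -> "GraphArrays":
        if self._arrays is None:
            self._arrays = GraphArrays.from_graph(self.graph)
        return self._arrays

    def edge_weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def total_node_strength(self) -> float:
        """W_T: summed edge weight over all nodes (each edge counted twice)."""
        return 2.0 * sum(d["weight"] for _, _, d in self.graph.edges(data=True))


class GraphArrays:
    """CSR adjacency (node ids in sorted-name order) for the greedy search."""

    __slots__ = ("nodes", "index", "indptr", "indices", "wts", "strength", "total")

    def __init__(self, nodes, index, indptr, indices, wts, strength, total):
        self.nodes = nodes
        self.index = index
        self.indptr = indptr
        self.indices = indices
        self.wts = wts
        self.strength = strength
        self.total = total

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "GraphArrays":
        nodes = sorted(graph.nodes)
        index = {g: i for i, g in enumerate(nodes)}
        n = len(nodes)
        indptr = np.zeros(n + 1, dtype=np.int64)
        idx_chunks = []
        w_chunks = []
        strength = np.zeros(n)
        for i, g in enumerate(nodes):
            nbrs = sorted(graph[g], key=index.__getitem__)
            ids = np.array([index[v] for v in nbrs], dtype=np.int64)
            w = np.array([graph[g][v]["weight"] for v in nbrs], dtype=float)
            idx_chunks.append(ids)
            w_chunks.append(w)
            strength[i] = w.sum()
            indptr[i + 1] = indptr[i] + len(ids)
        indices = np.concatenate(idx_chunks) if idx_chunks else np.empty(0, np.int64)
        wts = np.concatenate(w_chunks) if w_chunks else np.empty(0, float)
        return cls(nodes, index, indptr, indices, wts, strength, float(strength.sum()))


def assign_edge_weights(
    net: nx.Graph,
    significance: pd.DataFrame | Mapping[str, float],
    analyte: str,
    q_floor: float = Q_FLOOR,
    edge_fn: Callable[[float, float], float] = mean_edge_weight,
) -> WeightedNetwork:
    """Build the analyte's weighted network from per-gene q-values.

    ``significance`` is either a mapping gene -> q or a DataFrame with a ``q``
    column (as returned by :func:`netmark.diffstats.sam_qvalues`).  Every
    network node must have a q-value; q_min is taken over network nodes.
    """
    if isinstance(significance, pd.DataFrame):
        qmap = significance["q"].to_dict()
    else:
        qmap = dict(significance)
    missing = [g for g in net.nodes if g not in qmap]
    if missing:
        raise KeyError(f"no q-value for network gene(s): {sorted(missing)[:5]}")
    node_q = {g: float(np.clip(qmap[g], q_floor, 1.0)) for g in net.nodes}
    q_min = min(node_q.values())
    node_sig = {g: node_significance(q, q_min, q_floor) for g, q in node_q.items()}
    graph = nx.Graph()
    graph.add_nodes_from(net.nodes)
    for u, v in net.edges:
        graph.add_edge(u, v, weight=edge_fn(node_sig[u], node_sig[v]))
    return WeightedNetwork(
        graph=graph, analyte=analyte, node_q=node_q, q_min=q_min, node_sig=node_sig
    )


def export_edge_weights(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tweight\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\t{net.graph[u][v]['weight']:.6g}\n")


def export_node_significance(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tq\ts\n")
        for g in sorted(net.graph.nodes):
            fh.write(f"{g}\t{net.node_q[g]:.6g}\t{net.node_sig[g]:.6g}\n")
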