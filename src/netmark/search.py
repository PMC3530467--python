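"""Greedy subnetwork search on an edge-weighted interactome.

Search outline: every triangle in the network is a candidate seed, ranked by
mean edge weight.  From each seed the module grows greedily, always absorbing
the neighbour of the current gene set S that most increases a parameterized
local-modularity measure, and stopping when no neighbour increases it (or a
size cap is hit).  A finished module's score is its internal edge weight
divided by its size.

Two interchangeable gain strategies are provided:

``size-normalized`` (default)
    The measure is Q_alpha(S) = W_in(S) / |S|**alpha, the size-penalised
    internal weight; at alpha = 1 the greedy directly ascends the module
    score.  A candidate v is accepted exactly when its connection k_vS
    exceeds the module's own per-gene internal weight (scaled by alpha), so
    weakly-tied neighbours cannot accrete once a dense core has formed.
    alpha tunes the neighbourhood size: larger alpha, tighter modules;
    alpha -> 0 removes the size penalty and growth runs to the cap.

``configuration``
    A Newman-style gain k_vS/W_T - alpha * k_v*k_S/W_T**2 comparing the
    candidate's connection to its expectation under a strength-preserving
    null (W_T: total node strength; k_v: candidate strength; k_S: summed
    strength of S).  Kept as an alternative for networks whose edge weights
    measure interaction strength; with significance-derived weights its
    strength null is systematically blind to weakly-connected background
    neighbours, so it is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .weighting import WeightedNetwork

logger = logging.getLogger(__name__)

GAIN_KINDS = ("size-normalized", "configuration")


@dataclass(frozen=True)
class Module:
    """A connected gene set discovered on one analyte network."""

    genes: frozenset[str]
    analyte: str
    score: float | None = None
    pvalue: float | None = None
    seed: tuple[str, str, str] | None = None
    name: str | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def with_name(self, name: str) -> "Module":
        return replace(self, name=name)

    def with_pvalue(self, p: float) -> "Module":
        return replace(self, pvalue=p)


@dataclass
class SearchConfig:
    """Knobs of the greedy search.

    alpha: resolution of the local-modularity measure (> 0); default 1.0,
        which makes the greedy ascend the size-normalised module score.
    max_module_size: hard cap on module growth (runaway guard).
    seed_rank_limit: consider only the top-ranked seeds if set.
    gain: gain strategy, one of ``size-normalized`` / ``configuration``.
    redundancy_threshold: a freshly grown module is discarded when its
        overlap score against an already-accepted module exceeds this
        (the accepted module came from a better-ranked seed); ``None``
        disables the filter and only exact duplicates are collapsed.
    """

    alpha: float = 1.0
    max_module_size: int = 50
    seed_rank_limit: int | None = None
    gain: str = "size-normalized"
    redundancy_threshold: float | None = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.max_module_size < 3:
            raise ValueError("max_module_size must be >= 3")
        if self.gain not in GAIN_KINDS:
            raise ValueError(f"gain must be one of {GAIN_KINDS}")
        if self.redundancy_threshold is not None and not (
            0.0 < self.redundancy_threshold <= 1.0
        ):
            raise ValueError("redundancy_threshold must lie in (0, 1]")


def enumerate_triangles(net: WeightedNetwork) -> list[tuple[str, str, str]]:
    """All triangles {s,t,u} of the backbone, as name-sorted tuples."""
    arr = net.arrays
    n = len(arr.nodes)
    nbr_sets = [
        set(arr.indices[arr.indptr[i]:arr.indptr[i + 1]].tolist()) for i in range(n)
    ]
    triangles: list[tuple[str, str, str]] = []
    for u in range(n):
        for v in arr.indices[arr.indptr[u]:arr.indptr[u + 1]]:
            v = int(v)
            if v <= u:
                continue
            for w in nbr_sets[u] & nbr_sets[v]:
                if w > v:
                    triangles.append((arr.nodes[u], arr.nodes[v], arr.nodes[int(w)]))
    return triangles


def enumerate_seeds(
    net: WeightedNetwork,
    triangles: Sequence[tuple[str, str, str]] | None = None,
) -> list[tuple[str, str, str]]:
    """Triangle seeds ranked by mean edge weight, descending; ties broken by
    the sorted gene names.  Passing a precomputed triangle list (topology is
    weight-independent) skips re-enumeration, e.g. across permutation nulls.
    """
    if triangles is None:
        triangles = enumerate_triangles(net)
    if not triangles:
        logger.warning("network is triangle-free: no seeds")
        return []
    g = net.graph

    def mean_w(t: tuple[str, str, str]) -> float:
        a, b, c = t
        return (g[a][b]["weight"] + g[a][c]["weight"] + g[b][c]["weight"]) / 3.0

    return sorted(triangles, key=lambda t: (-mean_w(t), t))


# ---------------------------------------------------------------------------
# gain definitions (reference implementations, straight from the formulas)


def modularity_gain(
    net: WeightedNetwork,
    S: Iterable[str],
    v: str,
    alpha: float,
    kind: str = "size-normalized",
) -> float:
    """Local-modularity gain of adding gene v to set S, from the definition
    (the greedy loop maintains the same quantities incrementally)."""
    S = set(S)
    if v in S:
        raise ValueError(f"{v!r} is already in the module")
    g = net.graph
    if not any(u in S for u in g[v]):
        raise ValueError(f"{v!r} is not adjacent to the module")
    k_vS = sum(g[v][u]["weight"] for u in g[v] if u in S)
    if kind == "size-normalized":
        w_in = sum(
            d["weight"] for u, w, d in g.subgraph(S).edges(data=True)
        )
        n = len(S)
        return (w_in + k_vS) / (n + 1) ** alpha - w_in / n ** alpha
    if kind == "configuration":
        strength = {u: sum(d["weight"] for d in g[u].values()) for u in S | {v}}
        W_T = 2.0 * sum(d["weight"] for _, _, d in g.edges(data=True))
        return k_vS / W_T - alpha * (strength[v] * sum(strength[u] for u in S)) / (W_T * W_T)
    raise ValueError(f"unknown gain kind {kind!r}")


# ---------------------------------------------------------------------------
# greedy growth


@njit(cache=True)
def _grow_sizenorm(indptr, indices, wts, alpha, max_size, s0, s1, s2):
    """Greedy ascent of W_in/|S|^alpha from a triangle seed (CSR graph).

    The step's argmax gain is the boundary node with the largest k_vS (ties:
    smallest id); it is absorbed iff the measure strictly increases.
    """
    n = indptr.shape[0] - 1
    in_S = np.zeros(n, np.bool_)
    in_bound = np.zeros(n, np.bool_)
    k_vS = np.zeros(n)
    bound = np.empty(n, np.int64)
    members = np.empty(max_size, np.int64)
    nb = 0
    size = 0
    w_in = 0.0

    for step in range(max_size):
        if step < 3:
            node = s0 if step == 0 else (s1 if step == 1 else s2)
        else:
            best = -1
            best_k = 0.0
            for bi in range(nb):
                j = bound[bi]
                if in_S[j]:
                    continue
                kj = k_vS[j]
                if kj > best_k or (kj == best_k and best >= 0 and j < best):
                    best = j
                    best_k = kj
            if best < 0:
                break
            gain = (w_in + best_k) / (size + 1.0) ** alpha - w_in / float(size) ** alpha
            if gain <= 0.0:
                break
            node = best
        # absorb
        in_S[node] = True
        members[size] = node
        size += 1
        w_in += k_vS[node]
        for p in range(indptr[node], indptr[node + 1]):
            j = indices[p]
            if not in_S[j]:
                k_vS[j] += wts[p]
                if not in_bound[j]:
                    in_bound[j] = True
                    bound[nb] = j
                    nb += 1
    return members[:size], w_in


def _grow_configuration(net: WeightedNetwork, seed_ids, alpha, max_size):
    """Python greedy for the configuration-null gain (incremental k_vS/k_S)."""
    arr = net.arrays
    W_T = arr.total
    inv_WT = 1.0 / W_T
    alpha_WT2 = alpha / (W_T * W_T)
    in_S = np.zeros(len(arr.nodes), dtype=bool)
    boundary: dict[int, float] = {}
    k_S = 0.0
    w_in = 0.0
    members: list[int] = []

    def absorb(node: int) -> None:
        nonlocal k_S, w_in
        in_S[node] = True
        members.append(node)
        k_S += arr.strength[node]
        w_in += boundary.pop(node, 0.0)
        for p in range(arr.indptr[node], arr.indptr[node + 1]):
            j = int(arr.indices[p])
            if not in_S[j]:
                boundary[j] = boundary.get(j, 0.0) + arr.wts[p]

    for i in seed_ids:
        absorb(i)
    while boundary and len(members) < max_size:
        best_gain = 0.0
        best = -1
        for j, kvs in boundary.items():
            gain = kvs * inv_WT - alpha_WT2 * arr.strength[j] * k_S
            if gain > best_gain or (gain == best_gain and best >= 0 and j < best):
                best_gain = gain
                best = j
        if best < 0 or best_gain <= 0.0:
            break
        absorb(best)
    return members, w_in


def grow_module(
    net: WeightedNetwork,
    seed: tuple[str, str, str],
    config: SearchConfig,
) -> Module:
    """Greedy expansion from a triangle seed.

    At each step the neighbour with the largest positive gain joins (ties go
    to the lexicographically smallest gene name); growth stops when no
    neighbour improves the measure or the size cap is hit.
    """
    arr = net.arrays
    try:
        seed_ids = sorted(arr.index[g] for g in seed)
    except KeyError as exc:
        raise KeyError(f"seed gene {exc} not in network") from exc
    if config.gain == "size-normalized":
        members, w_in = _grow_sizenorm(
            arr.indptr, arr.indices, arr.wts,
            float(config.alpha), config.max_module_size,
            seed_ids[0], seed_ids[1], seed_ids[2],
        )
        members = list(members)
    else:
        members, w_in = _grow_configuration(
            net, seed_ids, config.alpha, config.max_module_size
        )
    genes = frozenset(arr.nodes[int(i)] for i in members)
    return Module(
        genes=genes,
        analyte=net.analyte,
        score=w_in / len(genes),
        seed=tuple(sorted(seed)),
    )


def score_module(net: WeightedNetwork, S: Iterable[str]) -> float:
    """Internal edge weight of S divided by |S| (size-normalised score)."""
    S = set(S)
    if len(S) < 3:
        raise ValueError("a module needs at least 3 genes")
    g = net.graph
    total = 0.0
    for u, v, d in g.subgraph(S).edges(data=True):
        total += d["weight"]
    return total / len(S)


def find_modules(
    net: WeightedNetwork,
    config: SearchConfig,
    triangles: Sequence[tuple[str, str, str]] | None = None,
) -> list[Module]:
    """Run the full seeded search.

    Seeds are visited in rank order; a seed whose three genes are already
    covered by accepted modules is skipped, and a freshly grown module that
    substantially overlaps an accepted one (overlap score above
    ``config.redundancy_threshold``, shared genes over the smaller set) is
    discarded — the accepted module came from a better-ranked seed.  Every
    returned module is connected, contains its seed and has >= 3 genes.
    """
    from .significance import overlap_score

    seeds = enumerate_seeds(net, triangles)
    if config.seed_rank_limit is not None:
        seeds = seeds[: config.seed_rank_limit]
    modules: list[Module] = []
    covered: set[str] = set()
    seen: set[frozenset[str]] = set()
    for seed in seeds:
        if all(g in covered for g in seed):
            continue
        module = grow_module(net, seed, config)
        if module.genes in seen:
            continue
        seen.add(module.genes)
        if config.redundancy_threshold is not None and any(
            overlap_score(module.genes, m.genes) > config.redundancy_threshold
            for m in modules
        ):
            continue
        modules.append(module)
        covered |= module.genes
    return modules
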