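"""Empirical module significance and overlap-based merging.

The null model permutes gene q-values across the network (topology, hence
every degree, is untouched) and reruns the full greedy search; the scores of
all modules found across all permuted networks form one pooled null per
analyte.  A candidate module's empirical p-value is the fraction of null
scores at least as large as its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .search import Module, SearchConfig, enumerate_triangles, find_modules
from .weighting import WeightedNetwork, assign_edge_weights

logger = logging.getLogger(__name__)


@dataclass
class NullScoreDistribution:
    """Module scores found on weight-permuted networks.

    ``scores`` pools every module score from every permutation (the plain
    pooled null); ``per_perm`` keeps each permutation's scores sorted in
    descending order so a rank-matched pool (top-k per permutation) can be
    formed when comparing an observed list of k modules.
    """

    analyte: str
    scores: np.ndarray  # pooled module scores from permuted networks
    n_permutations: int
    seed: int
    per_perm: list[np.ndarray] | None = None

    def pooled(self, top_k: int | None = None) -> np.ndarray:
        """All null scores, or the top-k of each permutation if given."""
        if top_k is None or self.per_perm is None:
            return self.scores
        if not self.per_perm:
            return np.array([])
        return np.concatenate([p[:top_k] for p in self.per_perm])


def permute_node_weights(net: WeightedNetwork, seed: int) -> WeightedNetwork:
    """Shuffle q-values uniformly across genes and rebuild edge weights.

    The edge set is untouched, so degrees are preserved exactly; the q-value
    multiset (hence q_min, the significance anchor) is preserved as well.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.graph.nodes)
    qs = np.array([net.node_q[g] for g in genes])
    permuted = dict(zip(genes, qs[rng.permutation(len(genes))]))
    return assign_edge_weights(net.graph, permuted, analyte=net.analyte)


def null_distribution(
    net: WeightedNetwork,
    config: SearchConfig,
    n_perm: int = 100,
    seed: int = 0,
) -> NullScoreDistribution:
    """Pooled module-score null over ``n_perm`` weight-permuted networks."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    triangles = enumerate_triangles(net)
    if not triangles:
        logger.warning("triangle-free network: empty null distribution")
        return NullScoreDistribution(net.analyte, np.array([]), n_perm, seed, [])
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_perm)
    per_perm: list[np.ndarray] = []
    for s in child_seeds:
        permuted = permute_node_weights(net, int(s))
        found = find_modules(permuted, config, triangles=triangles)
        per_perm.append(np.sort([m.score for m in found])[::-1])
    pooled = (
        np.concatenate(per_perm) if any(len(p) for p in per_perm) else np.array([])
    )
    if pooled.size == 0:
        logger.warning("no modules found in any permuted network")
    return NullScoreDistribution(net.analyte, pooled, n_perm, seed, per_perm)


def empirical_pvalue(score: float, null: NullScoreDistribution) -> float:
    """Fraction of null scores >= score (ties count against the candidate)."""
    if null.scores.size == 0:
        raise ValueError("empty null distribution")
    return float(np.mean(null.scores >= score))


def filter_significant(
    modules: Sequence[Module],
    null: NullScoreDistribution,
    cutoff: float = 0.05,
    rank_matched: bool = True,
) -> list[Module]:
    """Keep modules with empirical p < cutoff, p recorded on each; ordered by
    ascending p, then descending score, then name-sorted genes.

    By default the null pool is rank-matched: with k observed modules, each
    permutation contributes its top-k scores, so the observed list (itself
    the redundancy-filtered cream of its landscape) is compared against
    equally-composed null lists rather than diluted by every permutation's
    weakest modules.  ``rank_matched=False`` reproduces the plain pooled
    fraction.
    """
    if not modules:
        return []
    pool = null.pooled(len(modules) if rank_matched else None)
    if pool.size == 0:
        raise ValueError("empty null distribution")
    kept = []
    for mod in modules:
        p = float(np.mean(pool >= mod.score))
        if p < cutoff:
            kept.append(mod.with_pvalue(p))
    kept.sort(key=lambda m: (m.pvalue, -m.score, sorted(m.genes)))
    return kept


def overlap_score(A: set, B: set, kind: str = "min") -> float:
    """Set overlap of two modules: shared genes relative to the smaller set
    (``min``, the default) or the Dice coefficient 2c/(a+b) (``dice``)."""
    a, b = len(A), len(B)
    if a == 0 or b == 0:
        raise ValueError("overlap of an empty gene set is undefined")
    c = len(set(A) & set(B))
    if kind == "min":
        return c / min(a, b)
    if kind == "dice":
        return 2.0 * c / (a + b)
    raise ValueError(f"unknown overlap kind {kind!r}")


def merge_modules(
    modules: Sequence[Module],
    threshold: float = 0.5,
    kind: str = "min",
) -> list[Module]:
    """Union-merge modules until no pair overlaps above the threshold.

    The highest-overlap pair merges first (deterministic priority); a merged
    module keeps the common analyte tag or becomes ``merged`` when its parents
    disagree, and its score/p-value are cleared for downstream re-scoring.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    pool = [m for m in modules]
    while True:
        best = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                ov = overlap_score(pool[i].genes, pool[j].genes, kind=kind)
                if ov > threshold:
                    key = (-ov, sorted(pool[i].genes | pool[j].genes))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        if best is None:
            return pool
        _, i, j = best
        a, b = pool[i], pool[j]
        analyte = a.analyte if a.analyte == b.analyte else "merged"
        merged = Module(
            genes=a.genes | b.genes,
            analyte=analyte,
            score=None,
            pvalue=None,
            seed=None,
            name=_merged_name(a, b),
        )
        pool = [m for k, m in enumerate(pool) if k not in (i, j)] + [merged]


def _merged_name(a: Module, b: Module) -> str | None:
    parts = [n for n in (a.name, b.name) if n]
    return "+".join(sorted(set("+".join(parts).split("+")))) if parts else None
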