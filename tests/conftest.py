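import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netmark.io import OmicsMatrix
from netmark.weighting import WeightedNetwork
from netmark.synthetic import PlantedModule, SyntheticCohortSpec, generate_cohort


def wnet_from_graph(graph: nx.Graph, analyte: str = "expression") -> WeightedNetwork:
    """Wrap an arbitrary weighted graph as a WeightedNetwork (q metadata is
    irrelevant for pure search tests)."""
    node_q = {g: 0.5 for g in graph.nodes}
    node_sig = {g: 0.5 for g in graph.nodes}
    return WeightedNetwork(
        graph=graph, analyte=analyte, node_q=node_q, q_min=0.5, node_sig=node_sig
    )


def random_weighted_graph(rng: np.random.Generator, n_max: int = 10) -> nx.Graph:
    """Small random connected-ish graph with positive random edge weights."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.35, 0.8))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    graph = nx.Graph()
    graph.add_nodes_from(f"n{i:02d}" for i in range(n))
    for u, v in g.edges:
        graph.add_edge(f"n{u:02d}", f"n{v:02d}", weight=float(rng.uniform(0.05, 2.0)))
    return graph


def triangle_graph(weights=(1.0, 1.0, 1.0)) -> nx.Graph:
    g = nx.Graph()
    g.add_edge("A", "B", weight=weights[0])
    g.add_edge("A", "C", weight=weights[1])
    g.add_edge("B", "C", weight=weights[2])
    return g


def make_matrix(values, genes, samples, analyte="expression", labels=None):
    df = pd.DataFrame(np.asarray(values, float), index=genes, columns=samples)
    if labels is not None:
        labels = pd.Series(labels, index=samples)
    return OmicsMatrix(analyte, df, labels)


def two_group_matrix(rng, n_genes, n_pos, n_neg, analyte="expression"):
    samples = [f"P{i}" for i in range(n_pos)] + [f"N{i}" for i in range(n_neg)]
    labels = ["positive"] * n_pos + ["negative"] * n_neg
    values = rng.standard_normal((n_genes, n_pos + n_neg))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    return make_matrix(values, genes, samples, analyte, labels)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 400-gene cohort with three planted dual-analyte modules,
    sized for end-to-end pipeline tests."""
    spec = SyntheticCohortSpec(
        n_genes=400,
        n_edges_target=1600,
        n_pos=12,
        n_neg=14,
        planted_modules=tuple(PlantedModule(size=s) for s in (5, 6, 7)),
        seed=7,
    )
    return generate_cohort(spec)
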