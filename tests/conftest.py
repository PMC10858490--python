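import numpy as np
import pytest

from phenorare.ontology import (
    OntologyGraph,
    information_content,
    load_ontology,
)
from phenorare.similarity import SimilarityModel

TOY7_EDGES = "T1\tT0\nT2\tT0\nT3\tT1\nT4\tT1\nT5\tT3\nT6\tT2\n"

# Two ontological siblings with distinct etiologies under a shared parent,
# mirroring chronic kidney disease vs acute kidney injury below renal
# insufficiency.
RENAL_EDGES = (
    "renal_insufficiency\tabnormal_kidney\n"
    "abnormal_kidney\tphenotypic_abnormality\n"
    "chronic_kidney_disease\trenal_insufficiency\n"
    "acute_kidney_injury\trenal_insufficiency\n"
    "stage5_ckd\tchronic_kidney_disease\n"
)


@pytest.fixture(scope="session")
def toy7() -> OntologyGraph:
    return load_ontology(TOY7_EDGES)


@pytest.fixture(scope="session")
def toy7_stats(toy7):
    return information_content(toy7)


@pytest.fixture(scope="session")
def toy7_lin(toy7, toy7_stats):
    return SimilarityModel(method="lin", graph=toy7, stats=toy7_stats)


@pytest.fixture(scope="session")
def toy7_restricted(toy7, toy7_stats):
    return SimilarityModel(method="restricted_lin", graph=toy7, stats=toy7_stats)


@pytest.fixture(scope="session")
def renal() -> OntologyGraph:
    return load_ontology(RENAL_EDGES)


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Random rooted DAG: each term after the root picks 1-2 earlier parents."""
    import networkx as nx

    names = [f"N{i:03d}" for i in range(n_terms)]
    g = nx.DiGraph()
    g.add_node(names[0])
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3 and i >= 2)
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in parents:
            g.add_edge(names[i], names[p])
    return OntologyGraph(graph=g, root=names[0])


def brute_force_ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """Reflexive ancestors by naive fixed-point expansion over parent edges."""
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown |= set(graph.graph.successors(t))
        if grown == out:
            return out
        out = grown


def brute_force_descendant_count(graph: OntologyGraph, term: str) -> int:
    """Count terms whose reflexive ancestor set contains ``term``."""
    return sum(term in brute_force_ancestors(graph, t) for t in graph.terms)


def brute_force_mica_ic(graph: OntologyGraph, stats, p1: str, p2: str) -> float:
    common = brute_force_ancestors(graph, p1) & brute_force_ancestors(graph, p2)
    return max(stats.ic[t] for t in common)
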