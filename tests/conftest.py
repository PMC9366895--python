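"""Shared fixtures: a hand-sized cross-species ontology with known IC values,
plus random-DAG builders used by the oracle-equivalence tests."""

import numpy as np
import pytest

from phenosim.annotations import AnnotationCorpus
from phenosim.ontology import OntologyGraph, PhenotypeClass
from phenosim.similarity import compute_ic


@pytest.fixture
def toy_graph() -> OntologyGraph:
    """R root; human A with child A1; model Ap ≡ A with child A1p; B under R.

    The equivalence merges A and Ap, so A1 (human) and A1p (model) share the
    merged class as their most informative common ancestor.
    """
    g = OntologyGraph()
    g.add_class(PhenotypeClass("R:0", label="root", species_tag="integrated"))
    g.add_class(PhenotypeClass("A:1", label="A", species_tag="human"))
    g.add_class(PhenotypeClass("A:2", label="A1", species_tag="human"))
    g.add_class(PhenotypeClass("Z:1", label="A-prime", species_tag="fish"))
    g.add_class(PhenotypeClass("Z:2", label="A1-prime", species_tag="fish"))
    g.add_class(PhenotypeClass("B:1", label="B", species_tag="human"))
    g.add_subclass_edge("A:1", "R:0")
    g.add_subclass_edge("A:2", "A:1")
    g.add_subclass_edge("Z:1", "R:0")
    g.add_subclass_edge("Z:2", "Z:1")
    g.add_subclass_edge("B:1", "R:0")
    g.add_equivalence("A:1", "Z:1")
    g.validate()
    return g


@pytest.fixture
def toy_corpus(toy_graph) -> AnnotationCorpus:
    """Four entities whose propagated sets give ic[A] = -log2(3/4) ≈ 0.415.

    e1:{A1}, e2:{A1'}, e3:{B}, e4:{A} — the merged A class appears in three
    of the four propagated sets, the root in all four, everything else once.
    """
    return AnnotationCorpus.from_direct(
        {"e1": {"A:2"}, "e2": {"Z:2"}, "e3": {"B:1"}, "e4": {"A:1"}},
        toy_graph,
        entity_kind="gene",
        species_tag="human",
    )


@pytest.fixture
def toy_ic(toy_corpus):
    return compute_ic([toy_corpus])


def random_dag(rng: np.random.Generator, n_nodes: int) -> OntologyGraph:
    """Random DAG: each node gets subclass edges to a few lower-index nodes."""
    g = OntologyGraph()
    for i in range(n_nodes):
        g.add_class(PhenotypeClass(f"N:{i:03d}"))
    for i in range(1, n_nodes):
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in parents:
            g.add_subclass_edge(f"N:{i:03d}", f"N:{int(p):03d}")
    g.validate()
    return g


def brute_force_ancestors(graph: OntologyGraph, class_id: str) -> frozenset:
    """Naive reachability enumeration over canonical subclass edges."""
    start = graph.canonical(class_id)
    edges = {}
    for c, p in graph.subclass_edges:
        cc, cp = graph.canonical(c), graph.canonical(p)
        if cc != cp:
            edges.setdefault(cc, set()).add(cp)
    seen = {start}
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for parent in edges.get(node, ()):
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return frozenset(seen)
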