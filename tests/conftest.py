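"""Shared fixtures: toy ontologies and seeded synthetic corpora."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from okdsp.ontology import (
    AnnotationSet,
    OntologyDAG,
    build_semantic_weights,
    propagate_annotations,
)
from okdsp.synthetic import (
    SyntheticSpec,
    apply_planted_annotations,
    generate_matrix,
    generate_ontology_and_annotations,
    nested_demo_spec,
)


def make_dag(is_a: dict[str, set[str]], root: str) -> OntologyDAG:
    terms = set(is_a) | {p for ps in is_a.values() for p in ps}
    return OntologyDAG(
        terms=terms,
        name={t: t for t in terms},
        is_a={t: set(is_a.get(t, set())) for t in terms},
        namespace_root=root,
    )


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """root <- A <- B."""
    return make_dag({"A": {"root"}, "B": {"A"}, "root": set()}, "root")


@pytest.fixture
def sibling_dag() -> OntologyDAG:
    """root <- p <- {c1, c2}."""
    return make_dag(
        {"p": {"root"}, "c1": {"p"}, "c2": {"p"}, "root": set()}, "root"
    )


@pytest.fixture(scope="session")
def synth_corpus():
    """Deterministic mid-size synthetic ontology + annotations + weights."""
    spec = SyntheticSpec(n_genes=300, ontology_depth=4, branching=3, seed=11)
    dag, ann = generate_ontology_and_annotations(spec)
    weights = build_semantic_weights(dag, ann)
    return dag, ann, weights


@pytest.fixture(scope="session")
def nested_fixture():
    """Noiseless nested two-signal compendium with ground truth."""
    spec = nested_demo_spec(seed=3)
    dag, ann = generate_ontology_and_annotations(spec)
    ann = apply_planted_annotations(spec, dag, ann)
    matrix, truth = generate_matrix(spec, dag, ann)
    return spec, dag, ann, matrix, truth


def exact_steiner_length(graph: nx.Graph, terminals: set[str]) -> float:
    """Brute-force minimum Steiner tree by enumerating Steiner-node subsets.

    Independent oracle: for every subset S of non-terminals, take the
    minimum spanning tree of the subgraph induced on terminals + S (if
    connected and spanning all terminals) and return the global minimum
    total weight.
    """
    terminals = set(terminals)
    others = [n for n in graph.nodes if n not in terminals]
    best = float("inf")
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = terminals | set(extra)
            sub = graph.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            mst_w = sum(
                d["weight"] for _, _, d in nx.minimum_spanning_edges(sub, data=True)
            )
            best = min(best, mst_w)
    return best


def uniform_annotations(dag: OntologyDAG, genes_per_leaf: int = 2) -> AnnotationSet:
    """Every leaf annotates ``genes_per_leaf`` distinct genes."""
    leaves = sorted(t for t in dag.terms if not dag.children(t))
    direct = {}
    i = 0
    for t in leaves:
        for _ in range(genes_per_leaf):
            direct[f"g{i}"] = {t}
            i += 1
    return propagate_annotations(direct, dag)
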