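"""Ontology backbone: is-a DAG, annotation propagation, information content,
semantic distances, and per-instance GOGene graphs.

The ontology is restricted to a single namespace (default
``biological_process``) and to ``is_a`` edges.  Gene annotations are
propagated up the hierarchy under the true-path rule: annotation to a term
implies annotation to every ancestor of that term.

Semantic weighting follows the standard annotation-frequency information
content

    ic(t) = -ln( n_t / N )

where ``n_t`` is the number of background genes annotated (after
propagation) to ``t`` and ``N`` the background size.  An is-a edge
(parent p, child c) is weighted ``ic(c) - ic(p) >= 0``, and the semantic
distance between two terms is the weighted shortest path in the
undirected is-a graph.  This makes distances additive along is-a chains
and computable from the loaded corpus alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyDAG",
    "AnnotationSet",
    "GOGeneGraph",
    "SemanticWeights",
    "OntologyFormatError",
    "OntologyValidationError",
    "UnknownTermError",
    "UndefinedICError",
    "EmptyGraphError",
    "load_obo",
    "propagate_annotations",
    "information_content",
    "build_semantic_weights",
    "semantic_distance",
    "build_gogene_graph",
]

DEFAULT_NAMESPACE = "biological_process"


class OntologyFormatError(ValueError):
    """The OBO file could not be parsed."""


class OntologyValidationError(ValueError):
    """The parsed ontology violates a structural invariant (cycle, no root...)."""


class UnknownTermError(KeyError):
    """An annotation refers to a term absent from the ontology."""

    def __init__(self, terms: Iterable[str]):
        self.terms = sorted(set(terms))
        super().__init__(f"annotations refer to unknown term(s): {', '.join(self.terms)}")


class UndefinedICError(ValueError):
    """Information content requested for a term annotating zero genes."""


class EmptyGraphError(ValueError):
    """No input gene carries any annotation."""


@dataclass
class OntologyDAG:
    """Single-namespace is-a hierarchy.

    Parameters
    ----------
    terms : set of term ids
    name : term id -> human-readable label
    is_a : child term id -> set of parent term ids
    namespace_root : the unique term without parents
    """

    terms: set[str]
    name: dict[str, str]
    is_a: dict[str, set[str]]
    namespace_root: str
    namespace: str = DEFAULT_NAMESPACE

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        for child, parents in self.is_a.items():
            if child not in self.terms:
                raise OntologyValidationError(f"is_a child {child!r} not in terms")
            missing = parents - self.terms
            if missing:
                raise OntologyValidationError(
                    f"is_a parents of {child!r} not in terms: {sorted(missing)}"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyValidationError(f"is_a cycle detected at edge {cyc[0][:2]}")
        roots = [t for t in self.terms if not self.parents(t)]
        if len(roots) != 1:
            raise OntologyValidationError(
                f"expected exactly one namespace root, found {sorted(roots)}"
            )
        if roots[0] != self.namespace_root:
            raise OntologyValidationError(
                f"declared root {self.namespace_root!r} but parentless term is {roots[0]!r}"
            )
        for t in self.terms:
            if t != self.namespace_root and self.namespace_root not in self.ancestors(t):
                raise OntologyValidationError(f"term {t!r} cannot reach the root")

    def graph(self) -> nx.DiGraph:
        """Directed child -> parent graph over is-a edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self.is_a.items():
            for p in parents:
                g.add_edge(child, p)
        return g

    def parents(self, term: str) -> set[str]:
        return set(self.is_a.get(term, set()))

    def children(self, term: str) -> set[str]:
        return {c for c, ps in self.is_a.items() if term in ps}

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of ``term`` (term itself excluded)."""
        seen: set[str] = set()
        stack = list(self.parents(term))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents(t))
        return seen

    def descendants(self, term: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self.children(term))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.children(t))
        return seen

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDAG):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.name == other.name
            and {t: set(p) for t, p in self.is_a.items() if p}
            == {t: set(p) for t, p in other.is_a.items() if p}
            and self.namespace_root == other.namespace_root
        )


@dataclass
class AnnotationSet:
    """Direct and true-path-propagated gene -> term annotations."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    background: set[str]

    def genes_of_term(self, term: str) -> set[str]:
        """Background genes annotated to ``term`` after propagation."""
        return {g for g in self.background if term in self.propagated.get(g, ())}

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.background:
            for t in self.propagated.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass
class GOGeneGraph:
    """Ontology subgraph induced by a gene list's annotations.

    Each node keeps track of the genes it currently holds; during
    summarization genes migrate upward as leaves are trimmed.
    """

    dag: OntologyDAG
    node_genes: dict[str, set[str]]
    input_genes: list[str]
    unannotated: set[str] = field(default_factory=set)

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.node_genes.values():
            out |= gs
        return out


@dataclass
class SemanticWeights:
    """IC per term and the derived is-a edge weights.

    Terms with zero propagated annotations are floored at one gene when the
    weight table is built, so every edge keeps a finite, non-negative weight
    and IC stays monotone along is-a edges (the true count of a parent is
    never smaller than a child's).
    """

    ic: dict[str, float]
    edge_weight: dict[tuple[str, str], float]

    def weighted_graph(self, dag: OntologyDAG) -> nx.Graph:
        """Undirected is-a graph with ``weight`` edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(dag.terms)
        for (p, c), w in self.edge_weight.items():
            g.add_edge(p, c, weight=w)
        return g


# ---------------------------------------------------------------------------
# readers / constructors
# ---------------------------------------------------------------------------


def load_obo(path: str, namespace: str = DEFAULT_NAMESPACE) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into a validated single-namespace DAG.

    Obsolete terms are dropped (obonet's default), as are terms outside the
    selected namespace; only ``is_a`` edges are kept.  A file whose is-a
    edges form a cycle raises :class:`OntologyValidationError` naming one
    offending edge.
    """
    try:
        raw = obonet.read_obo(path)
    except Exception as exc:  # pragma: no cover - message shape varies
        raise OntologyFormatError(f"cannot parse OBO file {path!r}: {exc}") from exc

    def ns_of(data: Mapping) -> str:
        return data.get("namespace", namespace)

    keep = {t for t, d in raw.nodes(data=True) if ns_of(d) == namespace}
    if not keep:
        raise OntologyValidationError(f"no terms in namespace {namespace!r} in {path!r}")
    terms = set(keep)
    name = {t: raw.nodes[t].get("name", t) for t in terms}
    is_a: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, key in raw.edges(keys=True):
        if key == "is_a" and child in terms and parent in terms:
            is_a[child].add(parent)

    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for c, ps in is_a.items():
        g.add_edges_from((c, p) for p in ps)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise OntologyValidationError(f"is_a cycle detected at edge {cyc[0][:2]}")
    roots = sorted(t for t in terms if not is_a[t])
    if len(roots) != 1:
        raise OntologyValidationError(
            f"expected exactly one namespace root, found {roots}"
        )
    return OntologyDAG(
        terms=terms, name=name, is_a=is_a, namespace_root=roots[0], namespace=namespace
    )


def propagate_annotations(
    direct: Mapping[str, Iterable[str]], dag: OntologyDAG
) -> AnnotationSet:
    """Propagate direct gene annotations up all is-a paths (true-path rule).

    ``background`` is the set of genes with at least one direct annotation.
    Annotation to a term absent from the DAG raises
    :class:`UnknownTermError` listing every offending term id.
    """
    unknown: set[str] = set()
    direct_sets: dict[str, set[str]] = {}
    for g, ts in direct.items():
        ts = set(ts)
        unknown |= ts - dag.terms
        if ts:
            direct_sets[g] = ts
    if unknown:
        raise UnknownTermError(unknown)

    anc_cache: dict[str, set[str]] = {}

    def anc(t: str) -> set[str]:
        if t not in anc_cache:
            anc_cache[t] = dag.ancestors(t)
        return anc_cache[t]

    propagated = {
        g: set().union(ts, *(anc(t) for t in ts)) for g, ts in direct_sets.items()
    }
    return AnnotationSet(
        direct={g: set(ts) for g, ts in direct_sets.items()},
        propagated=propagated,
        background=set(direct_sets),
    )


def information_content(term: str, ann: AnnotationSet) -> float:
    """Annotation-frequency IC in natural-log units: -ln(n_term / N)."""
    n = sum(1 for g in ann.background if term in ann.propagated.get(g, ()))
    if n == 0:
        raise UndefinedICError(f"term {term!r} annotates no background gene")
    return -math.log(n / len(ann.background))


def build_semantic_weights(dag: OntologyDAG, ann: AnnotationSet) -> SemanticWeights:
    """IC for every term and weights for every is-a edge.

    Zero-count terms are floored at a single gene so the weight table covers
    the whole DAG; :func:`information_content` itself still refuses them.
    """
    counts = ann.term_counts()
    n_bg = max(len(ann.background), 1)
    ic = {t: -math.log(max(counts.get(t, 0), 1) / n_bg) for t in dag.terms}
    edge_weight: dict[tuple[str, str], float] = {}
    for child, parents in dag.is_a.items():
        for p in parents:
            w = ic[child] - ic[p]
            # counts can only shrink child-ward; guard fp round-off
            edge_weight[(p, child)] = max(w, 0.0)
    return SemanticWeights(ic=ic, edge_weight=edge_weight)


def semantic_distance(
    t1: str, t2: str, weights: SemanticWeights, dag: OntologyDAG
) -> float:
    """Weighted shortest-path distance in the undirected is-a graph.

    Symmetric, zero iff ``t1 == t2``; ``math.inf`` for terms in disconnected
    components (different namespaces).
    """
    if t1 == t2:
        return 0.0
    g = weights.weighted_graph(dag)
    try:
        return float(nx.dijkstra_path_length(g, t1, t2))
    except nx.NetworkXNoPath:
        return math.inf


def build_gogene_graph(
    genes: Iterable[str], dag: OntologyDAG, ann: AnnotationSet
) -> GOGeneGraph:
    """GOGene graph for one perturbation instance's responding gene list.

    Nodes are the direct-annotation terms of the input genes plus all their
    ancestors; each direct-annotation node initially holds the genes
    annotated to it (a gene annotated in two branches sits at both leaves).
    Genes without any annotation are reported in ``unannotated``, never
    silently dropped.
    """
    genes = list(genes)
    if not genes:
        raise EmptyGraphError("empty input gene list")
    node_genes: dict[str, set[str]] = {}
    nodes: set[str] = set()
    unannotated: set[str] = set()
    for g in genes:
        terms = ann.direct.get(g, set()) & dag.terms
        if not terms:
            unannotated.add(g)
            continue
        for t in terms:
            node_genes.setdefault(t, set()).add(g)
            if t not in nodes:
                nodes.add(t)
                nodes |= dag.ancestors(t)
    if not nodes:
        raise EmptyGraphError("no input gene carries any annotation")
    sub = OntologyDAG(
        terms=nodes,
        name={t: dag.name.get(t, t) for t in nodes},
        is_a={t: dag.parents(t) & nodes for t in nodes},
        namespace_root=dag.namespace_root,
        namespace=dag.namespace,
    )
    for t in nodes:
        node_genes.setdefault(t, set())
    return GOGeneGraph(
        dag=sub, node_genes=node_genes, input_genes=genes, unannotated=unannotated
    )
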