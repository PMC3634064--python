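"""Summarize responding gene lists into enriched, coherent functional modules.

The summarization walks a GOGene graph bottom-up.  Each round, every current
leaf term is scored with a one-sided hypergeometric enrichment test over the
genes it currently holds.  A leaf that is significantly enriched, holds at
least ``min_module_genes`` genes, and whose held genes are functionally
coherent is frozen: its held genes are emitted as a functional module under
that summary term and the node is removed without merging.  Otherwise the
least-enriched leaf (largest p) is trimmed — its held genes migrate to the
nearest present parent by semantic distance — until only the namespace root
remains.  Genes that end up at the root are reported as unassigned.

Coherence is Monte-Carlo-costly, so it is evaluated lazily, only for leaves
that already pass enrichment and the size floor; the emitted set is
identical to the eager order of checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom

from .coherence import CoherenceScorer
from .ontology import (
    AnnotationSet,
    GOGeneGraph,
    OntologyDAG,
    SemanticWeights,
    build_gogene_graph,
)

__all__ = [
    "FunctionalModule",
    "SummarizationParams",
    "SummarizationResult",
    "enrichment_pvalue",
    "summarize_instance",
    "merge_modules",
]


@dataclass
class FunctionalModule:
    """A gene set summarized under one enriched, coherent ontology term."""

    summary_term: str
    genes: set[str]
    enrichment_p: float
    coherence_p: float
    source_instances: set[str] = field(default_factory=set)
    name: str = ""
    #: per-source (enrichment_p, coherence_p), populated by merge_modules
    source_pvalues: dict[str, tuple[float, float]] = field(default_factory=dict)

    def sort_key(self) -> str:
        return self.summary_term


@dataclass
class SummarizationParams:
    enrichment_alpha: float = 0.05
    coherence_alpha: float = 0.05
    min_module_genes: int = 3
    n_null: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.enrichment_alpha < 1 and 0 < self.coherence_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.min_module_genes < 2:
            raise ValueError("min_module_genes must be >= 2")


@dataclass
class SummarizationResult:
    modules: list[FunctionalModule]
    unassigned: set[str]
    unannotated: set[str]


def enrichment_pvalue(term: str, gene_list: set[str], ann: AnnotationSet) -> float:
    """One-sided hypergeometric upper-tail enrichment p-value, P(X >= k).

    N = background size, K = background genes annotated to ``term`` under
    propagation, n = |gene_list|, k = |overlap of gene_list with K-set|.
    """
    term_genes = ann.genes_of_term(term)
    if not term_genes:
        raise ValueError(f"term {term!r} annotates no background gene")
    gene_list = set(gene_list) & ann.background
    N = len(ann.background)
    K = len(term_genes)
    n = len(gene_list)
    k = len(gene_list & term_genes)
    assert k <= min(K, n)
    if k == 0:
        return 1.0
    # survival function P(X > k-1) = P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def _nearest_parent(
    leaf: str,
    present: set[str],
    gg_dag: OntologyDAG,
    weights: SemanticWeights,
    wgraph,
) -> str:
    """Present parent at minimal semantic distance; ties broken toward the
    more general parent (smaller IC) and then lexicographic term id."""
    parents = sorted(gg_dag.parents(leaf) & present)
    if not parents:
        raise RuntimeError(f"leaf {leaf!r} has no present parent")  # pragma: no cover
    if len(parents) == 1:
        return parents[0]
    # true weighted shortest paths: with zero-weight edges the direct is-a
    # edge need not be the closest route, and ties must fall to the more
    # general parent
    dist = nx.single_source_dijkstra_path_length(wgraph, leaf, weight="weight")
    return min(parents, key=lambda p: (dist.get(p, math.inf), weights.ic[p], p))


def summarize_instance(
    gene_list: set[str] | list[str],
    dag: OntologyDAG,
    ann: AnnotationSet,
    weights: SemanticWeights,
    params: SummarizationParams | None = None,
    scorer: CoherenceScorer | None = None,
    instance_id: str | None = None,
) -> SummarizationResult:
    """Iterative leaf trimming of the GOGene graph for one instance.

    A shared :class:`~okdsp.coherence.CoherenceScorer` may be passed to reuse
    null-distribution caches across instances; results are identical either
    way because null draws depend only on (seed, gene-set size).
    """
    params = params or SummarizationParams()
    if scorer is None:
        scorer = CoherenceScorer(
            dag, ann, weights, n_null=params.n_null, seed=params.seed
        )
    gg: GOGeneGraph = build_gogene_graph(list(gene_list), dag, ann)
    present = set(gg.dag.terms)
    held = {t: set(gs) for t, gs in gg.node_genes.items()}
    children_left = {t: len(gg.dag.children(t) & present) for t in present}
    root = gg.dag.namespace_root
    wgraph = weights.weighted_graph(dag)
    modules: list[FunctionalModule] = []
    instance_ids = {instance_id} if instance_id is not None else set()

    def leaves() -> list[str]:
        return sorted(t for t in present if children_left[t] == 0 and t != root)

    def remove(t: str) -> None:
        present.discard(t)
        for p in gg.dag.parents(t) & present:
            children_left[p] -= 1

    while len(present) > 1:
        current = leaves()
        pvals = {t: enrichment_pvalue(t, held[t], ann) for t in current}
        emitted = False
        for t in current:
            if pvals[t] > params.enrichment_alpha:
                continue
            if len(held[t]) < params.min_module_genes:
                continue
            coh = scorer.pvalue(held[t])
            if coh.p_value > params.coherence_alpha:
                continue
            modules.append(
                FunctionalModule(
                    summary_term=t,
                    genes=set(held[t]),
                    enrichment_p=pvals[t],
                    coherence_p=coh.p_value,
                    source_instances=set(instance_ids),
                    name=gg.dag.name.get(t, t),
                )
            )
            remove(t)  # frozen: genes leave the graph, no upward merge
            emitted = True
        if emitted:
            continue
        worst = max(current, key=lambda t: (pvals[t], t))
        target = _nearest_parent(worst, present, gg.dag, weights, wgraph)
        held[target] |= held[worst]
        remove(worst)

    unassigned = set(held[root]) if root in present else set()
    modules.sort(key=FunctionalModule.sort_key)
    return SummarizationResult(
        modules=modules, unassigned=unassigned, unannotated=set(gg.unannotated)
    )


def merge_modules(per_instance_modules: list[FunctionalModule]) -> list[FunctionalModule]:
    """Merge modules sharing a summary term across perturbation instances.

    Genes and source instances are unioned; the merged record carries the
    minimum enrichment/coherence p-values for reporting, with the per-source
    values preserved in ``source_pvalues``.
    """
    by_term: dict[str, FunctionalModule] = {}
    for m in per_instance_modules:
        cur = by_term.get(m.summary_term)
        src_p = dict(m.source_pvalues)
        if not src_p and m.source_instances:
            src_p = {
                i: (m.enrichment_p, m.coherence_p) for i in sorted(m.source_instances)
            }
        if cur is None:
            by_term[m.summary_term] = FunctionalModule(
                summary_term=m.summary_term,
                genes=set(m.genes),
                enrichment_p=m.enrichment_p,
                coherence_p=m.coherence_p,
                source_instances=set(m.source_instances),
                name=m.name,
                source_pvalues=src_p,
            )
        else:
            cur.genes |= m.genes
            cur.source_instances |= m.source_instances
            cur.enrichment_p = min(cur.enrichment_p, m.enrichment_p)
            cur.coherence_p = min(cur.coherence_p, m.coherence_p)
            cur.source_pvalues.update(src_p)
            if not cur.name:
                cur.name = m.name
    return sorted(by_term.values(), key=FunctionalModule.sort_key)
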