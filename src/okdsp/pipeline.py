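"""End-to-end orchestration: summarize -> mbsec -> dag.

``run_all`` consumes an ontology, annotations and a binary
perturbation x gene matrix, summarizes each instance's responding genes
into functional modules, merges them across instances, mines a maximal
dense bipartite subgraph per merged module, organizes the perturbation
instances into a signaling-unit DAG, and writes all artifacts plus a
plain-text report.  Output JSON uses sorted keys and fixed float
formatting, so two runs with the same seed and config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

from . import io as okio
from .coherence import CoherenceScorer
from .dag_builder import SignalingUnitDAG, build_signaling_dag
from .mbsec import (
    BipartiteSubgraph,
    MbsecParams,
    PerturbationResponseMatrix,
    build_module_graph,
    interaction_ratio,
    mbsec_search,
)
from .module_mining import (
    FunctionalModule,
    SummarizationParams,
    merge_modules,
    summarize_instance,
)
from .ontology import (
    AnnotationSet,
    OntologyDAG,
    build_semantic_weights,
    load_obo,
    propagate_annotations,
)

log = logging.getLogger("okdsp")

__all__ = ["RunConfig", "PipelineResult", "run_all", "run_pipeline"]


@dataclass
class RunConfig:
    obo: str = ""
    annotations: str = ""
    matrix: str = ""
    interactions: str | None = None
    out_dir: str = "okdsp_out"
    namespace: str = "biological_process"
    annotation_format: str = "auto"
    matrix_threshold: float | None = None
    enrichment_alpha: float = 0.05
    coherence_alpha: float = 0.05
    min_module_genes: int = 3
    n_null: int = 1000
    alpha: float = 0.7
    min_size: int = 10
    min_side: int = 3
    mean_connectivity: bool = False
    k_min: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def merged_with_cli(self, **overrides) -> "RunConfig":
        """New config with non-None CLI overrides applied over file values."""
        vals = dataclasses.asdict(self)
        vals.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**vals)


@dataclass
class PipelineResult:
    modules: list[FunctionalModule]
    subgraphs: list[BipartiteSubgraph]
    dag: SignalingUnitDAG
    unassigned: set[str] = field(default_factory=set)
    unannotated: set[str] = field(default_factory=set)
    silent_instances: set[str] = field(default_factory=set)
    interaction_ratios: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    dag: OntologyDAG,
    ann: AnnotationSet,
    matrix: PerturbationResponseMatrix,
    config: RunConfig | None = None,
    interactions: set[frozenset[str]] | None = None,
) -> PipelineResult:
    """Library entry point on in-memory objects (no file I/O)."""
    config = config or RunConfig()
    weights = build_semantic_weights(dag, ann)
    params = SummarizationParams(
        enrichment_alpha=config.enrichment_alpha,
        coherence_alpha=config.coherence_alpha,
        min_module_genes=config.min_module_genes,
        n_null=config.n_null,
        seed=config.seed,
    )
    scorer = CoherenceScorer(dag, ann, weights, n_null=config.n_null, seed=config.seed)

    per_instance: list[FunctionalModule] = []
    unassigned: set[str] = set()
    unannotated: set[str] = set()
    silent: set[str] = set()
    for inst in matrix.instances:
        genes = matrix.responding_genes(inst)
        if not genes:
            silent.add(inst)
            continue
        if not any(ann.direct.get(g) for g in genes):
            unannotated |= genes
            continue
        res = summarize_instance(
            genes, dag, ann, weights, params, scorer=scorer, instance_id=inst
        )
        per_instance.extend(res.modules)
        unassigned |= res.unassigned
        unannotated |= res.unannotated
    merged = merge_modules(per_instance)
    log.info(
        "summarization: %d per-instance modules, %d merged; %d silent instances",
        len(per_instance), len(merged), len(silent),
    )

    mbsec_params = MbsecParams(
        alpha=config.alpha,
        min_size=config.min_size,
        min_side=config.min_side,
        mean_connectivity=config.mean_connectivity,
    )
    subgraphs: list[BipartiteSubgraph] = []
    for m in merged:
        graph = build_module_graph(matrix, m)
        if graph.is_empty:
            log.info("module %s has no calls; search skipped", m.summary_term)
            continue
        sub = mbsec_search(graph, mbsec_params)
        if sub is not None:
            sub.summary_term = m.summary_term
            sub.name = m.name
            subgraphs.append(sub)
    log.info("mbsec: %d dense subgraphs from %d module graphs", len(subgraphs), len(merged))

    sdag = build_signaling_dag(subgraphs, k_min=config.k_min)

    ratios: dict[str, float] = {}
    if interactions:
        for s in subgraphs:
            if len(s.right_module) >= 2:
                ratios[s.summary_term] = interaction_ratio(s.right_module, [tuple(p) for p in interactions])

    return PipelineResult(
        modules=merged,
        subgraphs=subgraphs,
        dag=sdag,
        unassigned=unassigned,
        unannotated=unannotated,
        silent_instances=silent,
        interaction_ratios=ratios,
    )


def run_all(config: RunConfig) -> PipelineResult:
    """File-based end-to-end run; writes all artifacts under out_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for path, what in [
        (config.obo, "ontology OBO"),
        (config.annotations, "annotations"),
        (config.matrix, "matrix"),
    ]:
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"{what} file not found: {path!r}")
    if config.interactions and not os.path.exists(config.interactions):
        raise FileNotFoundError(f"interactions file not found: {config.interactions!r}")

    dag = load_obo(config.obo, namespace=config.namespace)
    direct = okio.read_annotations(config.annotations, dag, fmt=config.annotation_format)
    ann = propagate_annotations(direct, dag)
    matrix = okio.read_matrix_tsv(config.matrix, threshold=config.matrix_threshold)
    interactions = (
        okio.read_interactions_tsv(config.interactions) if config.interactions else None
    )

    result = run_pipeline(dag, ann, matrix, config, interactions=interactions)

    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    okio.write_modules_json(result.modules, out("modules.json"))
    okio.write_modules_tsv(result.modules, out("modules.tsv"))
    okio.write_subgraphs_json(result.subgraphs, out("subgraphs.json"))
    okio.write_subgraph_edges_tsv(result.subgraphs, out("subgraph_edges.tsv"))
    okio.write_dag_json(result.dag, out("dag.json"))
    okio.write_dag_graphml(result.dag, out("dag.graphml"))
    okio.write_dag_dot(result.dag, out("dag.dot"))
    with open(out("report.txt"), "w") as fh:
        fh.write(f"functional modules: {len(result.modules)}\n")
        fh.write(f"dense subgraphs: {len(result.subgraphs)}\n")
        fh.write(f"signaling units: {len(result.dag.unit_nodes)}\n")
        fh.write(f"unit edges: {len(result.dag.unit_edges)}\n")
        fh.write(f"unassigned genes: {len(result.unassigned)}\n")
        fh.write(f"unannotated genes: {len(result.unannotated)}\n")
        fh.write(f"silent instances: {len(result.silent_instances)}\n")
        fh.write(f"excluded instances: {len(result.dag.excluded_instances)}\n")
        if result.interaction_ratios:
            mean_ratio = sum(result.interaction_ratios.values()) / len(
                result.interaction_ratios
            )
            fh.write(f"mean interaction ratio: {mean_ratio:.6g}\n")
    return result
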