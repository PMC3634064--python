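"""Readers and writers for the pipeline's plain-text formats.

Inputs: OBO ontologies (via :func:`okdsp.ontology.load_obo`), GAF 2.x or
2-column ``gene<TAB>term`` annotations, binary (or thresholded log-ratio)
perturbation x gene matrices, and ``geneA<TAB>geneB`` interaction lists.
Outputs: JSON records with sorted keys and 6-significant-digit floats (for
reproducible diffs), TSV flat views, GraphML and DOT renderings of the
signaling-unit DAG.
"""

from __future__ import annotations

import json
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .dag_builder import SignalingUnitDAG
from .mbsec import BipartiteSubgraph, PerturbationResponseMatrix
from .module_mining import FunctionalModule
from .ontology import OntologyDAG

log = logging.getLogger("okdsp")

__all__ = [
    "read_annotations",
    "read_matrix_tsv",
    "read_instance_gene_lists",
    "read_interactions_tsv",
    "write_modules_json",
    "read_modules_json",
    "write_modules_tsv",
    "write_subgraphs_json",
    "read_subgraphs_json",
    "write_subgraph_edges_tsv",
    "write_dag_json",
    "write_dag_graphml",
    "write_dag_dot",
    "dump_json",
]

_ASPECT_OF_NAMESPACE = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


def _sigfig(x: float, digits: int = 6) -> float:
    return float(f"{x:.{digits}g}")


def dump_json(obj, path: str) -> None:
    """JSON with sorted keys and stable float formatting."""

    def clean(o):
        if isinstance(o, dict):
            return {k: clean(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, (set, frozenset)):
            return [clean(v) for v in sorted(o)]
        if isinstance(o, (np.floating, float)):
            return _sigfig(float(o))
        if isinstance(o, np.integer):
            return int(o)
        return o

    with open(path, "w") as fh:
        json.dump(clean(obj), fh, sort_keys=True, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_annotations(
    path: str, dag: OntologyDAG, fmt: str = "auto"
) -> dict[str, set[str]]:
    """Gene -> direct term ids from GAF 2.x or 2-column TSV.

    GAF rows outside the DAG's namespace aspect, and annotations to terms
    absent from the loaded DAG (other namespaces, obsolete ids), are dropped
    with a logged count — never silently and never an error.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if fmt == "auto":
        body = [ln for ln in lines if not ln.startswith("!")]
        fmt = "gaf" if (
            any(ln.startswith("!gaf-version") for ln in lines)
            or (body and len(body[0].split("\t")) >= 15)
        ) else "tsv"
    aspect = _ASPECT_OF_NAMESPACE.get(dag.namespace, "P")
    direct: dict[str, set[str]] = {}
    dropped_ns = 0
    dropped_unknown = 0
    for ln in lines:
        if ln.startswith("!"):
            continue
        cols = ln.split("\t")
        if fmt == "gaf":
            if len(cols) < 9:
                raise ValueError(f"malformed GAF row: {ln[:80]!r}")
            gene, term, asp = cols[1], cols[4], cols[8]
            if asp != aspect:
                dropped_ns += 1
                continue
        else:
            if len(cols) < 2:
                raise ValueError(f"malformed 2-column annotation row: {ln[:80]!r}")
            gene, term = cols[0], cols[1]
        if term not in dag.terms:
            dropped_unknown += 1
            continue
        direct.setdefault(gene, set()).add(term)
    if dropped_ns or dropped_unknown:
        log.info(
            "annotations dropped: %d outside namespace aspect, %d to terms "
            "absent from the loaded ontology",
            dropped_ns,
            dropped_unknown,
        )
    return direct


def read_matrix_tsv(path: str, threshold: float | None = None) -> PerturbationResponseMatrix:
    """Binary matrix TSV: header of gene ids, first column instance ids.

    With ``threshold`` set, cells are treated as signed log-ratios and
    binarized as ``|x| >= threshold``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if threshold is not None:
        calls = (np.abs(values) >= threshold).astype(np.int8)
    else:
        calls = values.astype(np.int8)
    return PerturbationResponseMatrix(
        instances=[str(i) for i in df.index],
        genes=[str(c) for c in df.columns],
        calls=calls,
    )


def read_instance_gene_lists(path: str) -> dict[str, set[str]]:
    """Per-instance gene lists from ``instance<TAB>gene`` TSV."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            inst, gene = ln.split("\t")[:2]
            out.setdefault(inst, set()).add(gene)
    return out


def read_interactions_tsv(path: str) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            a, b = ln.split("\t")[:2]
            if a != b:
                pairs.add(frozenset((a, b)))
    return pairs


# ---------------------------------------------------------------------------
# module / subgraph serialization
# ---------------------------------------------------------------------------


def write_modules_json(modules: list[FunctionalModule], path: str) -> None:
    records = [
        {
            "summary_term": m.summary_term,
            "name": m.name,
            "genes": sorted(m.genes),
            "enrichment_p": m.enrichment_p,
            "coherence_p": m.coherence_p,
            "source_instances": sorted(m.source_instances),
        }
        for m in modules
    ]
    dump_json(records, path)


def read_modules_json(path: str) -> list[FunctionalModule]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        FunctionalModule(
            summary_term=r["summary_term"],
            genes=set(r["genes"]),
            enrichment_p=float(r["enrichment_p"]),
            coherence_p=float(r["coherence_p"]),
            source_instances=set(r.get("source_instances", [])),
            name=r.get("name", ""),
        )
        for r in records
    ]


def write_modules_tsv(modules: list[FunctionalModule], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("summary_term\tname\tn_genes\tenrichment_p\tcoherence_p\tgenes\n")
        for m in modules:
            fh.write(
                f"{m.summary_term}\t{m.name}\t{len(m.genes)}\t"
                f"{_sigfig(m.enrichment_p)}\t{_sigfig(m.coherence_p)}\t"
                f"{','.join(sorted(m.genes))}\n"
            )


def write_subgraphs_json(subgraphs: list[BipartiteSubgraph], path: str) -> None:
    records = [
        {
            "summary_term": s.summary_term,
            "name": s.name,
            "perturbation_module": sorted(s.left_module),
            "responding_module": sorted(s.right_module),
            "connectivity": s.connectivity,
            "alpha": s.alpha,
            "edges": sorted([list(e) for e in s.edges]),
        }
        for s in subgraphs
    ]
    dump_json(records, path)


def read_subgraphs_json(path: str) -> list[BipartiteSubgraph]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        BipartiteSubgraph(
            left_module=set(r["perturbation_module"]),
            right_module=set(r["responding_module"]),
            edges={(u, v) for u, v in r.get("edges", [])},
            alpha=float(r["alpha"]),
            connectivity=float(r["connectivity"]),
            summary_term=r.get("summary_term"),
            name=r.get("name", ""),
        )
        for r in records
    ]


def write_subgraph_edges_tsv(subgraphs: list[BipartiteSubgraph], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("summary_term\tinstance\tgene\n")
        for s in subgraphs:
            for u, v in sorted(s.edges):
                fh.write(f"{s.summary_term}\t{u}\t{v}\n")


# ---------------------------------------------------------------------------
# DAG serialization
# ---------------------------------------------------------------------------


def write_dag_json(dag: SignalingUnitDAG, path: str) -> None:
    dump_json(
        {
            "unit_nodes": {u: sorted(g) for u, g in dag.unit_nodes.items()},
            "signals": {u: sorted(s) for u, s in dag.signals.items()},
            "rm_nodes": sorted(dag.rm_nodes),
            "rm_names": dict(dag.rm_names),
            "unit_edges": sorted([list(e) for e in dag.unit_edges]),
            "rm_edges": sorted([list(e) for e in dag.rm_edges]),
            "excluded_instances": sorted(dag.excluded_instances),
        },
        path,
    )


def _labeled_graph(dag: SignalingUnitDAG) -> nx.DiGraph:
    g = nx.DiGraph()
    for u, insts in sorted(dag.unit_nodes.items()):
        g.add_node(u, kind="unit", label=",".join(sorted(insts)))
    for r in sorted(dag.rm_nodes):
        name = dag.rm_names.get(r, "")
        g.add_node(r, kind="rm", label=f"{r} {name}".strip())
    g.add_edges_from(sorted(dag.unit_edges))
    g.add_edges_from(sorted(dag.rm_edges))
    return g


def write_dag_graphml(dag: SignalingUnitDAG, path: str) -> None:
    nx.write_graphml(_labeled_graph(dag), path)


def write_dag_dot(dag: SignalingUnitDAG, path: str) -> None:
    """Minimal hand-rolled DOT serialization (box units, ellipse modules)."""
    g = _labeled_graph(dag)
    with open(path, "w") as fh:
        fh.write("digraph signaling_units {\n")
        fh.write("  rankdir=TB;\n")
        for n, d in sorted(g.nodes(data=True)):
            shape = "box" if d.get("kind") == "unit" else "ellipse"
            label = d.get("label", n).replace('"', "'")
            fh.write(f'  "{n}" [shape={shape}, label="{label}"];\n')
        for u, v in sorted(g.edges()):
            fh.write(f'  "{u}" -> "{v}";\n')
        fh.write("}\n")
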