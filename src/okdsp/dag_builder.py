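"""Organize perturbation instances and responding modules into a DAG.

Perturbation instances that affect an identical set of responding modules
(signal set) are grouped into one signaling-unit node.  A directed edge
u -> v between units means the signals of u strictly subsume those of v
(S(u) ⊋ S(v)); the edge set is transitively reduced.  Each responding
module is attached to the highest unit that carries it and is not already
reachable through a child, which makes the set of responding modules
reachable from a unit exactly equal to its signal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .mbsec import BipartiteSubgraph

__all__ = [
    "SignalingUnitDAG",
    "build_signaling_dag",
    "reachable_signals",
]


@dataclass
class SignalingUnitDAG:
    unit_nodes: dict[str, set[str]]  # unit-id -> perturbation instances
    signals: dict[str, set[str]]  # unit-id -> responding-module term ids S(u)
    rm_nodes: set[str]
    unit_edges: set[tuple[str, str]]  # parent unit -> child unit
    rm_edges: set[tuple[str, str]]  # unit -> responding-module term
    excluded_instances: set[str] = field(default_factory=set)
    rm_names: dict[str, str] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.unit_nodes

    def graph(self) -> nx.DiGraph:
        """Full directed graph over unit and responding-module nodes."""
        g = nx.DiGraph()
        for u in self.unit_nodes:
            g.add_node(u, kind="unit")
        for r in self.rm_nodes:
            g.add_node(r, kind="rm")
        g.add_edges_from(self.unit_edges)
        g.add_edges_from(self.rm_edges)
        return g


def build_signaling_dag(
    subgraphs: list[BipartiteSubgraph], k_min: int = 2
) -> SignalingUnitDAG:
    """Group instances by identical signal sets and wire subsumption edges.

    Steps: (1) drop perturbation modules with fewer than ``k_min``
    instances; (2) each retained instance's signal set is the summary terms
    of all retained subgraphs whose perturbation module contains it;
    (3) instances with identical signal sets become one unit node;
    (4) unit edge u -> v iff S(u) ⊋ S(v), transitively reduced;
    (5) responding-module edge u -> r iff r ∈ S(u) and no child of u
    carries r.  Instances in no retained module are excluded and listed.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    retained = [
        s for s in subgraphs if len(s.left_module) >= k_min and s.summary_term
    ]
    all_instances: set[str] = set()
    for s in subgraphs:
        all_instances |= s.left_module

    signal_of: dict[str, set[str]] = {}
    rm_names: dict[str, str] = {}
    for s in retained:
        rm_names.setdefault(s.summary_term, s.name)
        for inst in s.left_module:
            signal_of.setdefault(inst, set()).add(s.summary_term)

    excluded = all_instances - set(signal_of)
    if not signal_of:
        return SignalingUnitDAG(
            unit_nodes={}, signals={}, rm_nodes=set(), unit_edges=set(),
            rm_edges=set(), excluded_instances=excluded,
        )

    groups: dict[frozenset[str], set[str]] = {}
    for inst, sig in signal_of.items():
        groups.setdefault(frozenset(sig), set()).add(inst)
    # stable unit ids: order groups by (-|signals|, sorted signal tuple)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[0]), tuple(sorted(kv[0]))))
    unit_nodes: dict[str, set[str]] = {}
    signals: dict[str, set[str]] = {}
    for idx, (sig, insts) in enumerate(ordered):
        uid = f"U{idx:03d}"
        unit_nodes[uid] = set(insts)
        signals[uid] = set(sig)

    g = nx.DiGraph()
    g.add_nodes_from(unit_nodes)
    for u in unit_nodes:
        for v in unit_nodes:
            if u != v and signals[u] > signals[v]:
                g.add_edge(u, v)
    reduced = nx.transitive_reduction(g)
    unit_edges = set(reduced.edges())

    rm_edges: set[tuple[str, str]] = set()
    rm_nodes: set[str] = set()
    children = {u: {v for _, v in reduced.out_edges(u)} for u in unit_nodes}
    for u in unit_nodes:
        inherited: set[str] = set()
        for c in children[u]:
            inherited |= signals[c]
        for r in signals[u] - inherited:
            rm_edges.add((u, r))
            rm_nodes.add(r)
    rm_nodes |= {r for s in signals.values() for r in s}

    return SignalingUnitDAG(
        unit_nodes=unit_nodes,
        signals=signals,
        rm_nodes=rm_nodes,
        unit_edges=unit_edges,
        rm_edges=rm_edges,
        excluded_instances=excluded,
        rm_names={r: rm_names.get(r, "") for r in rm_nodes},
    )


def reachable_signals(dag: SignalingUnitDAG, unit: str) -> set[str]:
    """Responding-module nodes reachable from ``unit`` via directed paths."""
    if unit not in dag.unit_nodes:
        raise KeyError(f"unknown unit {unit!r}")
    g = dag.graph()
    return {n for n in nx.descendants(g, unit) if n in dag.rm_nodes}
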