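"""Self-contained synthetic fixtures for the whole pipeline.

Two generators: a random is-a ontology with leaf-level gene annotations
(Zipf-like term popularity, optional multi-parent edges), and a binary
perturbation x gene response matrix with planted dense blocks whose gene
sides are coherent under the ontology, plus optional nested signal
structure (instances perturbing an upstream signal also receive the
downstream signal's block edges — the subsumption pattern the DAG builder
is meant to recover).

Everything is deterministic for a fixed seed.  Scales are desk-sized by
default: 400 genes, 60 instances, a depth-4 branching-3 ontology — big
enough for non-trivial structure, generated in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mbsec import PerturbationResponseMatrix
from .ontology import AnnotationSet, OntologyDAG, propagate_annotations

__all__ = [
    "PlantedSignal",
    "SyntheticSpec",
    "GroundTruth",
    "generate_ontology_and_annotations",
    "generate_matrix",
    "nested_demo_spec",
    "apply_planted_annotations",
    "write_obo",
    "write_annotations_tsv",
    "write_matrix_tsv",
]


@dataclass
class PlantedSignal:
    """One planted block: a signal term, its instances and its genes."""

    term: str
    instances: list[str]
    genes: list[str]
    p_in: float = 1.0


@dataclass
class SyntheticSpec:
    n_genes: int = 400
    n_instances: int = 60
    ontology_depth: int = 4
    branching: int = 3
    multi_parent_frac: float = 0.1
    annotations_per_gene: tuple[int, int] = (1, 3)
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    #: (parent index, child index) pairs over planted_signals: the parent
    #: signal's instances also receive the child signal's block edges
    nested_structure: list[tuple[int, int]] = field(default_factory=list)
    background_p: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ontology_depth < 2 or self.branching < 2:
            raise ValueError("need ontology_depth >= 2 and branching >= 2")
        for s in self.planted_signals:
            if not (0 <= self.background_p < s.p_in <= 1):
                raise ValueError(
                    "need 0 <= background_p < p_in <= 1 for every planted signal"
                )

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def instance_ids(self) -> list[str]:
        return [f"pert{i:03d}" for i in range(self.n_instances)]


@dataclass
class GroundTruth:
    """Planted blocks and the signaling-unit structure they imply."""

    blocks: list[PlantedSignal]
    #: frozenset of signal terms -> set of instance ids (only instances in
    #: at least one block)
    unit_partition: dict[frozenset[str], set[str]]
    #: strict-subsumption edges between distinct signal sets, transitively
    #: reduced
    subsumption_edges: set[tuple[frozenset[str], frozenset[str]]]


def _tree_terms(depth: int, branching: int) -> tuple[list[str], dict[str, set[str]]]:
    terms = ["T0"]
    is_a: dict[str, set[str]] = {"T0": set()}
    level = ["T0"]
    counter = 1
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                t = f"T{counter}"
                counter += 1
                terms.append(t)
                is_a[t] = {parent}
                nxt.append(t)
        level = nxt
    return terms, is_a


def generate_ontology_and_annotations(
    spec: SyntheticSpec,
) -> tuple[OntologyDAG, AnnotationSet]:
    """Balanced is-a tree plus optional extra multi-parent edges, and gene
    annotations on leaves with Zipf-like popularity."""
    rng = np.random.default_rng([spec.seed, 1])
    terms, is_a = _tree_terms(spec.ontology_depth, spec.branching)
    depth_of: dict[str, int] = {"T0": 0}
    for t in terms[1:]:
        parent = next(iter(is_a[t]))
        depth_of[t] = depth_of[parent] + 1
    leaves = [t for t in terms if depth_of[t] == spec.ontology_depth]
    planted_terms = {s.term for s in spec.planted_signals}
    if len(planted_terms) > len(leaves):
        raise ValueError("more planted terms than ontology leaves")

    if spec.multi_parent_frac > 0:
        non_root = [t for t in terms if depth_of[t] >= 2]
        n_extra = int(round(spec.multi_parent_frac * len(non_root)))
        for t in rng.choice(len(non_root), size=n_extra, replace=False):
            child = non_root[int(t)]
            shallower = [
                u
                for u in terms
                if depth_of[u] < depth_of[child] and u not in is_a[child] and u != "T0"
            ]
            if shallower:
                extra = shallower[int(rng.integers(len(shallower)))]
                is_a[child] = is_a[child] | {extra}

    dag = OntologyDAG(
        terms=set(terms),
        name={t: f"synthetic term {t}" for t in terms},
        is_a=is_a,
        namespace_root="T0",
    )

    # Zipf-like leaf popularity: weight 1/rank over a random leaf order
    perm = rng.permutation(len(leaves))
    weights = np.array([1.0 / (r + 1) for r in range(len(leaves))])
    w = np.empty(len(leaves))
    w[perm] = weights
    w /= w.sum()
    lo, hi = spec.annotations_per_gene
    direct: dict[str, set[str]] = {}
    for g in spec.gene_ids():
        k = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False, p=w)
        direct[g] = {leaves[int(i)] for i in picks}
    return dag, propagate_annotations(direct, dag)


def _closure_signals(spec: SyntheticSpec) -> dict[int, set[int]]:
    """For each planted-signal index, itself plus all nested descendants."""
    children: dict[int, set[int]] = {i: set() for i in range(len(spec.planted_signals))}
    for p, c in spec.nested_structure:
        children[p].add(c)
    out: dict[int, set[int]] = {}

    def descend(i: int, seen: set[int]) -> set[int]:
        if i in out:
            return out[i]
        if i in seen:
            raise ValueError("nested_structure contains a cycle")
        acc = {i}
        for c in children[i]:
            acc |= descend(c, seen | {i})
        out[i] = acc
        return acc

    for i in children:
        descend(i, set())
    return out


def generate_matrix(
    spec: SyntheticSpec, dag: OntologyDAG, ann: AnnotationSet
) -> tuple[PerturbationResponseMatrix, GroundTruth]:
    """Bernoulli block model over planted signals plus uniform background.

    Inside a planted block (signal instances x signal genes) calls are
    Bernoulli(p_in); elsewhere Bernoulli(background_p).  With nesting, an
    upstream signal's instances also draw the downstream blocks.  The
    ground truth records the blocks and the implied unit partition and
    subsumption edges over effective signal-term sets.
    """
    rng = np.random.default_rng([spec.seed, 2])
    instances = spec.instance_ids()
    genes = spec.gene_ids()
    iidx = {x: i for i, x in enumerate(instances)}
    gidx = {x: j for j, x in enumerate(genes)}
    for s in spec.planted_signals:
        unknown_i = [i for i in s.instances if i not in iidx]
        unknown_g = [g for g in s.genes if g not in gidx]
        if unknown_i or unknown_g:
            raise ValueError(
                f"planted signal {s.term}: ids outside spec ranges "
                f"{unknown_i + unknown_g}"
            )

    closure = _closure_signals(spec)
    # effective block membership per instance: own signal plus nested children
    eff_signals: dict[str, set[int]] = {}
    for si, s in enumerate(spec.planted_signals):
        for inst in s.instances:
            eff_signals.setdefault(inst, set()).update(closure[si])

    p = np.full((len(instances), len(genes)), spec.background_p)
    for inst, sig_idxs in eff_signals.items():
        for si in sig_idxs:
            s = spec.planted_signals[si]
            rows = iidx[inst]
            cols = [gidx[g] for g in s.genes]
            cur = p[rows, cols]
            conflict = (cur > spec.background_p) & (cur != s.p_in)
            if conflict.any():
                raise ValueError(
                    f"overlapping blocks with contradictory p_in at instance {inst}"
                )
            p[rows, cols] = s.p_in
    calls = (rng.random(p.shape) < p).astype(np.int8)
    matrix = PerturbationResponseMatrix(
        instances=instances, genes=genes, calls=calls
    )

    partition: dict[frozenset[str], set[str]] = {}
    for inst, sig_idxs in eff_signals.items():
        key = frozenset(spec.planted_signals[si].term for si in sig_idxs)
        partition.setdefault(key, set()).add(inst)
    keys = list(partition)
    edges = {
        (a, b) for a in keys for b in keys if a > b  # strict superset
    }
    # transitive reduction over the subsumption relation
    reduced = {
        (a, b)
        for (a, b) in edges
        if not any(a > c > b for c in keys)
    }
    truth = GroundTruth(
        blocks=list(spec.planted_signals),
        unit_partition=partition,
        subsumption_edges=reduced,
    )
    return matrix, truth


def nested_demo_spec(seed: int = 0, background_p: float = 0.0) -> SyntheticSpec:
    """A small nested two-signal compendium used by tests and examples.

    Signal A (upstream, 3 instances) subsumes signal B (downstream, 3
    instances): A's instances light up both blocks.  Each signal's genes are
    spread two-per-leaf over the four leaf children of one depth-2 term of a
    depth-3, branching-4 ontology, so summarization recovers exactly the two
    planted terms.
    """
    depth, branching = 3, 4
    spec = SyntheticSpec(
        n_genes=120,
        n_instances=12,
        ontology_depth=depth,
        branching=branching,
        multi_parent_frac=0.0,
        annotations_per_gene=(1, 2),
        background_p=background_p,
        seed=seed,
    )
    # term layout of the balanced tree: level sizes 1, 4, 16, 64
    # depth-2 terms are T5..T20; leaf children of depth-2 term k sit at
    # positions 21 + 4*(k-5) .. 21 + 4*(k-5) + 3
    term_a, term_b = "T5", "T10"

    def leaf_children(term_idx: int) -> list[str]:
        base = 21 + 4 * (term_idx - 5)
        return [f"T{base + i}" for i in range(4)]

    genes = spec.gene_ids()
    genes_a = genes[:8]
    genes_b = genes[8:16]
    spec.planted_signals = [
        PlantedSignal(term=term_a, instances=[f"pert{i:03d}" for i in range(3)],
                      genes=genes_a, p_in=1.0),
        PlantedSignal(term=term_b, instances=[f"pert{i:03d}" for i in range(3, 6)],
                      genes=genes_b, p_in=1.0),
    ]
    spec.nested_structure = [(0, 1)]  # A upstream of B
    spec._planted_leaf_annotations = {  # type: ignore[attr-defined]
        term_a: (genes_a, leaf_children(5)),
        term_b: (genes_b, leaf_children(10)),
    }
    return spec


def apply_planted_annotations(
    spec: SyntheticSpec, dag: OntologyDAG, ann: AnnotationSet
) -> AnnotationSet:
    """Re-annotate planted genes two-per-leaf under their signal terms.

    Used with :func:`nested_demo_spec`: keeps block gene sets exactly
    recoverable as single summary terms (no leaf ever holds enough genes to
    freeze below the planted term).
    """
    planted = getattr(spec, "_planted_leaf_annotations", None)
    if not planted:
        return ann
    direct = {g: set(ts) for g, ts in ann.direct.items()}
    for _, (genes, leaves) in planted.items():
        for i, g in enumerate(genes):
            direct[g] = {leaves[i % len(leaves)]}
    return propagate_annotations(direct, dag)


# ---------------------------------------------------------------------------
# plain-text writers (round-trip partners of the io readers)
# ---------------------------------------------------------------------------


def write_obo(dag: OntologyDAG, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"default-namespace: {dag.namespace}\n\n")
        for t in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.name.get(t, t)}\n")
            fh.write(f"namespace: {dag.namespace}\n")
            for p in sorted(dag.is_a.get(t, ())):
                fh.write(f"is_a: {p} ! {dag.name.get(p, p)}\n")
            fh.write("\n")


def write_annotations_tsv(ann: AnnotationSet, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(ann.direct):
            for t in sorted(ann.direct[g]):
                fh.write(f"{g}\t{t}\n")


def write_matrix_tsv(matrix: PerturbationResponseMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("instance\t" + "\t".join(matrix.genes) + "\n")
        for i, inst in enumerate(matrix.instances):
            row = "\t".join(str(int(v)) for v in matrix.calls[i])
            fh.write(f"{inst}\t{row}\n")
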