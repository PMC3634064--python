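"""Maximal bipartite subgraph with expected connectivity (MBSEC).

Given a functional-module-based bipartite graph — perturbation instances on
one side, the module's responding genes on the other, an edge meaning the
gene was differentially expressed under the instance — find the largest
subgraph in which every vertex connects to at least a fraction ``alpha`` of
the opposite side (per-vertex quota ``ceil(alpha * |opposite|)``).  The
objective, maximizing ``|left| + |right|`` under the per-vertex constraint,
is NP-hard (a quasi-biclique problem); the solver is a greedy peeling that
repeatedly deletes the vertex with the smallest degree ratio until the
constraint holds, and an exact brute-force oracle is provided for small
instances.

``connectivity`` and ``interaction_ratio`` are the two evaluation metrics:
fraction of possible edges realized inside a subgraph, and fraction of
module gene pairs with a known interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .module_mining import FunctionalModule

__all__ = [
    "PerturbationResponseMatrix",
    "BipartiteGraph",
    "BipartiteSubgraph",
    "MbsecParams",
    "OracleSizeError",
    "build_module_graph",
    "mbsec_search",
    "brute_force_oracle",
    "check_feasible",
    "connectivity",
    "interaction_ratio",
]


class OracleSizeError(ValueError):
    """Brute-force oracle refused: instance too large to enumerate."""


@dataclass
class PerturbationResponseMatrix:
    """Binary instances x genes differential-expression calls."""

    instances: list[str]
    genes: list[str]
    calls: np.ndarray  # shape (n_instances, n_genes), dtype int, entries 0/1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.instances), len(self.genes)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.instances)} instances x {len(self.genes)} genes"
            )
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be binary")
        if len(set(self.instances)) != len(self.instances):
            raise ValueError("duplicate instance ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")

    def responding_genes(self, instance: str) -> set[str]:
        i = self.instances.index(instance)
        return {g for g, v in zip(self.genes, self.calls[i]) if v}


@dataclass
class BipartiteGraph:
    left: set[str]
    right: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        bad = [e for e in self.edges if e[0] not in self.left or e[1] not in self.right]
        if bad:
            raise ValueError(f"edges outside left x right: {sorted(bad)[:3]}")

    @property
    def is_empty(self) -> bool:
        return not self.edges


@dataclass
class BipartiteSubgraph:
    left_module: set[str]
    right_module: set[str]
    edges: set[tuple[str, str]]
    alpha: float
    connectivity: float
    summary_term: str | None = None
    name: str = ""


@dataclass
class MbsecParams:
    alpha: float = 0.7
    min_size: int = 10  # minimum |left| + |right|
    min_side: int = 3
    mean_connectivity: bool = False  # relax per-vertex quota to the average form

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")


def build_module_graph(
    matrix: PerturbationResponseMatrix, module: FunctionalModule
) -> BipartiteGraph:
    """Functional-module-based bipartite graph for one responding module.

    Right side: the module's genes.  Left side: every instance with at least
    one call among them.  A module gene absent from the matrix violates the
    contract and is reported by name.
    """
    missing = sorted(set(module.genes) - set(matrix.genes))
    if missing:
        raise ValueError(f"module genes absent from matrix: {missing}")
    cols = [matrix.genes.index(g) for g in sorted(module.genes)]
    sub = matrix.calls[:, cols]
    edges = {
        (matrix.instances[i], matrix.genes[cols[j]])
        for i, j in zip(*np.nonzero(sub))
    }
    left = {i for i, _ in edges}
    return BipartiteGraph(left=left, right=set(module.genes), edges=edges)


def _quota(alpha: float, n_opposite: int) -> int:
    # "at least alpha * |opposite|" with ceiling semantics
    return math.ceil(alpha * n_opposite - 1e-9)


def check_feasible(sub: BipartiteSubgraph, params: MbsecParams) -> bool:
    """Independent constraint checker used by tests and the search itself."""
    L, R = sub.left_module, sub.right_module
    if not L or not R:
        return False
    if len(L) + len(R) < params.min_size:
        return False
    if len(L) < params.min_side or len(R) < params.min_side:
        return False
    deg_l = {u: 0 for u in L}
    deg_r = {v: 0 for v in R}
    for u, v in sub.edges:
        if u not in L or v not in R:
            return False
        deg_l[u] += 1
        deg_r[v] += 1
    if params.mean_connectivity:
        return len(sub.edges) >= params.alpha * len(L) * len(R) - 1e-9
    ql, qr = _quota(params.alpha, len(R)), _quota(params.alpha, len(L))
    return all(d >= ql for d in deg_l.values()) and all(d >= qr for d in deg_r.values())


def _constraints_hold(
    L: list[str], R: list[str], deg: dict[str, int], alpha: float,
    mean_form: bool, n_edges: int,
) -> bool:
    if not L or not R:
        return False
    if mean_form:
        return n_edges >= alpha * len(L) * len(R) - 1e-9
    ql, qr = _quota(alpha, len(R)), _quota(alpha, len(L))
    return all(deg[u] >= ql for u in L) and all(deg[v] >= qr for v in R)


def mbsec_search(
    graph: BipartiteGraph, params: MbsecParams | None = None
) -> BipartiteSubgraph | None:
    """Greedy peeling for the MBSEC objective.

    Repeatedly delete the vertex with the smallest degree ratio
    (degree / size of the opposite side; ties broken lexicographically, left
    side first) until every remaining vertex meets its alpha quota or a side
    empties.  Since each deletion shrinks the size by one, the first feasible
    state encountered maximizes ``|left| + |right|`` among all feasible
    states on the peeling trajectory.  Returns ``None`` when the best
    feasible state misses ``min_size`` or ``min_side``.
    """
    params = params or MbsecParams()
    if graph.is_empty:
        return None
    L = set(graph.left)
    R = set(graph.right)
    adj: dict[str, set[str]] = {u: set() for u in L | R}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    deg = {x: len(adj[x]) for x in adj}

    while L and R:
        if _constraints_hold(
            sorted(L), sorted(R), deg, params.alpha, params.mean_connectivity,
            sum(deg[u] for u in L),
        ):
            edges = {(u, v) for u in L for v in adj[u] if v in R}
            sub = BipartiteSubgraph(
                left_module=set(L),
                right_module=set(R),
                edges=edges,
                alpha=params.alpha,
                connectivity=len(edges) / (len(L) * len(R)),
            )
            if check_feasible(sub, params):
                return sub
            return None
        # peel the vertex with the smallest degree ratio
        cand = [(deg[u] / len(R), 0, u) for u in L] + [
            (deg[v] / len(L), 1, v) for v in R
        ]
        _, side, worst = min(cand)
        (L if side == 0 else R).discard(worst)
        for nb in adj[worst]:
            adj[nb].discard(worst)
            deg[nb] -= 1
        adj.pop(worst)
        deg.pop(worst)
    return None


def _popcounts(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x.astype(np.uint64))


def brute_force_oracle(
    graph: BipartiteGraph, params: MbsecParams | None = None
) -> BipartiteSubgraph | None:
    """Exact maximizer of ``|left| + |right|`` under the per-vertex quota.

    Enumerates subsets of the smaller side as bitmasks; for each fixed left
    set the right-feasible candidate pool is pruned first, then right
    subsets of the pool are scanned with vectorized popcounts.  Refuses
    instances with more than 24 vertices in total.  Ties are resolved
    exactly as in :func:`mbsec_search`: higher connectivity, then
    lexicographically smallest (left, right) vertex sets.
    """
    params = params or MbsecParams()
    if params.mean_connectivity:
        raise NotImplementedError("oracle implements the per-vertex form only")
    n_total = len(graph.left) + len(graph.right)
    if n_total > 24:
        raise OracleSizeError(f"{n_total} vertices exceed the 24-vertex oracle guard")
    if graph.is_empty:
        return None

    swap = len(graph.left) > len(graph.right)
    A = sorted(graph.right if swap else graph.left)  # enumerated side
    B = sorted(graph.left if swap else graph.right)
    nA, nB = len(A), len(B)
    # neighborhood bitmasks over B for each a in A, and over A for each b
    nb_of_a = np.zeros(nA, dtype=np.uint64)
    nb_of_b = np.zeros(nB, dtype=np.uint64)
    bidx = {b: j for j, b in enumerate(B)}
    aidx = {a: i for i, a in enumerate(A)}
    for u, v in graph.edges:
        a, b = (v, u) if swap else (u, v)
        nb_of_a[aidx[a]] |= np.uint64(1 << bidx[b])
        nb_of_b[bidx[b]] |= np.uint64(1 << aidx[a])

    all_b_masks = np.arange(1, 1 << nB, dtype=np.uint64)
    b_sizes = _popcounts(all_b_masks)

    best: tuple[int, float, list[str], list[str]] | None = None
    best_sub: BipartiteSubgraph | None = None

    for a_mask in range(1, 1 << nA):
        a_members = [i for i in range(nA) if a_mask >> i & 1]
        ka = len(a_members)
        qa = _quota(params.alpha, ka)  # quota for B vertices, given |A-side| = ka
        # candidate pool: b vertices with enough neighbors inside the A set
        pool_ok = _popcounts(nb_of_b & np.uint64(a_mask)) >= qa
        pool = np.uint64(0)
        for j in np.nonzero(pool_ok)[0]:
            pool |= np.uint64(1 << int(j))
        if pool == 0:
            continue
        sel = (all_b_masks & ~pool) == 0
        masks = all_b_masks[sel]
        if masks.size == 0:
            continue
        sizes = b_sizes[sel]
        # A-side quota depends on |B set|: ceil(alpha * kb)
        quotas = np.ceil(params.alpha * sizes.astype(np.float64) - 1e-9).astype(np.int64)
        ok = np.ones(masks.shape, dtype=bool)
        for i in a_members:
            ok &= _popcounts(masks & nb_of_a[i]).astype(np.int64) >= quotas
        if not ok.any():
            continue
        masks, sizes = masks[ok], sizes[ok]
        order = np.argsort(sizes)[::-1]
        for idx in order:
            kb = int(sizes[idx])
            size = ka + kb
            if best is not None and size < best[0]:
                break
            b_members = [j for j in range(nB) if int(masks[idx]) >> j & 1]
            a_names = [A[i] for i in a_members]
            b_names = [B[j] for j in b_members]
            left_names = sorted(b_names if swap else a_names)
            right_names = sorted(a_names if swap else b_names)
            if len(left_names) < params.min_side or len(right_names) < params.min_side:
                continue
            if size < params.min_size:
                continue
            n_edges = int(_popcounts(nb_of_a[a_members] & masks[idx]).sum())
            conn = n_edges / (ka * kb)
            if (
                best is None
                or size > best[0]
                or (size == best[0] and conn > best[1])
                or (
                    size == best[0]
                    and conn == best[1]
                    and (left_names, right_names) < (best[2], best[3])
                )
            ):
                best = (size, conn, left_names, right_names)
                edges = {
                    (u, v)
                    for (u, v) in graph.edges
                    if u in set(left_names) and v in set(right_names)
                }
                best_sub = BipartiteSubgraph(
                    left_module=set(left_names),
                    right_module=set(right_names),
                    edges=edges,
                    alpha=params.alpha,
                    connectivity=conn,
                )
    return best_sub


def connectivity(sub: BipartiteSubgraph) -> float:
    """Fraction of possible edges realized: |E| / (|left| * |right|)."""
    m, n = len(sub.left_module), len(sub.right_module)
    if m == 0 or n == 0:
        raise ValueError("connectivity undefined for an empty side")
    return len(sub.edges) / (m * n)


def interaction_ratio(
    module_genes: Iterable[str], interactions: Iterable[Sequence[str]]
) -> float:
    """Fraction of module gene pairs with a known interaction.

    ``interactions`` is a collection of unordered gene pairs; self-pairs are
    ignored and duplicates counted once.
    """
    genes = set(module_genes)
    q = len(genes)
    if q < 2:
        raise ValueError("interaction ratio undefined for fewer than 2 genes")
    seen: set[frozenset[str]] = set()
    for pair in interactions:
        a, b = pair[0], pair[1]
        if a == b:
            continue
        if a in genes and b in genes:
            seen.add(frozenset((a, b)))
    return len(seen) / (q * (q - 1) // 2)
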