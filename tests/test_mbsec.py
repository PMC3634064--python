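"""Bipartite graph construction, greedy MBSEC search, exact oracle, metrics."""

import numpy as np
import pytest

from okdsp.mbsec import (
    BipartiteGraph,
    BipartiteSubgraph,
    MbsecParams,
    OracleSizeError,
    PerturbationResponseMatrix,
    brute_force_oracle,
    build_module_graph,
    check_feasible,
    connectivity,
    interaction_ratio,
    mbsec_search,
)
from okdsp.module_mining import FunctionalModule


def module(genes):
    return FunctionalModule(
        summary_term="T1", genes=set(genes), enrichment_p=0.01, coherence_p=0.01
    )


def random_graph(rng, nl, nr, p, block=None):
    L = [f"i{x}" for x in range(nl)]
    R = [f"g{x}" for x in range(nr)]
    edges = set()
    for u in L:
        for v in R:
            if rng.random() < p:
                edges.add((u, v))
    if block:
        bl, br = block
        for u in L[:bl]:
            for v in R[:br]:
                edges.add((u, v))
    return BipartiteGraph(set(L), set(R), edges)


class TestBuildModuleGraph:
    def test_single_call(self):
        m = PerturbationResponseMatrix(
            instances=["i1", "i2"], genes=["g1", "g2"],
            calls=np.array([[1, 0], [0, 0]]),
        )
        g = build_module_graph(m, module(["g1", "g2"]))
        assert g.left == {"i1"}
        assert g.right == {"g1", "g2"}
        assert g.edges == {("i1", "g1")}

    def test_missing_gene_named(self):
        m = PerturbationResponseMatrix(
            instances=["i1"], genes=["g1"], calls=np.array([[1]])
        )
        with pytest.raises(ValueError, match="gX"):
            build_module_graph(m, module(["g1", "gX"]))

    def test_all_ones_complete(self):
        m = PerturbationResponseMatrix(
            instances=["i1", "i2", "i3"], genes=list("abcd"),
            calls=np.ones((3, 4), dtype=int),
        )
        g = build_module_graph(m, module("abcd"))
        assert len(g.edges) == 12

    def test_no_calls_sentinel(self):
        m = PerturbationResponseMatrix(
            instances=["i1"], genes=["g1"], calls=np.array([[0]])
        )
        g = build_module_graph(m, module(["g1"]))
        assert g.is_empty


class TestMbsecSearch:
    def test_complete_graph_returned_whole(self):
        g = random_graph(np.random.default_rng(0), 4, 5, 0.0, block=(4, 5))
        sub = mbsec_search(g, MbsecParams(alpha=0.7, min_size=6, min_side=2))
        assert sub is not None
        assert sub.left_module == g.left and sub.right_module == g.right
        assert sub.connectivity == 1.0

    def test_edgeless_none(self):
        g = BipartiteGraph({"i1"}, {"g1"}, set())
        assert mbsec_search(g, MbsecParams()) is None

    def test_planted_block_matches_oracle(self):
        rng = np.random.default_rng(42)
        g = random_graph(rng, 6, 8, 0.1, block=(4, 5))
        params = MbsecParams(alpha=0.8, min_size=6, min_side=2)
        greedy = mbsec_search(g, params)
        exact = brute_force_oracle(g, params)
        assert greedy is not None and exact is not None
        assert greedy.left_module == exact.left_module
        assert greedy.right_module == exact.right_module

    def test_feasibility_of_every_return(self):
        rng = np.random.default_rng(1)
        params = MbsecParams(alpha=0.6, min_size=6, min_side=2)
        for _ in range(100):
            g = random_graph(rng, 8, 8, rng.uniform(0.2, 0.9))
            sub = mbsec_search(g, params)
            if sub is not None:
                assert check_feasible(sub, params)
                assert sub.connectivity >= params.alpha

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            g = random_graph(rng, 8, 9, 0.5, block=(4, 4))
            s_lo = mbsec_search(g, MbsecParams(alpha=0.6, min_size=4, min_side=2))
            s_hi = mbsec_search(g, MbsecParams(alpha=0.9, min_size=4, min_side=2))
            n_lo = 0 if s_lo is None else len(s_lo.left_module) + len(s_lo.right_module)
            n_hi = 0 if s_hi is None else len(s_hi.left_module) + len(s_hi.right_module)
            assert n_hi <= n_lo

    def test_mean_connectivity_relaxation_is_weaker(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = random_graph(rng, 7, 7, 0.6)
            strict = mbsec_search(g, MbsecParams(alpha=0.7, min_size=4, min_side=2))
            mean = mbsec_search(
                g, MbsecParams(alpha=0.7, min_size=4, min_side=2, mean_connectivity=True)
            )
            ns = 0 if strict is None else len(strict.left_module) + len(strict.right_module)
            nm = 0 if mean is None else len(mean.left_module) + len(mean.right_module)
            assert nm >= ns


class TestBruteForceOracle:
    def test_greedy_never_beats_exact(self):
        rng = np.random.default_rng(5)
        params = MbsecParams(alpha=0.6, min_size=4, min_side=2)
        for _ in range(25):
            g = random_graph(rng, 6, 7, 0.5)
            greedy = mbsec_search(g, params)
            exact = brute_force_oracle(g, params)
            gs = 0 if greedy is None else len(greedy.left_module) + len(greedy.right_module)
            es = 0 if exact is None else len(exact.left_module) + len(exact.right_module)
            assert gs <= es

    def test_complete_3x3_alpha1(self):
        g = random_graph(np.random.default_rng(0), 3, 3, 0.0, block=(3, 3))
        sub = brute_force_oracle(g, MbsecParams(alpha=1.0, min_size=4, min_side=2))
        assert sub is not None
        assert sub.left_module == g.left and sub.right_module == g.right

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(8)
        params = MbsecParams(alpha=0.6, min_size=4, min_side=2)
        for rep in range(10):
            g = random_graph(rng, 5, 6, 0.5)
            base = brute_force_oracle(g, params)
            # relabel vertices with a random permutation
            perm_l = {u: f"x{j}" for j, u in enumerate(rng.permutation(sorted(g.left)))}
            perm_r = {v: f"y{j}" for j, v in enumerate(rng.permutation(sorted(g.right)))}
            g2 = BipartiteGraph(
                set(perm_l.values()), set(perm_r.values()),
                {(perm_l[u], perm_r[v]) for u, v in g.edges},
            )
            other = brute_force_oracle(g2, params)
            if base is None:
                assert other is None
            else:
                assert other is not None
                assert len(other.left_module) == len(base.left_module)
                assert len(other.right_module) == len(base.right_module)
                assert other.connectivity == pytest.approx(base.connectivity)

    def test_size_guard(self):
        g = random_graph(np.random.default_rng(0), 13, 13, 0.5)
        with pytest.raises(OracleSizeError):
            brute_force_oracle(g, MbsecParams())


class TestMetrics:
    def test_connectivity_cases(self):
        def sub(nl, nr, ne):
            L = {f"i{x}" for x in range(nl)}
            R = {f"g{x}" for x in range(nr)}
            edges = set(list((u, v) for u in sorted(L) for v in sorted(R))[:ne])
            return BipartiteSubgraph(L, R, edges, alpha=0.5, connectivity=ne / (nl * nr))

        assert connectivity(sub(3, 4, 12)) == 1.0
        assert connectivity(sub(3, 4, 6)) == 0.5
        assert connectivity(sub(1, 1, 1)) == 1.0

    def test_connectivity_empty_side(self):
        s = BipartiteSubgraph(set(), {"g"}, set(), alpha=0.5, connectivity=0)
        with pytest.raises(ValueError):
            connectivity(s)

    def test_interaction_ratio_cases(self):
        genes = {"a", "b", "c", "d"}
        inter = [("a", "b"), ("b", "c"), ("c", "d"), ("x", "y"), ("a", "a"), ("b", "a")]
        assert interaction_ratio(genes, inter) == pytest.approx(0.5)
        assert interaction_ratio(genes, []) == 0.0
        clique = [(x, y) for x in genes for y in genes if x < y]
        assert interaction_ratio(genes, clique) == 1.0
        with pytest.raises(ValueError):
            interaction_ratio({"a"}, inter)


class TestPlantedRecovery:
    def test_jaccard_recovery_of_planted_block(self):
        """8x12 complete block at background 0.05 is recovered (Jaccard >= .9)
        in >=95% of 100 seeded replicates at alpha 0.7."""
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            g = random_graph(rng, 20, 30, 0.05, block=(8, 12))
            sub = mbsec_search(g, MbsecParams(alpha=0.7, min_size=10, min_side=3))
            planted = {f"i{x}" for x in range(8)} | {f"g{x}" for x in range(12)}
            got = (
                set()
                if sub is None
                else sub.left_module | sub.right_module
            )
            jac = len(planted & got) / len(planted | got) if planted | got else 1.0
            ok += jac >= 0.9
        assert ok >= 95
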