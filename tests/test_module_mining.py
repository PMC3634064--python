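"""Hypergeometric enrichment, iterative summarization, module merging."""

import numpy as np
import pytest

from okdsp.coherence import CoherenceScorer
from okdsp.module_mining import (
    FunctionalModule,
    SummarizationParams,
    enrichment_pvalue,
    merge_modules,
    summarize_instance,
)
from okdsp.ontology import build_semantic_weights, propagate_annotations
from okdsp.synthetic import SyntheticSpec, generate_ontology_and_annotations

from .conftest import make_dag


class TestEnrichmentPvalue:
    def test_hand_computed_hypergeometric(self, sibling_dag):
        # N=10, K=5 (genes under c1), n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        direct = {f"g{i}": {"c1"} for i in range(5)}
        direct.update({f"h{i}": {"c2"} for i in range(5)})
        ann = propagate_annotations(direct, sibling_dag)
        p = enrichment_pvalue("c1", {"g0", "g1", "g2", "g3"}, ann)
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_no_overlap_is_one(self, sibling_dag):
        direct = {f"g{i}": {"c1"} for i in range(5)}
        direct.update({f"h{i}": {"c2"} for i in range(5)})
        ann = propagate_annotations(direct, sibling_dag)
        assert enrichment_pvalue("c1", {"h0", "h1"}, ann) == 1.0

    def test_root_term_is_one(self, sibling_dag):
        direct = {f"g{i}": {"c1"} for i in range(5)}
        direct.update({f"h{i}": {"c2"} for i in range(5)})
        ann = propagate_annotations(direct, sibling_dag)
        assert enrichment_pvalue("root", {"g0", "h0", "h1"}, ann) == 1.0


@pytest.fixture
def two_branch_corpus():
    """Star-of-stars: root <- {P1, P2, P3}, each with 4 leaf children.

    P1's leaves hold the focal genes two-per-leaf; P2/P3 leaves hold the
    background.  Summarizing the focal genes must emit exactly P1.
    """
    is_a = {}
    for p in ["P1", "P2", "P3"]:
        is_a[p] = {"root"}
        for i in range(4):
            is_a[f"{p}L{i}"] = {p}
    dag = make_dag(is_a, "root")
    direct = {}
    for j in range(8):
        direct[f"f{j}"] = {f"P1L{j % 4}"}
    k = 0
    for p in ["P2", "P3"]:
        for i in range(4):
            for _ in range(6):
                direct[f"b{k}"] = {f"{p}L{i}"}
                k += 1
    ann = propagate_annotations(direct, dag)
    return dag, ann, build_semantic_weights(dag, ann)


class TestSummarizeInstance:
    def test_immediate_freeze_single_leaf(self):
        # all focal genes at one star leaf; background spread across the
        # other leaves so the null cannot collapse onto a single term
        star = make_dag({f"c{i}": {"root"} for i in range(1, 11)}, "root")
        direct = {f"g{i}": {"c1"} for i in range(5)}
        for i in range(2, 11):
            direct.update({f"h{i}{j}": {f"c{i}"} for j in range(5)})
        ann = propagate_annotations(direct, star)
        w = build_semantic_weights(star, ann)
        res = summarize_instance(
            {"g0", "g1", "g2"}, star, ann, w,
            SummarizationParams(n_null=99, seed=0),
        )
        assert len(res.modules) == 1
        m = res.modules[0]
        assert m.summary_term == "c1"
        assert m.genes == {"g0", "g1", "g2"}
        assert res.unassigned == set()

    def test_genes_accumulate_to_planted_parent(self, two_branch_corpus):
        # two genes per leaf (< min size) migrate up and freeze at P1
        dag, ann, w = two_branch_corpus
        res = summarize_instance(
            {f"f{j}" for j in range(8)}, dag, ann, w,
            SummarizationParams(n_null=99, seed=1),
        )
        assert [m.summary_term for m in res.modules] == ["P1"]
        assert res.modules[0].genes == {f"f{j}" for j in range(8)}

    def test_scattered_genes_yield_nothing(self, two_branch_corpus):
        # two genes per top branch, each on a different leaf: no node below
        # the root ever holds min_module_genes enriched genes
        dag, ann, w = two_branch_corpus
        genes = {"f0", "f1", "b0", "b7", "b24", "b31"}
        res = summarize_instance(
            genes, dag, ann, w, SummarizationParams(n_null=99, seed=1)
        )
        assert res.modules == []
        assert res.unassigned == genes

    def test_gene_conservation_and_posthoc_recheck(self, synth_corpus):
        dag, ann, w = synth_corpus
        rng = np.random.default_rng(4)
        params = SummarizationParams(n_null=99, seed=2)
        scorer = CoherenceScorer(dag, ann, w, n_null=99, seed=2)
        for _ in range(5):
            genes = set(rng.choice(sorted(ann.background), size=25, replace=False))
            res = summarize_instance(genes, dag, ann, w, params, scorer=scorer)
            covered = set().union(
                res.unassigned, res.unannotated, *(m.genes for m in res.modules)
            )
            assert covered >= genes
            for m in res.modules:
                assert len(m.genes) >= params.min_module_genes
                assert enrichment_pvalue(m.summary_term, m.genes, ann) <= 0.05
                assert scorer.pvalue(m.genes).p_value <= 0.05
                term_genes = ann.genes_of_term(m.summary_term)
                assert m.genes <= term_genes

    def test_carbohydrate_transport_shaped_summary(self):
        """Sugar-process leaves summarize under their common transport parent.

        Synthetic replica of summarizing genes annotated to glucose
        detection / glucose binding / fructose transport leaves under one
        carbohydrate-transport term.
        """
        is_a = {
            "carbohydrate_transport": {"transport"},
            "transport": {"root"},
            "other_process": {"root"},
            "detection_of_glucose": {"carbohydrate_transport"},
            "glucose_binding": {"carbohydrate_transport"},
            "fructose_transmembrane_transporter": {"carbohydrate_transport"},
        }
        for i in range(6):
            is_a[f"op{i}"] = {"other_process"}
        dag = make_dag(is_a, "root")
        direct = {
            "SNF3": {"detection_of_glucose"},
            "MTH1": {"detection_of_glucose"},
            "GAL3": {"glucose_binding"},
            "GAL1": {"glucose_binding"},
            "FSY1": {"fructose_transmembrane_transporter"},
            "HXT1": {"fructose_transmembrane_transporter"},
        }
        k = 0
        for i in range(6):
            for _ in range(5):
                direct[f"y{k}"] = {f"op{i}"}
                k += 1
        ann = propagate_annotations(direct, dag)
        w = build_semantic_weights(dag, ann)
        res = summarize_instance(
            {"SNF3", "MTH1", "GAL3", "GAL1", "FSY1", "HXT1"}, dag, ann, w,
            SummarizationParams(n_null=99, seed=0),
        )
        assert [m.summary_term for m in res.modules] == ["carbohydrate_transport"]
        assert len(res.modules[0].genes) == 6

    def test_planted_term_recovered_across_seeds(self):
        """A list drawn from one subtree plus <=10% noise recovers the term
        (or a distance-1 ancestor) in >=90% of 50 seeded runs."""
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            spec = SyntheticSpec(
                n_genes=300, ontology_depth=4, branching=3,
                multi_parent_frac=0.0, annotations_per_gene=(1, 1),
                seed=100 + seed,
            )
            dag, ann = generate_ontology_and_annotations(spec)
            w = build_semantic_weights(dag, ann)
            rng = np.random.default_rng(seed)
            # a tight module source: a leaf-parent term of moderate size
            candidates = sorted(
                t for t in dag.terms
                if dag.children(t)
                and all(not dag.children(c) for c in dag.children(t))
                and 10 <= len(ann.genes_of_term(t)) <= 45
            )
            term = candidates[int(rng.integers(len(candidates)))]
            members = sorted(ann.genes_of_term(term))
            picked = set(rng.choice(members, size=10, replace=False))
            noise = set(rng.choice(sorted(ann.background - picked), size=1))
            res = summarize_instance(
                picked | noise, dag, ann, w,
                SummarizationParams(n_null=199, seed=seed),
            )
            near = {term} | dag.parents(term) | dag.children(term)
            if any(m.summary_term in near for m in res.modules):
                hits += 1
        assert hits >= 0.9 * n_runs


class TestMergeModules:
    def mk(self, term, genes, inst, ep=0.01, cp=0.02):
        return FunctionalModule(
            summary_term=term, genes=set(genes), enrichment_p=ep,
            coherence_p=cp, source_instances={inst},
        )

    def test_same_term_union(self):
        merged = merge_modules(
            [self.mk("T1", "ab", "i1", ep=0.01), self.mk("T1", "bc", "i2", ep=0.005)]
        )
        assert len(merged) == 1
        m = merged[0]
        assert m.genes == {"a", "b", "c"}
        assert m.source_instances == {"i1", "i2"}
        assert m.enrichment_p == 0.005
        assert m.source_pvalues["i1"] == (0.01, 0.02)

    def test_disjoint_terms_passthrough_sorted(self):
        out = merge_modules([self.mk("T2", "ab", "i1"), self.mk("T1", "cd", "i2")])
        assert [m.summary_term for m in out] == ["T1", "T2"]

    def test_counting_across_instances(self):
        mods = [
            self.mk("SHARED", "ab", f"i{k}") for k in range(3)
        ] + [self.mk("UNIQ", "xy", "i9")]
        out = merge_modules(mods)
        assert len(out) == 2
        shared = next(m for m in out if m.summary_term == "SHARED")
        assert len(shared.source_instances) == 3
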