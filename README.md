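# okdsp

Conceptualizing perturbation–response compendia through ontology-driven
knowledge mining and bipartite-graph data mining.

Systematic perturbation screens (gene deletions, chemical exposures)
profile the transcriptional response of a cell to hundreds of treatments.
The raw result is a binary perturbation × gene matrix of
differential-expression calls — too high-dimensional and too gene-centric
for a biologist to read off which *signals* each perturbation disturbs.
`okdsp` lifts such a compendium to a conceptual level in three stages:

1. **Functional-module summarization.** Each perturbation instance's
   responding gene list is placed on a *GOGene graph* — the ontology
   subgraph induced by the genes' annotations, in which every term node
   tracks the genes it currently holds. Leaves are trimmed iteratively:
   each round the least-enriched leaf (one-sided hypergeometric test,
   largest p) merges its genes into the nearest parent by semantic
   distance and is removed. A leaf is instead frozen and emitted as a
   **functional module** once it is significantly enriched
   (p ≤ 0.05), holds ≥ 3 genes, and its genes are functionally coherent:
   the total length of an approximate Steiner tree connecting their
   annotation terms in the IC-weighted ontology graph beats size-matched
   random gene sets (Monte-Carlo p ≤ 0.05). Modules sharing a summary
   term are merged across instances.

2. **MBSEC — maximal bipartite subgraph with expected connectivity.** For
   each merged module, a bipartite graph connects perturbation instances
   to the module's genes (edge = gene differentially expressed under that
   instance). The solver searches for the largest subgraph in which every
   vertex connects to at least a fraction α (default 0.7) of the opposite
   side — a quasi-biclique objective (NP-hard). A greedy peeling deletes
   the vertex with the smallest degree ratio until the constraint holds;
   an exact brute-force oracle validates it on small instances. The
   perturbation side of a returned subgraph is a **perturbation module**,
   the gene side a **responding module (RM)**.

3. **Signaling-unit DAG.** Instances affecting an identical set of
   responding modules form one **signaling unit**. Units are wired by
   signal subsumption — a directed edge u → v when S(u) ⊋ S(v), with
   transitive reduction — and each RM is attached to the highest unit
   carrying it that does not inherit it through a child, so the RMs
   reachable from a unit are exactly its signal set.

A synthetic-data generator produces random ontologies, annotations and
matrices with planted, ontology-coherent biclusters and nested signal
structure, so the entire pipeline is testable without external downloads.

## Worked example

Simulate a small nested compendium (an upstream signal A whose three
instances also light up downstream signal B's block, plus three
B-only instances) and run the full pipeline:

```bash
okdsp simulate --out-dir demo/fix --seed 7
okdsp run-all --obo demo/fix/ontology.obo \
              --annotations demo/fix/annotations.tsv \
              --matrix demo/fix/matrix.tsv \
              --out-dir demo/out --n-null 499 --seed 7
```

which prints

```
2 modules, 2 subgraphs, 2 signaling units -> demo/out
```

and writes `report.txt`:

```
functional modules: 2
dense subgraphs: 2
signaling units: 2
unit edges: 1
unassigned genes: 0
unannotated genes: 0
silent instances: 6
excluded instances: 0
```

The two functional modules are the planted signal terms; each yields one
fully connected perturbation–response subgraph; grouping by signal sets
gives two units joined by one subsumption edge. `dag.dot` renders the
recovered hierarchy — the upstream unit (instances pert000–pert002)
points at the downstream unit (pert003–pert005) and carries the extra
responding module T5:

```
"U000" -> "U001";
"U000" -> "T5";
"U001" -> "T10";
```

`silent instances: 6` counts the background instances with no
differential-expression calls at all (the fixture is noiseless); they are
reported, never silently dropped.

The same stages are available as library calls (`summarize_instance`,
`mbsec_search`, `build_signaling_dag`, `run_pipeline`) and as individual
subcommands (`okdsp summarize`, `okdsp mbsec`, `okdsp dag`).

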