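# Methods

## The model

`okdsp` assumes that a functionally coherent gene module responding in a
coordinated way to several perturbation instances is the readout of one
cellular signal, and that the set of signals affected by an instance
characterizes where that instance acts in the signaling system. The
pipeline therefore (i) conceptualizes gene-level responses as
ontology-annotated modules, (ii) detects coordinated module responses as
dense bipartite subgraphs, and (iii) orders instance groups by set
inclusion of their affected modules.

## Ontology backbone

Only `is_a` edges within a single namespace (default
`biological_process`) are used; `part_of`/`regulates` relations, GO
slims and evidence codes are out of scope. Obsolete and
out-of-namespace terms are dropped at load time; annotations to terms
absent from the loaded graph are dropped with a logged count. Gene
annotations are propagated to all ancestors (true-path rule); the
background is the set of genes with at least one direct annotation.

**Information content and distances.** IC is annotation-frequency based,
`ic(t) = −ln(n_t / N)` with `n_t` the propagated annotation count of `t`
in the loaded corpus and `N` the background size. Computing IC from the
loaded corpus (rather than a fixed external one) keeps synthetic
ontologies self-consistent. An is-a edge (parent p, child c) has weight
`ic(c) − ic(p) ≥ 0`; the semantic distance between two terms is the
weighted shortest path in the undirected is-a graph. This choice is
monotone, additive along is-a chains, and fully determined by the loaded
data. Terms with zero annotations are floored at one gene inside the
weight table so the whole graph stays finitely weighted; the public
`information_content` function still refuses them.

## Functional coherence

A gene set is scored by the total length of an approximate Steiner tree
(shortest-path heuristic, a 2-approximation) connecting the union of the
genes' **direct** annotation terms — the same placement used by the
GOGene graph. Significance is an empirical Monte-Carlo null: `n_null`
(default 1000) gene sets of identical size drawn uniformly without
replacement from the background, with the add-one p-value
`p = (1 + #{null ≤ observed}) / (n_null + 1)`. Ties count against
significance, which keeps the p-value valid and conservative. The null
RNG is seeded from `(seed, set size)`, making the null distribution for
a given size a pure function of the corpus and seed; the
`CoherenceScorer` caches it per size, which changes nothing in the
results but makes summarization hundreds of times cheaper. Whether the
raw score should be size-normalized is immaterial here because nulls are
size-matched.

## Summarization

Parameters: `enrichment_alpha` = `coherence_alpha` = 0.05,
`min_module_genes` = 3 (a summary term backed by one or two genes is not
informative), no multiple-testing correction across leaves (each
instance's summarization is a single search, not a family of independent
hypotheses — and correcting would only shrink modules, not change the
machinery). Enrichment is the one-sided hypergeometric upper tail over
the full annotated background (configurable to responding-genes-only).

The trimming loop each round: emit every current leaf passing all three
thresholds (frozen leaves keep the genes accumulated from their trimmed
descendants — that is what merging genes upward implies); otherwise trim
the single least-enriched leaf into its nearest present parent by
semantic distance. Tie-breaks are deterministic: leaf selection by
(p-value, lexicographic term id); the merge target by (distance, smaller
IC — more general — then lexicographic id). Coherence is evaluated
lazily, only for leaves that already pass enrichment and the size floor;
the emitted set is identical to eager evaluation. Genes that reach the
root are reported `unassigned`; genes without annotations are reported
`unannotated`. Both are outputs, never errors.

## MBSEC

Per-vertex constraint: each vertex must connect to at least
`ceil(α · |opposite side|)` vertices (the "at least" reading warrants the
ceiling). The average form ("on average α") is available as a
`mean_connectivity` relaxation flag for comparison. Defaults: α = 0.7,
minimum subgraph size 10 vertices, minimum 3 per side — all exposed as
flags.

The greedy peels the vertex with the smallest degree ratio
(degree / opposite-side size, ties lexicographic) until the constraint
holds or a side empties; because each deletion shrinks the size by
exactly one, the first feasible state maximizes |left|+|right| along the
trajectory. The exact oracle enumerates subsets of the smaller side and,
for each, scans right-subsets of the degree-feasible candidate pool with
vectorized popcounts; it refuses instances above 24 vertices. Iterative
constraint propagation alone would not be exact because the quota on one
side depends on the chosen size of the other. One subgraph is extracted
per module graph (the maximal one).

## Signaling-unit DAG

Perturbation modules with fewer than `k_min` = 2 instances are dropped
(a module seen in a single instance offers no evidence of a shared
signal). Units are the equivalence classes of instances under identical
signal sets; edges are strict-superset relations, transitively reduced
so the drawing is minimal and the reachability law exact. Responding
modules attach only where not inherited through a child, which makes the
RMs reachable from a unit equal its signal set — the property the
verifier `reachable_signals` checks. Instances in no retained module are
excluded and listed.

## Synthetic data

The generator emulates a compendium of ~300 perturbations × ~5,000
responding genes at desk scale: defaults are 400 genes, 60 instances,
a depth-4 branching-3 is-a tree (121 terms) with 10% extra multi-parent
edges, and 1–3 leaf annotations per gene with Zipf-like term popularity
(few popular terms, many rare ones — the shape of real annotation
corpora). Matrices follow a Bernoulli block model: `p_in` inside planted
(instances × genes) blocks, `background_p` elsewhere; nested structure
makes an upstream signal's instances also draw the downstream blocks,
which is exactly the subsumption pattern the DAG stage must recover.

The bundled `nested_demo_spec` (120 genes, 12 instances, two planted
signals of 3 instances × 8 genes each, A upstream of B) spreads each
signal's genes two-per-leaf over the four leaf children of one term, so
no leaf can freeze below the planted term and summarization recovers the
two terms exactly in the noiseless case.

What the generator does **not** model: microarray noise and
differential-expression calling (calls are generated directly as
binary), correlated annotation errors, and realistic gene naming.
Passing tests therefore demonstrate the correctness of the algorithms
under the stated generative assumptions, not performance on any
particular real compendium — the published compendium plus a
2003-era annotation snapshot would be needed to reproduce historical
counts, which is out of scope here.

## Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are composed as integer lists, never re-used
  across purposes. Two runs with the same seed and config are
  byte-identical (JSON keys sorted, floats at 6 significant digits).
- Tolerances: float round-off guards of 1e-9..1e-12 on comparisons of
  accumulated edge weights and on the `ceil(α·n)` quota (so α·n that is
  an exact integer is not pushed up by representation error).
- Problem sizes in the verification suite and acceptance script: 500
  random graphs for feasibility, 50 graphs of 10+10 vertices for the
  exact-oracle comparison, 100 replicates of the 8×12 planted-block
  recovery, 600–1000 replicates for null calibration (several
  independent null caches decorrelate the shared-null replicates), and
  the 492 exhaustive ≤4-terminal Steiner instances of two toy
  ontologies. These sizes give stable rates in seconds to a couple of
  minutes on one CPU.

## Known limitations

- The Steiner heuristic is a 2-approximation; on the toy instances it is
  in fact optimal, but no such guarantee holds at scale.
- The greedy peeler can miss the optimum on adversarial graphs (it
  agrees with the exact oracle in ~85–95% of random instances); only
  the returned subgraph's feasibility is guaranteed, not optimality.
- Coherence terminals use direct annotations only; a gene set annotated
  consistently at very general terms scores coherent even though the
  shared concept is broad.
- One namespace per run; cross-namespace signals are invisible.
- The DAG stage trusts the upstream summary terms: instances are grouped
  by exact signal-set identity, with no tolerance for near-identical
  sets.
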