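# Methods

`comorbnet` analyses the shared genetic architecture of two comorbid
diseases — the reference use case is epilepsy and autism spectrum
disorder — by embedding their curated gene lists in a two-layer
(multiplex) network and reading biology off the module structure.  This
note records the model, the numerical choices, and what the synthetic
benchmark does and does not establish.

## The multiplex model

The node set is the union of two disease gene lists, each annotated with
a subgroup label (epilepsy subgroups 1–4; autism subgroups 1/2/3/S) and
auxiliary group flags (WES hits, bipolar disorder, schizophrenia,
intellectual disability, brain-enriched genes).  Genes carrying both
disease labels are the *common genes*.  Two undirected, simple,
binary-weight layers span the full node set:

* **PPI layer.** STRING-style edges with combined confidence ≥ 700 (the
  customary high-confidence cut) are kept and binarized.  Genes missing
  from the PPI source remain as degree-zero nodes: they may still be
  connected — and hence placed into modules — through the other layer.
* **Phenotype layer.** Each gene gets a phenotype vector over the
  ontology terms below "Phenotypic abnormality": entry = association
  score × the term's skewness weight, after restricting each term to its
  top-k scoring genes (k = 1000 for the full network, 500 for the WES
  profile).  Gene pairs are scored by cosine similarity, and an edge is
  added when the observed similarity *strictly* exceeds a per-pair
  permutation threshold: the 10th largest of 1000 similarities obtained
  by independently permuting the entries of both vectors (nominal tail
  probability 10/1000 = 0.01).  Strict comparison means a pair with a
  degenerate null (e.g. constant vectors) is never linked.  A pair of
  nonnegative vectors only interacts on the positions where the two
  permuted supports coincide, so the sampler draws the overlap size from
  the corresponding hypergeometric law and then random value subsets —
  distribution-identical to permuting the full vectors and much faster
  for sparse vectors.  Whether the two vectors should be permuted
  jointly or independently is a genuinely open choice; independent
  permutation is the default (a joint flag exists, but a shared
  permutation leaves cosine similarity unchanged and is therefore a
  degenerate null).  Zero vectors get similarity 0 and can never gain
  edges.

The two layers are stacked node-aligned.  The inter-layer coupling (each
gene tied to its own copy in the other layer) is represented implicitly:
community detection optimizes one partition shared by both layers, which
is exactly what explicit identity coupling induces.

## Community detection

Module quality on one layer is resolution-parameterised modularity
H = (1/2m) Σ_c (e_c − γ K_c²/(2m)) with e_c the within-community sum of
adjacency entries (twice the internal edge count), K_c the summed member
degree and γ the resolution.  Under this convention the all-in-one
partition scores exactly 0 at γ = 1 — the regression test for the
convention — and the two-disjoint-triangles fixture scores
H(γ) = 1 − γ/2 (0.5 at γ = 1).  The multiplex objective is
H = w_ppi·H_ppi + w_phen·H_phen with equal weights by default so both
layers contribute equally; an empty layer contributes 0.

The optimizer is an in-house multilevel Louvain: greedy local moves on
the combined per-layer gain, then simultaneous aggregation of both
layers, repeated to a fixed point.  Restarts use seeds
seed, seed+1, …, seed+n_restarts−1 (default 1000 restarts at reference
scale); quality ties keep the lowest seed, so runs are reproducible.
Tests check the optimizer against exhaustive partition enumeration on
graphs of ≤ 8 nodes and against an independent multiplex optimizer
(leidenalg) on planted two-layer graphs.  Quality values at different γ
are not mutually comparable, so the resolution sweep
(default γ ∈ {0.5, 1, 1.5, 2}) is reported in full and the partition at
the primary γ (default 1.0) is the headline result.  Modules are
renumbered by decreasing size with ties broken by smallest member
symbol, so "module 3"-style references are stable.  Module filtering
keeps modules with ≥ 2 genes and truncates to the 14 largest (the WES
profile keeps modules with ≥ 5 genes, uncapped).

## Layer concordance

Edge-set overlap and the NMI between the layers' individual Louvain
partitions are calibrated against degree-preserving nulls: each trial
rewires both layers by double edge swaps (10 × |E| swaps, preserving
every degree exactly — the strictest reading of "same degree
distribution"), implemented through igraph's C-level rewiring.
Empirical p-values use the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n_trials), which can never reach 0;
its floor at n trials is 1/(n+1).  NMI uses arithmetic-mean
normalization; degree correlation defaults to Spearman because degree
distributions are heavy-tailed (Pearson by flag); both choices are
recorded in the result metadata.

## Enrichment

Gene-group enrichment is the upper-tail hypergeometric probability of
the module/group overlap, under either the network background (the gene
universe itself) or a genome-scale background (default 19,556 genes,
the size of the PPI source database) with counts unchanged.  Phenotype
enrichment has two modes: an empirical test comparing the module's mean
association score for a term with the means of 10,000 random same-size
draws without replacement (genes without a score row count 0, since the
score table is sparse and silence is absence of evidence), and a
hypergeometric variant over externally annotated term-gene sets.  The
generic `annotation_set_enrichment` applies the same mechanics to any
user-supplied gene sets, replacing external GO/pathway services, which
are out of scope.  Benjamini–Hochberg correction is applied within each
panel (all module × group rows, or all module × term rows), matching
the practice of correcting across the groups/terms tested together;
star bands are pure post-processing of q-values
(**** < 1e−4, *** < 0.01, ** < 0.05, * < 0.1).

## Prioritization

Per-layer degree and shortest-path betweenness are computed on the full
layers and restricted to module members; "average" centralities are
unweighted arithmetic means of the two layers.  Betweenness follows the
convention σ(s,t) = 1 for s = t and σ(s,t|v) = 0 for v ∈ {s,t};
normalized mode (default, matching the scale of standard network
tooling) divides by the number of eligible unordered pairs, and the raw
ordered-pair sum of the formula is available (`ordered_pairs=True`,
equal to twice the unordered count).  Computing betweenness on whole
layers rather than module-induced subgraphs is a deliberate choice: a
gene's brokerage role in the full network is what the ranking should
reflect.

Cross-network module matching reports, for each module of one
partition, the fraction of its genes (among those present in the other
universe) landing in each module of the other partition.  The primary
candidate rule returns, inside a disease-A-focused module, the genes
carrying only the disease-B label; the secondary rule catches
focused-module genes of the smaller network whose module in the larger
network is the other prioritized module.  In the pipeline, the
disease-focused modules are the ones most enriched (smallest FDR) in
the corresponding phenotype subtree (seizure-like / autistic-behavior-
like).  The common-vs-specific centrality comparison uses a two-sided
Mann–Whitney rank-sum test (the centralities are heavy-tailed, so a
rank test is the safe default) on average degree.

## The synthetic benchmark

No inputs can be redistributed, so the generator emulates all four
tables with planted structure.  Defaults mirror the reference study
conditions scaled to desk size: 200 genes with label fractions matching
the real lists (58.5% disease A, 53.5% disease B, 12% common — note
these sum to 100% + common, as every gene carries at least one label),
4 planted modules, PPI block densities p_in = 0.4 / p_out = 0.01 with
within-block confidences forced ≥ 700 so planted structure survives the
threshold and between-block confidences uniform over 150–999 so the
threshold is exercised, a 120-term ontology with marked seizure-like
(`SEIZ:*`) and autistic-behavior-like (`AUT:*`) subtrees, 8
characteristic terms per module (module 1 draws from the seizure
subtree, module 2 from the autistic-behavior subtree), and phenotype
signal-to-noise 10 (signal scores ~10, background scores ~1 on 3 random
terms per gene).  Common genes are placed in module 1 with probability
0.8 (`common_module_bias`) so that, as in the real networks, one module
is enriched in dual-label genes; everything else is uniform.  One
global seed drives independent per-stage substreams so each stage is
reproducible in isolation.

The generator is deliberately idealized: confidence scores are
independent of network topology, phenotype noise is homogeneous, the
ontology is a tree rather than a DAG, auxiliary groups are random
flags (brain-enriched genes are sampled labels, not derived from
expression), and there is no ascertainment bias toward well-studied
genes.  Passing tests therefore establish that the machinery recovers
structure it was designed to detect under controlled conditions — not
that the biological conclusions of any particular real dataset are
correct.

## Problem sizes and tolerances

The test-suite and acceptance-script runs use the 200-gene fixture with
40 Louvain restarts, 1000 edge-overlap trials, 200 partition-NMI trials
(add-one p-value floors 1/1001 and 1/201) and 1000-trial empirical
enrichment; these sizes are the package's chosen desk-scale defaults,
while `PipelineConfig` retains the reference-scale settings (1000
restarts, 10,000/1000 trials, 10,000 enrichment trials).  Optimizer
quality is asserted equal to an independent re-evaluation of the
modularity formula to 1e−9; exhaustive oracles (hypergeometric tails up
to N = 12, betweenness on graphs ≤ 7 nodes, permutation nulls on
vectors of length ≤ 4) are matched to numerical precision; Monte-Carlo
estimates are compared to exact tails within 3 binomial standard
deviations.  Every run writes its resolved configuration and a config
hash beside its outputs, and a re-run with an identical configuration
is byte-identical.

## Known limitations

* Only two layers are supported, and layers are binary; weighted-edge
  variants would require a different null for the permutation
  threshold.
* The Louvain heuristic carries its usual caveats (it can in principle
  produce internally disconnected communities); the Leiden refinement
  is intentionally out of scope, with leidenalg used only as a test
  oracle.
* Gene symbol standardization is trimming + upper-casing only; alias
  resolution against a nomenclature database is out of scope, and gene
  clusters must be expanded to individual genes upstream.
* The empirical enrichment p-value is bounded below by 1/(n_trials+1);
  ranking terms below that floor requires more trials.
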