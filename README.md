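# comorbnet

Multiplex gene–phenotype network analysis for comorbid disease gene
sets.

Epilepsy and autism spectrum disorder co-occur far more often than
chance, and a substantial set of genes is implicated in both.
`comorbnet` characterizes that shared genetic architecture: it embeds
the two curated gene lists in a two-layer (multiplex) network — one
layer of high-confidence protein–protein interactions, one layer of
phenotype similarity derived from gene–phenotype association scores —
detects gene modules jointly across both layers, tests each module for
enrichment in gene groups and phenotype terms, and prioritizes
candidate genes that sit in a disease-focused module while carrying
only the other disease's label.  The same machinery applies to any pair
of comorbid diseases with curated gene lists.

## Model

* **Nodes** are the union of two disease gene lists with subgroup
  labels; genes on both lists are the *common genes*.
* **PPI layer**: STRING-style edges kept at combined confidence ≥ 700,
  binarized.  Genes absent from the PPI source stay as isolated nodes.
* **Phenotype layer**: each gene's vector holds score × skew for
  ontology terms under "Phenotypic abnormality" (per-term top-k filter,
  k = 1000).  An edge joins two genes when their cosine similarity
  strictly exceeds a per-pair permutation threshold — the 10th largest
  of 1000 similarities after independently permuting both vectors
  (nominal p = 0.01).
* **Modules** maximize the multiplex modularity
  `H = w_ppi·H_ppi + w_phen·H_phen`, each layer's
  `H = (1/2m) Σ_c (e_c − γ K_c²/(2m))`, with equal layer weights, via
  seeded-restart multilevel Louvain under one shared partition.
* **Enrichment** is upper-tail hypergeometric (gene groups, annotated
  terms) or an empirical mean-score test (10,000 random same-size
  draws), with Benjamini–Hochberg FDR per panel.
* **Prioritization** ranks module genes by per-layer degree and
  betweenness centrality and applies the candidate rule to module
  overlaps across networks.

Because the real inputs (STRING, Phen2Gene, SFARI, curated epilepsy
lists) cannot be redistributed, the package ships a first-class
synthetic generator that emulates all four input tables with planted
module structure, making the full pipeline testable end to end against
known ground truth.

## Worked example

Simulate a bundle at the default study conditions (200 genes, 4 planted
modules, PPI block densities 0.4/0.01, phenotype signal-to-noise 10)
and run the full pipeline:

```bash
comorbnet simulate --out bundle/ --seed 1
comorbnet run-all --input bundle/ --out results/ --seed 1 \
    --restarts 40 --overlap-trials 1000 --nmi-trials 200 \
    --enrichment-trials 1000
```

which prints:

```
modules kept: [1, 2, 3, 4]
focused modules: {'epilepsy': 1, 'autism': 2}
candidates: ['G0017', 'G0020', 'G0031', ...]
common-vs-specific centrality: p=3.363e-06 (common_higher)
```

Reading the output: the multiplex partition recovered four modules;
module 1 is the most enriched in seizure-like phenotype terms
("epilepsy-focused") and module 2 in autistic-behavior-like terms; the
candidate list contains the genes of the epilepsy-focused module that
carry only an autism label — the planted analogue of proposing new
epilepsy genes — and common genes have significantly higher network
centrality than single-disease genes (rank-sum p ≈ 3.4e−06).  The
output directory contains the layer edge lists, the multiplex and
per-layer partitions, the layer-concordance report
(`layer_comparison.json`: edge-overlap and partition-NMI empirical
p-values against degree-preserving rewired nulls, degree correlation),
the enrichment tables with FDR and star bands, per-module centrality
tables, cross-partition module matches and the candidate list.  Every
file carries a header with the tool version, seed and configuration
hash, and re-running with the same configuration reproduces every file
byte for byte.

The same analysis is available as a library:

```python
from comorbnet import PipelineConfig, SimulationConfig, run_pipeline

result = run_pipeline(PipelineConfig(simulate=SimulationConfig(seed=1), seed=1))
print(result.kept_modules, result.focused_modules)
print(result.gene_enrichment_network.head())
```

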