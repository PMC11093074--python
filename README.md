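# geneflows

Fuzzy expression-level **flow analysis** for grouped single-cell RNA
profiles, with the supporting steps a cohort-scale CITE-seq analysis needs:
antibody-based cell calling for low-RNA cell types, pseudobulk aggregation,
gene-set enrichment of flow memberships, per-cell module scoring, and a
seeded planted-pattern simulator that gives every stage a known ground
truth.

## The problem and the model

Comparing cell states across an *ordered* series of conditions (e.g.
healthy → sterile inflammation → bacterial infection) with hard
differential-expression cutoffs forces every gene into a yes/no call per
comparison. Flow analysis instead grades each gene's expression on an
ordered vocabulary of levels and follows it across the series:

- **Fuzzification.** For each gene g and group (cluster c, condition t) the
  mean normalized expression x is mapped to memberships
  μ\_ℓ(x) ∈ [0, 1] over L ordered levels (default *NotExpressed, Low,
  Medium, High*). Triangular membership functions peak at level anchors
  a\_0 = 0 < a\_1 < … < a\_{L−1} (fitted as global quantiles of the positive
  group means) and satisfy the partition of unity Σ\_ℓ μ\_ℓ(x) = 1.
- **Flows.** A *level path* p = (ℓ\_1, …, ℓ\_T) assigns one level per
  condition. A gene belongs to p with m\_g(p) = Π\_t μ[g, t, ℓ\_t] (product
  t-norm; minimum available). The *flow weight* w(c, p) = Σ\_g m\_g(p) is
  the ribbon width of an alluvial diagram; under the product combiner
  Σ\_p w(c, p) = G exactly, and the weights are computed by a factorized
  recursion rather than path-by-path enumeration.
- **Patterns and ranking.** Pattern predicates select path sets, e.g.
  *final level strictly above every earlier level, at least Medium*. A
  gene's combined membership M(g) sums its path memberships over the
  selected set and is combined across clusters by minimum (fuzzy AND, "in
  all clusters") or maximum. Genes are ranked by M(g); enrichment of gene
  sets in the memberships is tested exactly (hypergeometric, BH-corrected)
  or by membership-weighted permutation.

Around the core: cells are called from surface-antibody counts (a cell
needs all required antibodies above thresholds derived from a background
quantile), which rescues transcriptionally quiet cell types that a per-cell
UMI cutoff would discard; per-sample tables can be downsampled to a fixed
cap and pooled; module scores compare a gene set's per-cell mean expression
with expression-matched binned controls.

## Worked example

`python examples/01_planted_flow_recovery.py` simulates 5,000 genes ×
3,000 cells (5 clusters × 3 conditions × 200 cells) with 50 genes induced
4-fold in the final condition in every cluster, and prints:

```
simulated 5000 genes x 3000 cells, 50 planted genes
fitted level anchors: {'NotExpressed': 0.0, 'Low': 0.217, 'Medium': 0.371, 'High': 0.872}
13 of 64 level paths match the pattern
  gene  membership
g00420    0.888486
g02900    0.887891
g04739    0.875662
g04300    0.825604
g03508    0.822299
recovery of planted genes in the top 60: 100.0%
```

The anchors are the fitted level boundaries on the log-normalized scale; 13
of the 4³ = 64 level paths show a final level strictly above both earlier
levels and at least *Medium*; the membership column is the degree (0–1) to
which a gene follows those flows in **all** clusters simultaneously — here
the planted genes fill the top of the ranking.

The other examples cover antibody cell calling vs. UMI filtering
(`02_cell_calling.py`), crisp and weighted enrichment (`03_enrichment.py`)
and module scoring (`04_module_scores.py`). A thin CLI mirrors the library
(`geneflows simulate|ingest|fuzzify|flow|enrich|score|sankey|run`); see
`geneflows --help`.

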