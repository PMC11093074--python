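# Methods

## Scope and data model

The package analyses grouped expression profiles: a genes × cells count
matrix, an optional antibodies × cells capture matrix aligned to the same
cells, and a per-cell annotation (sample, condition, cluster). Conditions
form an explicitly ordered series declared once per analysis; clusters are
inputs (no clustering is performed here). All matrices are genes × cells
internally; Matrix Market input is transposed automatically when the
companion id files show it was stored cells × genes.

## Ingest

**Cell calling.** A droplet is called as a cell when its capture count
reaches the threshold for *all* required antibodies. Thresholds are either
explicit or derived as a quantile (default 0.99) of a declared background
population. RNA content is deliberately ignored so that cell types with
little RNA survive; `umi_filter` implements the conventional per-cell
transcript cutoff (boundary inclusive: total ≥ cutoff keeps the cell) for
comparison. The pipeline, lacking an external background annotation, uses
the lowest-decile-RNA droplets as the background population; standalone
calling accepts any declared subset. Raising any threshold can only shrink
the called set (tested as a monotonicity property).

**Normalization and pseudobulk.** Counts are scaled per cell to a fixed
total (default 10,000) and log1p-transformed — the conventional single-cell
normalization — before aggregation. For each (cluster, condition) group the
profile records the mean normalized expression per gene, the fraction of
member cells with raw count > 0, and the cell count; empty groups are
omitted and logged, and a declared condition with no cells at all is an
error. Group means are invariant to cell order, and because normalization
is strictly per cell, removing or appending cells outside a group cannot
change that group's summary.

**Downsampling.** Per-sample tables are capped at `n_per_sample` rows drawn
uniformly without replacement from a single seeded generator; samples below
the cap contribute everything (with a warning) rather than failing, so
small samples do not abort a cohort pool. The pooled size is exactly
Σ_s min(cap, |s|).

## Fuzzification

Levels are an ordered vocabulary (default *NotExpressed, Low, Medium,
High*; the count is configurable) pinned to anchors a_0 = 0 < a_1 < … <
a_{L−1} on the normalized log scale. Membership functions are triangular:
μ_ℓ rises linearly from the previous anchor, peaks at a_ℓ, and falls
linearly to the next; inputs at or below a_0 (resp. ≥ a_{L−1}) belong fully
to the first (last) level. This family was chosen for its partition-of-unity
property — memberships are nonnegative and sum to exactly 1 for every input
— which is what makes flow weights conserve gene count downstream.

Anchors are fitted **globally** as quantiles of the positive group means
pooled over all (cluster, condition) groups, default (0.25, 0.5, 0.9) for
four levels. Global anchoring keeps levels comparable across clusters and
conditions; per-cluster anchoring would break cross-cluster flow
comparison. The default quantiles put the top anchor in the upper tail so
that *High* denotes clearly elevated expression rather than the upper
quartile. Genes expressed in fewer than 1% of cells in every group are
dropped before fuzzification (configurable, logged): their group means sit
in the noise floor and would otherwise populate flows spuriously.

## Flows

With L levels and T conditions there are L^T level paths. A gene's
membership in a path is the product (default) or minimum of its level
memberships along the path. The product combiner is the default because it
factorizes: summing over all paths gives Π_t Σ_ℓ μ = 1 per gene, so total
flow weight per cluster equals the gene count exactly, and all L^T weights
are computed by an iterated outer product (O(G·L^T) memory-bounded, no
per-path loops over genes). The min combiner is available but enumerates.
Enumeration is capped (default 10^6 paths) with an error advising
pattern-restricted analysis beyond it.

Pattern predicates: `final_above_all_prior` (the final condition's level
strictly exceeds every earlier one — chosen over "monotone increase"
because the scientific question compares the final condition against each
baseline, not a trend), `final_below_all_prior`, `nondecreasing`,
`nonincreasing`, `constant`, `any`; `min_final_level` additionally bounds
the final level from below. Selected paths are disjoint, so a gene's
combined membership is the sum of its path memberships (≤ 1 under the
product combiner). Across clusters, `all_clusters` combines by minimum
(fuzzy AND), `any_cluster` by maximum. Rankings break ties by gene id so
results are deterministic.

The Sankey export serializes nodes (condition, level; throughput
Σ_g μ[g,t,ℓ]) and links (the product marginal Σ_g μ[g,t,ℓ]·μ[g,t+1,ℓ′]) as
a JSON document for any plotting front-end; node throughputs per condition
sum to G, and links out of a node sum to its throughput. Both a single
T-column alluvial and pairwise two-column layouts can be rendered from the
same document, since the links are stored per consecutive condition pair.

## Enrichment

Crisp mode thresholds M(g) (default 0.5, boundary inclusive) into a hit set
and applies the one-sided hypergeometric over-representation test
(P[X ≥ k] via `scipy.stats.hypergeom`), BH-corrected across the tested
family. Weighted mode scores each set by Σ_{g∈S} M(g) and permutes the
membership vector over the universe; p-values use the add-one estimator
(1 + #{null ≥ obs})/(1 + B), which is valid (never zero) and exactly
calibrated at achievable levels. The universe is the set of genes that
survived the ingest expression gate — not the full annotation — to avoid
composition bias. Only over-representation is tested; results are sorted by
set name so input order is irrelevant.

## Module scores

score(cell) = mean normalized expression of the set genes − mean of control
genes, controls drawn per set gene from its average-expression bin
(`n_bins` = 24 equal-occupancy bins over the scored cells' gene means,
rank ties broken by gene id), `n_ctrl` = 100 per set gene, excluding set
genes from the pool (falling back to all non-set genes if a bin holds
nothing else, with replacement only when a pool is smaller than `n_ctrl`).
The draw is seeded and fully deterministic. Scoring a cell subset computes
means and bins on that subset only, so appending unscored cells changes
nothing. The test suite cross-checks direction and magnitude against
scanpy's independent binned-control scorer on data with planted per-cell
structure.

## Synthetic data

The generator emulates the cohort design the analysis targets: C = 5
clusters × T = 3 ordered conditions (healthy, stroke, infection), 2 samples
per condition, 100 cells per (cluster, condition, sample) block — 200 cells
per pseudobulk group, 3,000 cells in total — and G = 5,000 genes. Baseline
gene means are log-normal(−1, 1) counts/cell (median ≈ 0.37, a realistic
depth for fixed whole-blood single-cell data); counts are negative binomial
via gamma-Poisson with dispersion θ = 0.3 (var = μ + μ²/θ), strongly
overdispersed as single-cell RNA counts are. All clusters share the same
baseline — a deliberate simplification: the planted pattern models the
conserved cross-cluster response that the all-clusters flow pattern is
designed to detect, and real cluster-specific expression offsets are not
emulated.

One pattern is planted by default: 50 genes at fold change 4 in the final
condition in every cluster. Planted genes are drawn from genes with
baseline mean in [0.25, 0.6] counts/cell. The window is a property of the
question, not a convenience: a level-*increase* pattern needs headroom on
the ordered level scale, so genes already saturating the top level cannot
display an increase, and silent genes cannot reach *Medium* even after a
4-fold induction; a flow analysis targets exactly the mid-expressed genes
the window contains. Antibody counts are a two-component negative binomial
mixture (stained mean 100, background mean 2) with a much milder dispersion
(shape 10) than RNA, reflecting the lower technical noise of antibody
tags; with RNA-like dispersion the stained mode would smear into the
background, which is not what capture-antibody data look like. A single
`numpy` generator seeded once drives everything, so identical seeds give
byte-identical datasets.

What passing tests on these data do **not** show: robustness to batch
effects, ambient RNA, doublets, cluster-specific baselines or non-NB noise
— none of which the generator emulates.

## Pipeline and determinism

`run_pipeline` chains ingest → fuzzify → flows → enrich from a flat YAML
config in which every seed is explicit, and writes all tables
(fixed `%.10g` float formatting), the Sankey documents, and a JSON run log
with package/library versions, the full config, input checksums and derived
quantities — but no timestamps, so reruns with identical config and inputs
are byte-identical, provenance files included. Any stage failure aborts
with the stage name and context.

## Problem sizes and numerical choices

The planted-recovery analyses run at the default 5,000 × 3,000 scale; the
conservation and factorization identities are verified on 200-gene random
Dirichlet tensors against explicit path enumeration (tolerance 1e-12,
conservation 1e-9·G); hypergeometric p-values are checked exhaustively
against exact rational arithmetic for every universe ≤ 30; permutation
calibration uses 200 structureless repeats × 10 disjoint sets at 999
permutations, where the achievable p < 0.05 rate is 49/1000 per test.
Membership sums are validated to 1e-9 at tensor construction; quantile
anchors must be strictly increasing or fitting aborts with advice to use
fewer levels.

## Known limitations

- The membership family and anchoring rule are design choices; other
  graded-membership schemes (Gaussian, learned) are not implemented.
- Flow weights are descriptive; no significance is attached to a flow's
  width.
- The min combiner loses the conservation identity and the factorized
  computation.
- Enrichment does no ontology-graph reasoning (no parent-term redundancy
  reduction) and no cross-species id mapping.
- The simulator's cells are i.i.d. within blocks; sample-level variance
  components are not modelled.
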