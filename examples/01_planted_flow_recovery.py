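"""Recover planted condition-responsive genes with a flow pattern.

Simulates a cohort (5 clusters x healthy/stroke/infection, 200 cells per
group) in which 50 genes are induced 4-fold in the final condition across
all clusters, then runs pseudobulk -> fuzzification -> flow selection and
ranks genes by their combined membership in "increased to at least Medium
in every cluster" flows.
"""

from geneflows import (
    FlowPattern,
    SyntheticSpec,
    compute_flows,
    fit_fuzzy_spec,
    fuzzify,
    generate,
    pseudobulk,
    top_genes,
    truth_eval,
)

spec = SyntheticSpec(seed=1)
rna, adt, annotation, truth = generate(spec)
print(f"simulated {rna.n_genes} genes x {rna.n_cells} cells, "
      f"{len(truth)} planted genes")

profile = pseudobulk(rna, annotation, spec.condition_series)
fuzzy = fit_fuzzy_spec(profile)
print("fitted level anchors:",
      {l: round(a, 3) for l, a in zip(fuzzy.levels, fuzzy.anchors)})

mu = fuzzify(profile, fuzzy)
pattern = FlowPattern(direction="final_above_all_prior",
                      min_final_level="Medium", scope="all_clusters")
result = compute_flows(mu, pattern)
print(f"{len(result.selected_paths)} of 64 level paths match the pattern")

ranked = top_genes(result.membership, 60)
recovery = truth_eval(ranked["gene"], truth, 60)
print(ranked.head(5).to_string(index=False))
print(f"recovery of planted genes in the top 60: {100 * recovery:.1f}%")
# The membership column is the fuzzy degree (0..1) to which each gene follows
# the selected increase-in-infection flows in ALL clusters simultaneously.
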