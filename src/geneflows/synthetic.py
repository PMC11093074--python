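"""Seeded simulator of RNA + antibody counts with planted flow patterns.

The generator emulates a cohort design: C cell clusters observed across T
ordered conditions, with S samples per condition and a fixed number of cells
per (cluster, condition, sample) block.  RNA counts are negative binomial
(gamma-Poisson) around log-normally distributed baseline gene means shared by
all clusters; *planted* genes carry a multiplicative fold change in chosen
(cluster, condition) blocks and are recorded in a ground-truth table, giving
every downstream module a known answer to recover.

Antibody capture counts are a two-component negative binomial mixture
(stained population vs. ambient background) with a much milder dispersion
than RNA, as is typical for antibody tags; this is the ground truth for
cell-calling tests.

Planted genes are drawn from genes whose baseline mean lies in a
mid-expression window (default 0.25-0.6 counts/cell): a level-increase flow
needs headroom on the ordered level scale, so silent genes (whose induced
level cannot reach Medium) and genes already saturating the top level are
not meaningful planting targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import AdtMatrix, ConditionSeries, ExpressionMatrix, write_expression

__all__ = [
    "PlantedPattern",
    "SyntheticSpec",
    "sample_negative_binomial",
    "generate",
    "generate_adt_mixture",
    "truth_eval",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantedPattern:
    """A block of genes with a fold change in chosen clusters x conditions.

    ``conditions``/``clusters`` of None mean "the final condition" and "all
    clusters" respectively — the conserved cross-cluster induction a
    final-above-all-prior flow pattern is designed to find.
    """

    n_genes: int = 50
    fold_change: float = 4.0
    conditions: tuple[str, ...] | None = None
    clusters: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("a planted pattern needs at least one gene")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the planted-pattern simulator.

    Defaults mirror the cohort structure at toy scale: 5 clusters x 3 ordered
    conditions, 2 samples per condition and 100 cells per (cluster,
    condition, sample) block (200 cells per pseudobulk group), 5,000 genes
    with one planted block of 50 genes at fold change 4 in the final
    condition across all clusters.
    """

    n_genes: int = 5000
    clusters: tuple[str, ...] = ("c0", "c1", "c2", "c3", "c9")
    conditions: tuple[str, ...] = ("healthy", "stroke", "infection")
    samples_per_condition: int = 2
    cells_per_block: int = 100          # per (cluster, condition, sample)
    baseline_log_mean: float = -1.0     # lognormal location of gene means (counts/cell)
    baseline_log_sigma: float = 1.0
    dispersion: float = 0.3             # NB shape for RNA; var = mu + mu^2 / theta
    planted: tuple[PlantedPattern, ...] = (PlantedPattern(),)
    planted_baseline_range: tuple[float, float] = (0.25, 0.6)
    antibodies: tuple[str, ...] = ("CD45", "MHC1")
    stained_mean: float = 100.0
    background_mean: float = 2.0
    stained_fraction: float = 1.0       # fraction of droplets that are stained cells
    adt_dispersion: float = 10.0        # antibody tags are far less overdispersed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.samples_per_condition < 1 or self.cells_per_block < 1:
            raise ValueError("all sizes must be positive")
        if self.dispersion <= 0 or self.adt_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if len(self.conditions) < 2:
            raise ValueError("at least two ordered conditions are required")
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise ValueError("stained_fraction must be in [0, 1]")
        for pattern in self.planted:
            if pattern.n_genes > self.n_genes:
                raise ValueError(
                    f"planted subset of {pattern.n_genes} genes exceeds {self.n_genes}"
                )

    @property
    def condition_series(self) -> ConditionSeries:
        return ConditionSeries(self.conditions)


def sample_negative_binomial(
    rng: np.random.Generator, mean, shape: float, size=None
) -> np.ndarray:
    """Gamma-Poisson draw: var = mean + mean^2 / shape."""
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) / shape, size=size)
    return rng.poisson(lam)


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, AdtMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (ExpressionMatrix, AdtMatrix, annotation, ground truth).

    The annotation holds cell_id, sample_id, condition, cluster and a
    ``stained`` flag; the ground-truth table lists each planted gene with its
    pattern index, fold change and target conditions/clusters.  Identical
    seeds give byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    clusters, conditions = spec.clusters, spec.conditions
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sigma, n_genes)

    lo, hi = spec.planted_baseline_range
    eligible = list(np.flatnonzero((baseline >= lo) & (baseline <= hi)))
    fold = np.ones((n_genes, len(clusters), len(conditions)))
    truth_rows = []
    for pat_idx, pattern in enumerate(spec.planted):
        if pattern.n_genes > len(eligible):
            raise ValueError(
                f"planted pattern {pat_idx} needs {pattern.n_genes} genes but only "
                f"{len(eligible)} remain in the baseline window {spec.planted_baseline_range}"
            )
        chosen = rng.choice(eligible, size=pattern.n_genes, replace=False)
        eligible = [g for g in eligible if g not in set(chosen)]
        target_conditions = pattern.conditions or (conditions[-1],)
        target_clusters = pattern.clusters or clusters
        ci = [clusters.index(c) for c in target_clusters]
        ti = [conditions.index(t) for t in target_conditions]
        fold[np.ix_(sorted(chosen), ci, ti)] *= pattern.fold_change
        for g in sorted(chosen):
            truth_rows.append({
                "gene": gene_ids[g],
                "pattern": pat_idx,
                "fold_change": pattern.fold_change,
                "conditions": ",".join(target_conditions),
                "clusters": ",".join(target_clusters),
                "baseline_mean": baseline[g],
            })
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "pattern", "fold_change", "conditions", "clusters", "baseline_mean"],
    )

    blocks = []
    meta_rows = []
    cell_counter = 0
    for t_idx, cond in enumerate(conditions):
        for s in range(spec.samples_per_condition):
            sample_id = f"{cond}_s{s}"
            for c_idx, cluster in enumerate(clusters):
                n = spec.cells_per_block
                mu = baseline * fold[:, c_idx, t_idx]
                counts = sample_negative_binomial(
                    rng, mu[:, None], spec.dispersion, size=(n_genes, n)
                )
                blocks.append(counts.astype(np.int32))
                for _ in range(n):
                    meta_rows.append((f"cell{cell_counter:06d}", sample_id, cond, cluster))
                    cell_counter += 1
    counts = np.concatenate(blocks, axis=1)
    annotation = pd.DataFrame(
        meta_rows, columns=["cell_id", "sample_id", "condition", "cluster"]
    )
    rna = ExpressionMatrix(
        counts=counts, gene_ids=gene_ids, cell_ids=list(annotation["cell_id"])
    )

    n_cells = counts.shape[1]
    stained = rng.random(n_cells) < spec.stained_fraction
    adt_counts = np.empty((len(spec.antibodies), n_cells), dtype=np.int32)
    for a in range(len(spec.antibodies)):
        mean = np.where(stained, spec.stained_mean, spec.background_mean)
        adt_counts[a] = sample_negative_binomial(rng, mean, spec.adt_dispersion)
    adt = AdtMatrix(
        counts=adt_counts,
        antibody_ids=list(spec.antibodies),
        cell_ids=list(annotation["cell_id"]),
    )
    annotation["stained"] = stained
    return rna, adt, annotation, truth


def generate_adt_mixture(
    n_stained: int = 500,
    n_background: int = 500,
    stained_mean: float = 100.0,
    background_mean: float = 2.0,
    dispersion: float = 10.0,
    antibodies: tuple[str, ...] = ("CD45", "MHC1"),
    seed: int = 0,
) -> tuple[AdtMatrix, np.ndarray]:
    """Bimodal antibody fixture for cell-calling tests.

    Returns the ADT matrix (stained cells first) and the boolean ground-truth
    stained labels.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.ones(n_stained, dtype=bool), np.zeros(n_background, dtype=bool)]
    )
    mean = np.where(labels, stained_mean, background_mean)
    counts = np.stack(
        [sample_negative_binomial(rng, mean, dispersion) for _ in antibodies]
    ).astype(np.int32)
    cell_ids = [f"drop{i:05d}" for i in range(len(labels))]
    return AdtMatrix(counts=counts, antibody_ids=list(antibodies), cell_ids=cell_ids), labels


def truth_eval(ranked_genes, truth: pd.DataFrame, k: int) -> float:
    """Fraction of planted genes among the top k of a ranking.

    ``ranked_genes`` is an ordered iterable of gene ids (e.g. the ``gene``
    column of :func:`geneflows.flows.top_genes`).
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    planted = set(truth["gene"])
    if not planted:
        raise ValueError("ground truth lists no planted genes")
    top = list(ranked_genes)[:k]
    return len(planted & set(top)) / len(planted)


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Materialize a generated dataset in standard on-disk formats.

    Writes rna/ and adt/ Matrix Market directories, metadata.tsv and
    ground_truth.tsv under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rna, adt, annotation, truth = generate(spec)
    write_expression(rna, out_dir / "rna", format="mtx")
    write_expression(
        ExpressionMatrix(counts=adt.counts, gene_ids=adt.antibody_ids,
                         cell_ids=adt.cell_ids),
        out_dir / "adt", format="mtx",
    )
    annotation.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return out_dir
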