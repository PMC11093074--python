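"""Per-cell module scoring against expression-matched control genes.

The score of a gene set in a cell is the mean normalized expression of the
set genes minus the mean normalized expression of control genes.  Controls
are drawn per set gene from that gene's average-expression bin (the gene-mean
distribution is cut into ``n_bins`` equal-occupancy bins over the scored
cells), ``n_ctrl`` controls per set gene, excluding the set genes themselves.
Matching controls on average expression removes the depth/abundance component
of the signal, so the score is centred near 0 for a random set and measures
coordinated up-regulation of the set.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .ingest import DEFAULT_TARGET_SUM, ExpressionMatrix, normalize_counts

log = logging.getLogger(__name__)

__all__ = ["module_score", "module_scores"]


def _expression_bins(gene_means: np.ndarray, gene_ids: list[str], n_bins: int) -> np.ndarray:
    """Equal-occupancy bin index per gene, by rank of mean expression.

    Rank ties are resolved by gene id so binning is deterministic.
    """
    order = np.lexsort((np.asarray(gene_ids, dtype=object), gene_means))
    ranks = np.empty(len(gene_means), dtype=np.int64)
    ranks[order] = np.arange(len(gene_means))
    return (ranks * n_bins) // len(gene_means)


def module_score(
    rna: ExpressionMatrix,
    gene_set: Iterable[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    cells: np.ndarray | None = None,
    normalized: np.ndarray | None = None,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> pd.Series:
    """Module score of one gene set for every scored cell.

    ``cells`` optionally restricts scoring to a boolean mask of cells; gene
    means and bins are computed on the scored cells only, so appending
    unscored cells leaves the result unchanged.  ``normalized`` may supply an
    already-normalized genes x cells array (same shape as the counts);
    otherwise counts are normalized to ``target_sum`` per cell and log1p'ed,
    matching the pseudobulk normalization.  The control draw is seeded and
    fully deterministic.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be positive")
    gene_set = set(gene_set)
    present = [g for g in rna.gene_ids if g in gene_set]
    if not present:
        raise ValueError(
            f"gene set is disjoint from the matrix; missing symbols: "
            f"{sorted(gene_set)[:10]}"
        )
    missing = gene_set - set(present)
    if missing:
        log.info("module_score: %d set genes absent from the matrix", len(missing))

    norm = normalized if normalized is not None else normalize_counts(
        rna.counts, target_sum=target_sum
    )
    cell_ids = rna.cell_ids
    if cells is not None:
        cells = np.asarray(cells, dtype=bool)
        norm = norm[:, cells]
        cell_ids = [c for c, keep in zip(cell_ids, cells) if keep]
    if norm.shape[1] == 0:
        raise ValueError("no cells to score")

    gene_means = norm.mean(axis=1)
    bins = _expression_bins(gene_means, rna.gene_ids, n_bins)
    gene_pos = {g: i for i, g in enumerate(rna.gene_ids)}
    set_idx = np.array([gene_pos[g] for g in present])
    in_set = np.zeros(len(rna.gene_ids), dtype=bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    control_rows: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            pool = np.flatnonzero(~in_set)
            if pool.size == 0:
                raise ValueError("no control genes available outside the set")
        replace = pool.size < n_ctrl
        control_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
    controls = np.concatenate(control_rows)

    score = norm[set_idx].mean(axis=0) - norm[controls].mean(axis=0)
    return pd.Series(score, index=cell_ids, name="score")


def module_scores(
    rna: ExpressionMatrix,
    collection: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    cells: np.ndarray | None = None,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> pd.DataFrame:
    """Module scores for every set in a collection (cells x sets).

    Normalization is computed once; each set gets its own seeded control
    draw (seed offset by the set's rank so sets are independent but the
    whole table is reproducible).
    """
    norm = normalize_counts(rna.counts, target_sum=target_sum)
    out = {}
    for offset, name in enumerate(sorted(collection)):
        out[name] = module_score(
            rna, collection[name], n_bins=n_bins, n_ctrl=n_ctrl,
            seed=seed + offset, cells=cells, normalized=norm,
        )
    return pd.DataFrame(out)
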