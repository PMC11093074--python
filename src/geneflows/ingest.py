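"""Readers, antibody-based cell calling, filtering and pseudobulk aggregation.

This module turns raw gene x cell (and antibody x cell) count matrices plus a
per-cell annotation into a :class:`GroupedProfile`: per-gene mean normalized
expression, fraction of expressing cells and cell count for every
(cluster, condition) group.  The grouped profile is the input to
fuzzification and flow analysis.

Cell calling follows the surface-antibody route: a droplet is kept as a cell
when ALL required antibodies reach their thresholds, regardless of its RNA
content.  This deliberately rescues transcriptionally quiet cell types (e.g.
granulocytes with low RNA abundance) that a plain per-cell UMI cutoff would
discard; ``umi_filter`` provides that conventional cutoff for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .enrich import GeneSetCollection

log = logging.getLogger(__name__)

DEFAULT_TARGET_SUM = 10_000.0

__all__ = [
    "ConditionSeries",
    "ExpressionMatrix",
    "AdtMatrix",
    "GroupedProfile",
    "read_expression",
    "write_expression",
    "read_adt",
    "read_annotation",
    "read_gmt",
    "normalize_counts",
    "background_quantile_thresholds",
    "call_cells",
    "umi_filter",
    "downsample_and_pool",
    "pseudobulk",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ConditionSeries:
    """Explicitly ordered condition labels (the comparison axis of a flow).

    The order is declared once and is immutable; every flow pattern (e.g.
    "final level above all prior levels") is interpreted along this order.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(c) for c in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a condition series needs at least two conditions")
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


def _min_entry(counts) -> float:
    if sp.issparse(counts):
        return float(counts.data.min()) if counts.nnz else 0.0
    return float(np.min(counts)) if counts.size else 0.0


@dataclass
class ExpressionMatrix:
    """Nonnegative integer counts, genes x cells, with unique id lists."""

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene ids")
        self.cell_ids = _check_ids(self.cell_ids, "cell ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if _min_entry(self.counts) < 0:
            raise ValueError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        counts = self.counts.tocsc()[:, mask] if sp.issparse(self.counts) else self.counts[:, mask]
        return type(self)(
            counts=counts,
            gene_ids=list(self.gene_ids),
            cell_ids=[c for c, keep in zip(self.cell_ids, mask) if keep],
        )


@dataclass
class AdtMatrix:
    """Antibody-capture counts, antibodies x cells."""

    counts: np.ndarray | sp.spmatrix
    antibody_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.antibody_ids = _check_ids(self.antibody_ids, "antibody ids")
        self.cell_ids = _check_ids(self.cell_ids, "cell ids")
        if self.counts.shape != (len(self.antibody_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.antibody_ids)} antibodies x {len(self.cell_ids)} cells"
            )
        if _min_entry(self.counts) < 0:
            raise ValueError("counts contain negative entries")

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class GroupedProfile:
    """Per-gene summaries for every (cluster, condition) group.

    ``mean_expr`` and ``frac_expr`` are genes x groups frames whose columns
    are a (cluster, condition) MultiIndex; ``n_cells`` maps each group to its
    cell count.  Groups with zero cells are omitted (and logged) rather than
    reported.
    """

    mean_expr: pd.DataFrame
    frac_expr: pd.DataFrame
    n_cells: pd.Series
    conditions: ConditionSeries

    def __post_init__(self) -> None:
        if not self.mean_expr.columns.equals(self.frac_expr.columns):
            raise ValueError("mean_expr and frac_expr must share group columns")
        if not self.mean_expr.index.equals(self.frac_expr.index):
            raise ValueError("mean_expr and frac_expr must share gene index")
        if ((self.frac_expr < 0) | (self.frac_expr > 1)).any().any():
            raise ValueError("frac_expr outside [0, 1]")
        if not np.isfinite(self.mean_expr.to_numpy()).all():
            raise ValueError("mean_expr contains non-finite values")
        if (self.n_cells < 1).any():
            raise ValueError("reported groups must contain at least one cell")

    @property
    def genes(self) -> list[str]:
        return list(self.mean_expr.index)

    @property
    def clusters(self) -> list[str]:
        return list(dict.fromkeys(self.mean_expr.columns.get_level_values(0)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, cluster, condition, mean_expr, frac_expr, n_cells."""
        mean_long = self.mean_expr.stack([0, 1], future_stack=True).rename("mean_expr")
        frac_long = self.frac_expr.stack([0, 1], future_stack=True).rename("frac_expr")
        out = pd.concat([mean_long, frac_long], axis=1).reset_index()
        out.columns = ["gene", "cluster", "condition", "mean_expr", "frac_expr"]
        out["n_cells"] = [
            int(self.n_cells[(c, t)]) for c, t in zip(out["cluster"], out["condition"])
        ]
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, conditions: ConditionSeries) -> "GroupedProfile":
        mean = frame.pivot_table(
            index="gene", columns=["cluster", "condition"], values="mean_expr", sort=False
        )
        frac = frame.pivot_table(
            index="gene", columns=["cluster", "condition"], values="frac_expr", sort=False
        )
        n_cells = (
            frame.drop_duplicates(["cluster", "condition"])
            .set_index(["cluster", "condition"])["n_cells"]
            .astype(int)
        )
        return cls(mean_expr=mean, frac_expr=frac.loc[mean.index, mean.columns],
                   n_cells=n_cells, conditions=conditions)


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_column(path: Path) -> list[str]:
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return list(table.iloc[:, 0])


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    matrix_path = path / "matrix.mtx"
    if not matrix_path.exists():
        candidates = sorted(path.glob("*.mtx"))
        if not candidates:
            raise FileNotFoundError(f"no .mtx file in {path}")
        matrix_path = candidates[0]
    features_path = path / "features.tsv"
    if not features_path.exists():
        features_path = path / "genes.tsv"
    barcodes_path = path / "barcodes.tsv"
    for p in (features_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"missing companion id file {p}")
    try:
        counts = scipy.io.mmread(matrix_path)
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {matrix_path}: {exc}") from exc
    genes = _read_id_column(features_path)
    cells = _read_id_column(barcodes_path)
    if counts.shape == (len(genes), len(cells)):
        pass
    elif counts.shape == (len(cells), len(genes)):
        log.info("matrix %s stored cells x genes; transposing to genes x cells", matrix_path)
        counts = counts.T
    else:
        raise ValueError(
            f"matrix shape {counts.shape} matches neither {len(genes)} genes x "
            f"{len(cells)} cells nor its transpose"
        )
    counts = counts.tocsr()
    if counts.nnz and counts.data.min() < 0:
        raise ValueError(f"{matrix_path}: negative counts are not allowed")
    return ExpressionMatrix(counts=counts.astype(np.int64), gene_ids=genes, cell_ids=cells)


def _read_dense_csv(path: Path) -> ExpressionMatrix:
    try:
        table = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    values = table.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in the count matrix")
    if values.size and np.min(values) < 0:
        raise ValueError(f"{path}: negative counts are not allowed")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: counts must be integers")
    return ExpressionMatrix(
        counts=values.astype(np.int64),
        gene_ids=list(table.index.astype(str)),
        cell_ids=list(table.columns.astype(str)),
    )


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    ``format`` is ``"mtx"`` (a directory holding matrix.mtx + features.tsv +
    barcodes.tsv) or ``"csv"`` (dense, gene ids in the first column, cell ids
    in the header); when omitted it is inferred from the path.  Row/column
    orientation of Matrix Market input is auto-detected from the companion id
    files and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.is_dir() else "csv"
    if format == "mtx":
        return _read_mtx_dir(path)
    if format == "csv":
        return _read_dense_csv(path)
    raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "mtx") -> Path:
    """Write a count matrix so that :func:`read_expression` round-trips it."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        counts = matrix.counts if sp.issparse(matrix.counts) else sp.coo_matrix(matrix.counts)
        scipy.io.mmwrite(path / "matrix.mtx", counts, field="integer")
        pd.Series(matrix.gene_ids).to_csv(path / "features.tsv", sep="\t",
                                          header=False, index=False)
        pd.Series(matrix.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                          header=False, index=False)
        return path
    if format == "csv":
        frame = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
        frame.to_csv(path)
        return path
    raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")


def read_adt(path: str | Path, format: str | None = None) -> AdtMatrix:
    """Read an antibodies x cells capture-count matrix (same formats as RNA)."""
    em = read_expression(path, format=format)
    return AdtMatrix(counts=em.counts, antibody_ids=em.gene_ids, cell_ids=em.cell_ids)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata with columns cell_id, sample_id, condition, cluster."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    required = {"cell_id", "sample_id", "condition", "cluster"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if table["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell_id rows")
    return table


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-set collection from a GMT file."""
    return GeneSetCollection.from_gmt(path)


# ---------------------------------------------------------------------------
# cell calling and filtering


def background_quantile_thresholds(
    adt: AdtMatrix,
    antibodies: Iterable[str],
    background: np.ndarray,
    quantile: float = 0.99,
) -> dict[str, float]:
    """Per-antibody thresholds at a quantile of a declared background subset."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    background = np.asarray(background, dtype=bool)
    if background.shape != (len(adt.cell_ids),):
        raise ValueError("background mask length must equal the number of cells")
    if not background.any():
        raise ValueError("background subset is empty")
    dense = adt.dense()
    thresholds = {}
    for ab in antibodies:
        if ab not in adt.antibody_ids:
            raise ValueError(f"required antibody {ab!r} absent from the ADT matrix")
        row = dense[adt.antibody_ids.index(ab)]
        thresholds[ab] = float(np.quantile(row[background], quantile))
    return thresholds


def call_cells(
    adt: AdtMatrix,
    required_antibodies: Iterable[str],
    thresholds: Mapping[str, float] | None = None,
    *,
    background: np.ndarray | None = None,
    quantile: float = 0.99,
) -> np.ndarray:
    """Call cells from surface-antibody signal.

    A cell is called when its capture count is at or above the threshold for
    ALL required antibodies.  Thresholds are either explicit per antibody or
    derived as the ``quantile`` of a declared ``background`` subset of cells.
    RNA content plays no role here, so low-RNA cell types survive calling.
    """
    required = list(required_antibodies)
    if not required:
        raise ValueError("at least one required antibody is needed")
    missing = [ab for ab in required if ab not in adt.antibody_ids]
    if missing:
        raise ValueError(f"required antibodies absent from the ADT matrix: {missing}")
    if thresholds is None:
        if background is None:
            raise ValueError(
                "either explicit thresholds or a background subset (for the "
                "background-quantile rule) must be given"
            )
        thresholds = background_quantile_thresholds(adt, required, background, quantile)
    else:
        missing_thr = [ab for ab in required if ab not in thresholds]
        if missing_thr:
            raise ValueError(f"no threshold given for antibodies: {missing_thr}")
    dense = adt.dense()
    mask = np.ones(len(adt.cell_ids), dtype=bool)
    for ab in required:
        mask &= dense[adt.antibody_ids.index(ab)] >= thresholds[ab]
    log.info(
        "call_cells: %d / %d cells called with thresholds %s",
        int(mask.sum()), len(mask), {a: thresholds[a] for a in required},
    )
    return mask


def umi_filter(rna: ExpressionMatrix, cutoff: int) -> np.ndarray:
    """Conventional per-cell transcript filter: keep cells whose UMI total is
    at or above ``cutoff`` (boundary inclusive)."""
    if int(cutoff) != cutoff or cutoff < 1:
        raise ValueError("cutoff must be a positive integer")
    totals = np.asarray(rna.counts.sum(axis=0)).ravel()
    mask = totals >= cutoff
    log.info("umi_filter(cutoff=%d): %d / %d cells kept", cutoff, int(mask.sum()), len(mask))
    return mask


def downsample_and_pool(
    tables: Sequence[pd.DataFrame],
    n_per_sample: int,
    seed: int,
) -> pd.DataFrame:
    """Downsample each per-sample cell table to at most ``n_per_sample`` rows
    (uniformly, without replacement) and concatenate.

    Samples smaller than the cap contribute all their rows (with a warning);
    the pooled table preserves every input column, including sample ids.
    Identical seeds give identical selections.
    """
    if not tables:
        raise ValueError("no per-sample tables given")
    if int(n_per_sample) != n_per_sample or n_per_sample < 1:
        raise ValueError("n_per_sample must be a positive integer")
    rng = np.random.default_rng(seed)
    parts = []
    for i, table in enumerate(tables):
        n = len(table)
        if n <= n_per_sample:
            if n < n_per_sample:
                warnings.warn(
                    f"sample table {i} has {n} < {n_per_sample} rows; keeping all",
                    stacklevel=2,
                )
            parts.append(table)
        else:
            idx = np.sort(rng.choice(n, size=n_per_sample, replace=False))
            parts.append(table.iloc[idx])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# normalization and pseudobulk


def normalize_counts(counts, target_sum: float = DEFAULT_TARGET_SUM) -> np.ndarray:
    """Scale every cell to ``target_sum`` total counts, then log(1 + x).

    Cells with zero total stay all-zero.  Returns a dense float array,
    genes x cells.
    """
    dense = np.asarray(counts.todense()) if sp.issparse(counts) else np.asarray(counts)
    dense = dense.astype(float)
    totals = dense.sum(axis=0)
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0
    )
    return np.log1p(dense * scale[None, :])


def pseudobulk(
    rna: ExpressionMatrix,
    annotation: pd.DataFrame,
    conditions: ConditionSeries,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> GroupedProfile:
    """Aggregate normalized expression into per-(cluster, condition) summaries.

    For every gene and group: mean of per-cell normalized values, fraction of
    member cells with raw count > 0, and the cell count.  Groups with zero
    cells are omitted and logged; a condition declared in the series but
    absent from the annotation altogether is an error.
    """
    ann = annotation.set_index("cell_id")
    missing = [c for c in rna.cell_ids if c not in ann.index]
    if missing:
        raise ValueError(f"{len(missing)} cells lack annotation, e.g. {missing[:5]}")
    ann = ann.loc[rna.cell_ids]
    unknown = set(ann["condition"]) - set(conditions.labels)
    if unknown:
        raise ValueError(
            f"annotation conditions {sorted(unknown)} are not in the declared series "
            f"{conditions.labels}"
        )
    absent = [t for t in conditions.labels if t not in set(ann["condition"])]
    if absent:
        raise ValueError(f"declared conditions with no annotated cells: {absent}")

    norm = normalize_counts(rna.counts, target_sum=target_sum)
    raw = rna.dense()
    clusters = sorted(set(ann["cluster"]))
    cluster_arr = ann["cluster"].to_numpy()
    cond_arr = ann["condition"].to_numpy()

    columns, mean_cols, frac_cols, n_cells = [], [], [], {}
    for cluster in clusters:
        for cond in conditions.labels:
            member = (cluster_arr == cluster) & (cond_arr == cond)
            n = int(member.sum())
            if n == 0:
                log.info("pseudobulk: group (%s, %s) has no cells; omitted", cluster, cond)
                continue
            columns.append((cluster, cond))
            mean_cols.append(norm[:, member].mean(axis=1))
            frac_cols.append((raw[:, member] > 0).mean(axis=1))
            n_cells[(cluster, cond)] = n

    col_index = pd.MultiIndex.from_tuples(columns, names=["cluster", "condition"])
    mean_expr = pd.DataFrame(
        np.column_stack(mean_cols), index=rna.gene_ids, columns=col_index
    )
    frac_expr = pd.DataFrame(
        np.column_stack(frac_cols), index=rna.gene_ids, columns=col_index
    )
    return GroupedProfile(
        mean_expr=mean_expr,
        frac_expr=frac_expr,
        n_cells=pd.Series(n_cells),
        conditions=conditions,
    )
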