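"""End-to-end pipeline: ingest -> fuzzify -> flows -> enrich, with provenance.

A :class:`RunConfig` is a flat, YAML-serializable record of every input path,
parameter and seed; :func:`run_pipeline` executes the stages and writes all
tables, the Sankey documents and a run log (package and library versions,
parameters, input checksums).  Outputs are fully determined by config +
inputs + seeds — no hidden state, no timestamps — so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import crisp_overlap, hypergeom_enrichment, weighted_enrichment
from .flows import FlowPattern, compute_flows, export_sankey, top_genes
from .fuzzify import fit_fuzzy_spec, fuzzify
from .ingest import (
    ConditionSeries,
    call_cells,
    pseudobulk,
    read_adt,
    read_annotation,
    read_expression,
    read_gmt,
    umi_filter,
)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of a full run; round-trips through YAML unchanged."""

    rna_path: str
    meta_path: str
    out_dir: str
    conditions: tuple[str, ...]
    adt_path: str | None = None
    gmt_path: str | None = None
    call_antibodies: tuple[str, ...] = ()
    adt_quantile: float = 0.99
    umi_cutoff: int | None = None
    n_levels: int = 4
    quantiles: tuple[float, ...] | None = None
    min_frac: float = 0.01
    direction: str = "final_above_all_prior"
    min_final_level: str | None = "Medium"
    scope: str = "all_clusters"
    combiner: str = "product"
    top_k: int = 30
    enrich_mode: str = "crisp"
    crisp_threshold: float = 0.5
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("the ordered condition series must be declared")
        object.__setattr__(self, "conditions", tuple(str(c) for c in self.conditions))
        object.__setattr__(self, "call_antibodies", tuple(self.call_antibodies or ()))
        if self.quantiles is not None:
            object.__setattr__(self, "quantiles", tuple(float(q) for q in self.quantiles))
        ConditionSeries(self.conditions)  # validates length and uniqueness
        if self.enrich_mode not in ("crisp", "weighted"):
            raise ValueError("enrich_mode must be 'crisp' or 'weighted'")

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        return data

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        for key in ("conditions", "call_antibodies", "quantiles"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "conditions" not in data:
            raise ValueError(f"{path}: config is missing the condition series")
        return cls(**data)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _input_checksums(config: RunConfig) -> dict[str, str]:
    checksums = {}
    for label in ("rna_path", "adt_path", "meta_path", "gmt_path"):
        value = getattr(config, label)
        if value is None:
            continue
        path = Path(value)
        if path.is_dir():
            for sub in sorted(path.iterdir()):
                if sub.is_file():
                    checksums[f"{label}:{sub.name}"] = _sha256(sub)
        elif path.is_file():
            checksums[label] = _sha256(path)
    return checksums


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Execute ingest -> fuzzify -> flows -> enrich and write all outputs.

    Returns the output directory.  Any stage error aborts with the stage name
    and its context.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = ConditionSeries(config.conditions)

    # --- ingest -----------------------------------------------------------
    stage = _stage("ingest")
    rna = stage(read_expression, config.rna_path)
    annotation = stage(read_annotation, config.meta_path)
    kept_by_calling = None
    if config.adt_path and config.call_antibodies:
        adt = stage(read_adt, config.adt_path)
        if adt.cell_ids != rna.cell_ids:
            raise RuntimeError(
                "pipeline stage 'ingest' failed: ADT and RNA cell ids differ"
            )
        totals = np.asarray(rna.counts.sum(axis=0)).ravel()
        background = totals < np.quantile(totals, 0.1)  # lowest-RNA droplets as background
        mask = stage(
            call_cells, adt, config.call_antibodies,
            background=background, quantile=config.adt_quantile,
        )
        kept_by_calling = int(mask.sum())
        rna = rna.subset_cells(mask)
    if config.umi_cutoff is not None:
        mask = stage(umi_filter, rna, config.umi_cutoff)
        rna = rna.subset_cells(mask)
    annotation = annotation[annotation["cell_id"].isin(set(rna.cell_ids))]
    profile = stage(pseudobulk, rna, annotation, series)
    profile.to_frame().to_csv(out_dir / "grouped_profile.tsv", sep="\t",
                              index=False, float_format=FLOAT_FORMAT)

    # --- fuzzify ----------------------------------------------------------
    stage = _stage("fuzzify")
    spec = stage(fit_fuzzy_spec, profile, config.n_levels, config.quantiles)
    (out_dir / "fuzzy_spec.yaml").write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))
    mu = stage(fuzzify, profile, spec, config.min_frac)
    mu.to_frame().to_csv(out_dir / "memberships.tsv", sep="\t",
                         index=False, float_format=FLOAT_FORMAT)

    # --- flows ------------------------------------------------------------
    stage = _stage("flows")
    pattern = FlowPattern(direction=config.direction,
                          min_final_level=config.min_final_level,
                          scope=config.scope)
    result = stage(compute_flows, mu, pattern, config.combiner)
    result.weights.to_csv(out_dir / "flow_weights.tsv", sep="\t",
                          index=False, float_format=FLOAT_FORMAT)
    gene_table = result.per_cluster.copy()
    gene_table.insert(0, "combined", result.membership)
    gene_table.rename_axis("gene").reset_index().to_csv(
        out_dir / "gene_membership.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    ranking = top_genes(result.membership, config.top_k)
    ranking.to_csv(out_dir / "top_genes.tsv", sep="\t", index=False,
                   float_format=FLOAT_FORMAT)
    for cluster in mu.clusters:
        doc = stage(export_sankey, mu, cluster, result.selected_paths)
        (out_dir / f"sankey_{cluster}.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True)
        )

    # --- enrich -----------------------------------------------------------
    if config.gmt_path:
        stage = _stage("enrich")
        collection = stage(read_gmt, config.gmt_path)
        universe = list(result.membership.index)
        if config.enrich_mode == "crisp":
            hits = stage(crisp_overlap, result.membership, config.crisp_threshold)
            if hits:
                table = stage(hypergeom_enrichment, hits, collection, universe)
            else:
                log.warning("no genes reach the crisp membership threshold; "
                            "enrichment table left empty")
                table = pd.DataFrame(columns=["set", "size", "overlap", "score", "p", "q"])
        else:
            table = stage(weighted_enrichment, result.membership, collection,
                          n_perm=config.n_perm, seed=config.seed)
        table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False,
                     float_format=FLOAT_FORMAT)

    # --- provenance -------------------------------------------------------
    versions = {
        "geneflows": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    log_doc = {
        "config": config.to_dict(),
        "versions": versions,
        "input_checksums": _input_checksums(config),
        "n_cells_after_filters": len(rna.cell_ids),
        "n_cells_called": kept_by_calling,
        "n_genes_fuzzified": mu.n_genes,
        "selected_paths": ["-".join(map(str, p)) for p in result.selected_paths],
        "fuzzy_anchors": list(spec.anchors),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log_doc, indent=1, sort_keys=True))
    config.to_yaml(out_dir / "config.yaml")
    log.info("pipeline finished; outputs in %s", out_dir)
    return out_dir
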