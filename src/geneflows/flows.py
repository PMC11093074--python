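"""Level paths, flow weights, pattern selection and membership ranking.

A *level path* assigns one expression level to each condition of the ordered
series; with L levels and T conditions there are L^T paths.  A gene belongs
to a path with the product (or minimum) of its level memberships along the
path; a *flow weight* is the sum of these path memberships over genes, the
quantity drawn as ribbon width in an alluvial rendering.

Under the product combiner the paths partition each gene's unit mass:
summing a gene's membership over all L^T paths factorizes into
prod_t (sum_l mu[g,t,l]) = 1, so total flow weight per cluster equals the
number of genes exactly.  The same factorization computes all path weights
without enumerating paths gene by gene.

Flow *patterns* are predicates over paths (e.g. "final level strictly above
every earlier level, at least Medium"); a gene's combined membership in the
selected flows sums its memberships over the selected (disjoint) paths and is
combined across clusters by fuzzy AND (minimum, "in all clusters") or fuzzy
OR (maximum, "in any cluster").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fuzzify import MembershipTensor

log = logging.getLogger(__name__)

LevelPath = tuple[int, ...]

DIRECTIONS = (
    "final_above_all_prior",
    "final_below_all_prior",
    "nondecreasing",
    "nonincreasing",
    "constant",
    "any",
)

DEFAULT_PATH_CAP = 10 ** 6

__all__ = [
    "LevelPath",
    "FlowPattern",
    "FlowResult",
    "enumerate_paths",
    "path_membership",
    "flow_weights",
    "select_flows",
    "per_cluster_membership",
    "combined_gene_membership",
    "top_genes",
    "compute_flows",
    "export_sankey",
]


@dataclass(frozen=True)
class FlowPattern:
    """Predicate over level paths plus a cross-cluster combination scope.

    ``direction`` is one of ``final_above_all_prior`` (the final condition's
    level strictly exceeds every earlier one), ``final_below_all_prior``,
    ``nondecreasing``, ``nonincreasing``, ``constant`` or ``any``.
    ``min_final_level`` (label or index) additionally requires the final
    level to reach at least that level.  ``scope`` decides how per-cluster
    memberships combine: ``all_clusters`` (minimum), ``any_cluster``
    (maximum), or a single cluster label.
    """

    direction: str = "final_above_all_prior"
    min_final_level: str | int | None = None
    scope: str = "all_clusters"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; choose from {DIRECTIONS}"
            )


@dataclass
class FlowResult:
    """Flow weights, the selected path set, and per-gene memberships."""

    weights: pd.DataFrame           # columns: cluster, path, weight, selected
    selected_paths: list[LevelPath]
    per_cluster: pd.DataFrame       # genes x clusters membership in the selected set
    membership: pd.Series           # combined M(g) per gene
    pattern: FlowPattern


def enumerate_paths(n_levels: int, n_conditions: int,
                    cap: int = DEFAULT_PATH_CAP) -> list[LevelPath]:
    """All L^T level paths in lexicographic order."""
    if n_levels < 2 or n_conditions < 2:
        raise ValueError("need at least two levels and two conditions")
    total = n_levels ** n_conditions
    if total > cap:
        raise ValueError(
            f"{n_levels}^{n_conditions} = {total} paths exceed the cap {cap}; "
            "restrict enumeration with a pattern or lower L/T"
        )
    return list(itertools.product(range(n_levels), repeat=n_conditions))


def _validate_path(path: Sequence[int], n_levels: int, n_conditions: int) -> LevelPath:
    path = tuple(int(l) for l in path)
    if len(path) != n_conditions:
        raise ValueError(f"path length {len(path)} != {n_conditions} conditions")
    if any(l < 0 or l >= n_levels for l in path):
        raise ValueError(f"path {path} has level indices outside [0, {n_levels - 1}]")
    return path


def _path_memberships_all_genes(
    mu_cluster: np.ndarray, paths: Sequence[LevelPath], combiner: str
) -> np.ndarray:
    """Membership of every gene in each path; mu_cluster is (G, T, L)."""
    n_genes, n_conditions, _ = mu_cluster.shape
    out = np.empty((n_genes, len(paths)))
    for j, path in enumerate(paths):
        picked = mu_cluster[:, np.arange(n_conditions), path]  # (G, T)
        out[:, j] = picked.prod(axis=1) if combiner == "product" else picked.min(axis=1)
    return out


def _check_combiner(combiner: str) -> None:
    if combiner not in ("product", "min"):
        raise ValueError(f"unknown combiner {combiner!r}; choose 'product' or 'min'")


def path_membership(
    mu: MembershipTensor,
    gene: str,
    cluster: str,
    path: Sequence[int],
    combiner: str = "product",
) -> float:
    """Membership of one gene in one level path within one cluster."""
    _check_combiner(combiner)
    g = mu.gene_index(gene)
    c = mu.cluster_index(cluster)
    path = _validate_path(path, len(mu.levels), len(mu.conditions))
    picked = mu.mu[g, c, np.arange(len(path)), list(path)]
    return float(picked.prod() if combiner == "product" else picked.min())


def flow_weights(
    mu: MembershipTensor,
    cluster: str,
    combiner: str = "product",
    cap: int = DEFAULT_PATH_CAP,
) -> pd.Series:
    """Weight of every level path in a cluster: sum over genes of path
    membership.

    With the product combiner the weights are computed by the factorized
    recursion (an iterated outer product over conditions), and their total
    equals the number of genes exactly.  Indexed by path tuples in
    lexicographic order.
    """
    _check_combiner(combiner)
    c = mu.cluster_index(cluster)
    n_levels, n_conditions = len(mu.levels), len(mu.conditions)
    paths = enumerate_paths(n_levels, n_conditions, cap=cap)
    mu_c = mu.mu[:, c]  # (G, T, L)
    if combiner == "product":
        acc = mu_c[:, 0, :]  # (G, L)
        for t in range(1, n_conditions):
            acc = (acc[:, :, None] * mu_c[:, t, None, :]).reshape(mu.n_genes, -1)
        weights = acc.sum(axis=0)
    else:
        weights = _path_memberships_all_genes(mu_c, paths, combiner).sum(axis=0)
    return pd.Series(weights, index=pd.Index(paths, name="path", tupleize_cols=False))


def select_flows(
    pattern: FlowPattern,
    n_levels: int,
    n_conditions: int,
    levels: Sequence[str] | None = None,
    cap: int = DEFAULT_PATH_CAP,
) -> list[LevelPath]:
    """Level paths satisfying a pattern predicate.

    Cluster scoping does not apply here (it acts when gene memberships are
    combined across clusters); this is purely a predicate over paths.
    """
    min_level = None
    if pattern.min_final_level is not None:
        if isinstance(pattern.min_final_level, (int, np.integer)):
            min_level = int(pattern.min_final_level)
            if not 0 <= min_level < n_levels:
                raise ValueError(f"min_final_level index {min_level} out of range")
        else:
            if levels is None:
                raise ValueError("level labels are needed to resolve a named level")
            if pattern.min_final_level not in levels:
                raise ValueError(
                    f"unknown level {pattern.min_final_level!r}; levels are {tuple(levels)}"
                )
            min_level = list(levels).index(pattern.min_final_level)

    def keep(path: LevelPath) -> bool:
        final = path[-1]
        if min_level is not None and final < min_level:
            return False
        if pattern.direction == "final_above_all_prior":
            return all(final > l for l in path[:-1])
        if pattern.direction == "final_below_all_prior":
            return all(final < l for l in path[:-1])
        if pattern.direction == "nondecreasing":
            return all(a <= b for a, b in zip(path, path[1:]))
        if pattern.direction == "nonincreasing":
            return all(a >= b for a, b in zip(path, path[1:]))
        if pattern.direction == "constant":
            return len(set(path)) == 1
        return True  # "any"

    return [p for p in enumerate_paths(n_levels, n_conditions, cap=cap) if keep(p)]


def per_cluster_membership(
    mu: MembershipTensor,
    paths: Iterable[Sequence[int]],
    combiner: str = "product",
) -> pd.DataFrame:
    """Per-gene membership in a path set, per cluster (genes x clusters).

    Paths are disjoint events on the level scale, so the membership in the
    set is the sum of path memberships; under the product combiner it is at
    most 1.
    """
    _check_combiner(combiner)
    paths = [_validate_path(p, len(mu.levels), len(mu.conditions)) for p in paths]
    if not paths:
        raise ValueError("empty path selection")
    if len(set(paths)) != len(paths):
        raise ValueError("selected paths must be distinct")
    data = {}
    for c, cluster in enumerate(mu.clusters):
        data[cluster] = _path_memberships_all_genes(mu.mu[:, c], paths, combiner).sum(axis=1)
    return pd.DataFrame(data, index=mu.genes)


def combined_gene_membership(
    mu: MembershipTensor,
    paths: Iterable[Sequence[int]],
    scope: str = "all_clusters",
    combiner: str = "product",
) -> pd.Series:
    """Combined membership M(g) of each gene in the selected flows.

    ``all_clusters`` takes the minimum over clusters (fuzzy AND: the flow
    must hold in every cluster), ``any_cluster`` the maximum; a cluster label
    picks that cluster alone.
    """
    table = per_cluster_membership(mu, paths, combiner=combiner)
    if scope == "all_clusters":
        combined = table.min(axis=1)
    elif scope == "any_cluster":
        combined = table.max(axis=1)
    elif scope in table.columns:
        combined = table[scope]
    else:
        raise ValueError(
            f"scope {scope!r} is neither 'all_clusters', 'any_cluster' nor a cluster label"
        )
    combined.name = "membership"
    return combined


def top_genes(membership: pd.Series, k: int) -> pd.DataFrame:
    """The k genes with highest combined membership.

    Ties are broken by gene id (lexicographic), so rankings are
    deterministic.  Returns a two-column frame (gene, membership).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    table = membership.rename("membership").rename_axis("gene").reset_index()
    table = table.sort_values(["membership", "gene"], ascending=[False, True],
                              kind="mergesort")
    return table.head(min(k, len(table))).reset_index(drop=True)


def compute_flows(
    mu: MembershipTensor,
    pattern: FlowPattern,
    combiner: str = "product",
    cap: int = DEFAULT_PATH_CAP,
) -> FlowResult:
    """Full flow analysis: weights per (cluster, path), pattern selection and
    combined per-gene memberships."""
    selected = select_flows(pattern, len(mu.levels), len(mu.conditions),
                            levels=mu.levels, cap=cap)
    selected_set = set(selected)
    frames = []
    for cluster in mu.clusters:
        w = flow_weights(mu, cluster, combiner=combiner, cap=cap)
        frames.append(pd.DataFrame({
            "cluster": cluster,
            "path": ["-".join(str(l) for l in p) for p in w.index],
            "weight": w.to_numpy(),
            "selected": [p in selected_set for p in w.index],
        }))
    per_cluster = per_cluster_membership(mu, selected, combiner=combiner)
    membership = combined_gene_membership(mu, selected, scope=pattern.scope,
                                          combiner=combiner)
    return FlowResult(
        weights=pd.concat(frames, ignore_index=True),
        selected_paths=selected,
        per_cluster=per_cluster,
        membership=membership,
        pattern=pattern,
    )


def export_sankey(
    mu: MembershipTensor,
    cluster: str,
    selected_paths: Iterable[Sequence[int]] | None = None,
) -> dict:
    """Nodes/links description of one cluster's flows for alluvial plotting.

    Nodes are (condition, level) with throughput sum_g mu[g,t,l]; links carry
    the product-combiner marginal weight between consecutive conditions,
    sum_g mu[g,t,l] * mu[g,t+1,l'].  Links lying on a selected path's
    consecutive level pair are flagged for highlighting.  Node throughputs at
    each condition sum to the gene count, and the links out of a node sum to
    its throughput.
    """
    c = mu.cluster_index(cluster)
    mu_c = mu.mu[:, c]  # (G, T, L)
    n_conditions, n_levels = len(mu.conditions), len(mu.levels)
    selected = set()
    if selected_paths is not None:
        for p in selected_paths:
            p = _validate_path(p, n_levels, n_conditions)
            selected.update(
                (t, p[t], p[t + 1]) for t in range(n_conditions - 1)
            )

    def node_id(t: int, l: int) -> str:
        return f"{mu.conditions.labels[t]}|{mu.levels[l]}"

    nodes = []
    throughput = mu_c.sum(axis=0)  # (T, L)
    for t in range(n_conditions):
        for l in range(n_levels):
            nodes.append({
                "id": node_id(t, l),
                "condition": mu.conditions.labels[t],
                "level": mu.levels[l],
                "throughput": float(throughput[t, l]),
            })
    links = []
    for t in range(n_conditions - 1):
        pair = np.einsum("gl,gm->lm", mu_c[:, t], mu_c[:, t + 1])
        for l in range(n_levels):
            for m in range(n_levels):
                links.append({
                    "source": node_id(t, l),
                    "target": node_id(t + 1, m),
                    "weight": float(pair[l, m]),
                    "selected": (t, l, m) in selected,
                })
    return {
        "cluster": cluster,
        "conditions": list(mu.conditions.labels),
        "levels": list(mu.levels),
        "n_genes": mu.n_genes,
        "nodes": nodes,
        "links": links,
    }
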