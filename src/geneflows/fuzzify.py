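"""Fuzzification of grouped expression into ordered linguistic levels.

A :class:`FuzzySpec` names L ordered expression levels (default NotExpressed,
Low, Medium, High) and pins each to an anchor value on the normalized
log-expression scale, with the first anchor fixed at 0.  Triangular
membership functions peak at their anchor and decline linearly to zero at the
neighbouring anchors, so for any nonnegative input the L memberships form a
partition of unity: they are nonnegative and sum to exactly 1.  Inputs at or
below the first anchor belong fully to the lowest level; inputs at or beyond
the last anchor belong fully to the highest.

Anchors are fitted globally, from quantiles of the positive group means
pooled over all (cluster, condition) groups, so that a level means the same
thing in every cluster and condition — a prerequisite for comparing flows
across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import ConditionSeries, GroupedProfile

log = logging.getLogger(__name__)

DEFAULT_LEVELS = ("NotExpressed", "Low", "Medium", "High")
DEFAULT_QUANTILES = (0.25, 0.5, 0.9)

__all__ = [
    "FuzzySpec",
    "MembershipTensor",
    "fit_fuzzy_spec",
    "triangular_memberships",
    "fuzzify",
]


@dataclass(frozen=True)
class FuzzySpec:
    """Ordered level labels with strictly increasing anchors (a_0 = 0)."""

    levels: tuple[str, ...]
    anchors: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(str(l) for l in self.levels)
        anchors = tuple(float(a) for a in self.anchors)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "anchors", anchors)
        if len(levels) < 2:
            raise ValueError("at least two levels are required")
        if len(set(levels)) != len(levels):
            raise ValueError("level labels must be unique")
        if len(anchors) != len(levels):
            raise ValueError("one anchor per level is required")
        if anchors[0] != 0.0:
            raise ValueError("the first anchor must be 0")
        if not all(a < b for a, b in zip(anchors, anchors[1:])):
            raise ValueError(f"anchors must be strictly increasing, got {anchors}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, level: str | int) -> int:
        if isinstance(level, (int, np.integer)):
            if not 0 <= level < self.n_levels:
                raise ValueError(f"level index {level} out of range")
            return int(level)
        if level not in self.levels:
            raise ValueError(f"unknown level {level!r}; levels are {self.levels}")
        return self.levels.index(level)

    def to_dict(self) -> dict:
        return {"levels": list(self.levels), "anchors": [float(a) for a in self.anchors]}

    @classmethod
    def from_dict(cls, data: dict) -> "FuzzySpec":
        return cls(levels=tuple(data["levels"]), anchors=tuple(data["anchors"]))


@dataclass
class MembershipTensor:
    """Gene x cluster x condition x level membership values.

    ``mu[g, c, t, l]`` is the membership of gene g in level l for group
    (cluster c, condition t); memberships over levels sum to 1 for every
    (g, c, t).
    """

    mu: np.ndarray
    genes: list[str]
    clusters: list[str]
    conditions: ConditionSeries
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = (len(self.genes), len(self.clusters), len(self.conditions), len(self.levels))
        if self.mu.shape != expected:
            raise ValueError(f"mu shape {self.mu.shape} != {expected}")
        if np.min(self.mu) < -1e-12 or np.max(self.mu) > 1 + 1e-12:
            raise ValueError("memberships outside [0, 1]")
        sums = self.mu.sum(axis=-1)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ValueError("level memberships do not sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def cluster_index(self, cluster: str) -> int:
        try:
            return self.clusters.index(cluster)
        except ValueError:
            raise KeyError(f"unknown cluster {cluster!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, cluster, condition, level, membership."""
        index = pd.MultiIndex.from_product(
            [self.genes, self.clusters, self.conditions.labels, self.levels],
            names=["gene", "cluster", "condition", "level"],
        )
        return pd.DataFrame({"membership": self.mu.ravel()}, index=index).reset_index()


def fit_fuzzy_spec(
    profile: GroupedProfile,
    n_levels: int = 4,
    quantiles: Sequence[float] | None = None,
    levels: Sequence[str] | None = None,
) -> FuzzySpec:
    """Fit global anchors from quantiles of positive group means.

    The first anchor is 0; the remaining ``n_levels - 1`` anchors are the
    given quantiles (default ``(0.25, 0.5, 0.9)`` for four levels, scaled
    evenly otherwise) of the positive ``mean_expr`` values pooled over all
    groups.  Non-increasing anchors (too few distinct positive values) are
    rejected with advice to use fewer levels.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if quantiles is None:
        if n_levels == 4:
            quantiles = DEFAULT_QUANTILES
        else:
            quantiles = tuple(np.linspace(0, 1, n_levels + 1)[1:-1])
    quantiles = tuple(float(q) for q in quantiles)
    if len(quantiles) != n_levels - 1:
        raise ValueError(f"need {n_levels - 1} quantiles for {n_levels} levels")
    if not all(0 < q < 1 for q in quantiles):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    if not all(a < b for a, b in zip(quantiles, quantiles[1:])):
        raise ValueError("quantiles must be strictly increasing")

    values = profile.mean_expr.to_numpy().ravel()
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("profile has no positive mean expression values")
    anchors = (0.0,) + tuple(float(np.quantile(positive, q)) for q in quantiles)
    if not all(a < b for a, b in zip(anchors, anchors[1:])):
        raise ValueError(
            f"fitted anchors {anchors} are not strictly increasing; the profile has "
            "too few distinct positive values — use fewer levels"
        )
    if levels is None:
        levels = DEFAULT_LEVELS if n_levels == 4 else tuple(
            f"Level{i}" for i in range(n_levels)
        )
    log.info("fitted fuzzy anchors %s at quantiles %s", anchors, quantiles)
    return FuzzySpec(levels=tuple(levels), anchors=anchors)


def triangular_memberships(x: np.ndarray, anchors: Sequence[float]) -> np.ndarray:
    """Triangular level memberships for nonnegative inputs.

    Returns an array of shape ``x.shape + (L,)``.  mu_l peaks at anchor a_l
    and declines linearly to 0 at the adjacent anchors; values are clamped to
    full membership in the lowest/highest level beyond the anchor range.  The
    memberships at any x sum to 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size and np.min(x) < 0:
        raise ValueError("expression values must be nonnegative")
    anchors = np.asarray(anchors, dtype=float)
    n_levels = len(anchors)
    clamped = np.clip(x, anchors[0], anchors[-1])
    idx = np.searchsorted(anchors, clamped, side="right") - 1
    idx = np.minimum(idx, n_levels - 2)
    left = anchors[idx]
    width = anchors[idx + 1] - left
    upper = (clamped - left) / width
    out = np.zeros(x.shape + (n_levels,), dtype=float)
    np.put_along_axis(out, idx[..., None], (1.0 - upper)[..., None], axis=-1)
    np.put_along_axis(out, (idx + 1)[..., None], upper[..., None], axis=-1)
    return out


def fuzzify(
    profile: GroupedProfile,
    spec: FuzzySpec,
    min_frac: float = 0.01,
) -> MembershipTensor:
    """Fuzzify grouped mean expression into a membership tensor.

    Genes expressed in fewer than ``min_frac`` of cells in EVERY group are
    dropped (logged) before fuzzification, so flows are not driven by
    noise-level genes; set ``min_frac=0`` to keep everything.
    """
    clusters = profile.clusters
    conditions = profile.conditions
    expected = pd.MultiIndex.from_product([clusters, conditions.labels])
    missing = [col for col in expected if col not in profile.mean_expr.columns]
    if missing:
        raise ValueError(
            f"profile lacks groups {missing}; fuzzification needs every "
            "(cluster, condition) group"
        )

    keep = profile.frac_expr.max(axis=1) >= min_frac if min_frac > 0 else np.ones(
        len(profile.mean_expr), dtype=bool
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "fuzzify: dropped %d genes below the %.3g expressed-fraction gate",
            n_dropped, min_frac,
        )
    mean = profile.mean_expr.loc[keep, expected]
    genes = list(mean.index)
    values = mean.to_numpy().reshape(len(genes), len(clusters), len(conditions))
    mu = triangular_memberships(values, spec.anchors)
    return MembershipTensor(
        mu=mu,
        genes=genes,
        clusters=list(clusters),
        conditions=conditions,
        levels=spec.levels,
    )
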