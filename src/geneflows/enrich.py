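"""Gene-set over-representation within flow memberships.

Two routes are provided.  The crisp route thresholds the combined flow
membership ``M(g)`` into an ordinary hit set and applies the one-sided
hypergeometric over-representation test.  The weighted route keeps the graded
memberships and scores each set by the sum of memberships of its members,
with significance assessed by permuting the membership vector over the
universe.  Both routes report Benjamini-Hochberg adjusted q-values across the
tested family.

Only over-representation is tested; depletion is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "crisp_overlap",
    "overrepresentation_pvalue",
    "hypergeom_enrichment",
    "weighted_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. read from a GMT file)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Parse a tab-separated GMT file (name, description, members...).

        Duplicate member symbols within a set are deduplicated with a
        warning; a line with fewer than three fields is a parse error.
        """
        sets: dict[str, frozenset[str]] = {}
        descriptions: dict[str, str] = {}
        path = Path(path)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n").rstrip("\r")
                if not line:
                    continue
                fields = line.split("\t")
                members = [m for m in fields[2:] if m]
                if len(fields) < 3 or not members:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs a name, a description "
                        "and at least one member"
                    )
                name, description = fields[0], fields[1]
                if name in sets:
                    raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
                unique = frozenset(members)
                if len(unique) < len(members):
                    warnings.warn(
                        f"{path}:{lineno}: set {name!r} lists duplicate members; "
                        "deduplicated",
                        stacklevel=2,
                    )
                sets[name] = unique
                descriptions[name] = description
        if not sets:
            raise ValueError(f"{path}: no gene sets found")
        return cls(sets=sets, descriptions=descriptions)

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; empty intersections are
        dropped with a warning."""
        uni = frozenset(universe)
        sets: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            inside = members & uni
            if not inside:
                warnings.warn(
                    f"gene set {name!r} has no members in the universe; dropped",
                    stacklevel=2,
                )
                continue
            if inside != members:
                warnings.warn(
                    f"gene set {name!r}: {len(members) - len(inside)} members "
                    "outside the universe dropped",
                    stacklevel=2,
                )
            sets[name] = inside
        return GeneSetCollection(
            sets=sets,
            descriptions={n: self.descriptions.get(n, "") for n in sets},
        )


def crisp_overlap(membership: Mapping[str, float] | pd.Series, threshold: float) -> set[str]:
    """Genes whose combined flow membership reaches ``threshold`` (inclusive)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    series = pd.Series(membership, dtype=float)
    return set(series.index[series >= threshold])


def overrepresentation_pvalue(k: int, n_universe: int, n_set: int, n_hits: int) -> float:
    """One-sided over-representation p-value P[X >= k].

    X is hypergeometric with population ``n_universe``, ``n_set`` successes
    and ``n_hits`` draws.
    """
    return float(hypergeom.sf(k - 1, n_universe, n_set, n_hits))


def _bh(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    hit_set: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Exact hypergeometric over-representation of each set in the hit set.

    Returns one row per set (sorted by name, so results are independent of
    input order) with columns ``set, size, overlap, score, p, q``.  ``size``
    is the set size within the universe and ``score`` is the raw overlap.
    """
    universe = set(universe)
    hits = set(hit_set)
    if not universe:
        raise ValueError("universe is empty")
    if not hits:
        raise ValueError("hit set is empty")
    if not hits <= universe:
        extra = sorted(hits - universe)[:5]
        raise ValueError(f"hit set contains genes outside the universe, e.g. {extra}")
    restricted = collection.restricted_to(universe)
    n_universe, n_hits = len(universe), len(hits)
    rows = []
    for name in sorted(restricted):
        members = restricted[name]
        k = len(members & hits)
        p = overrepresentation_pvalue(k, n_universe, len(members), n_hits)
        rows.append((name, len(members), k, float(k), p))
    table = pd.DataFrame(rows, columns=["set", "size", "overlap", "score", "p"])
    table["q"] = _bh(table["p"].to_numpy())
    return table


def weighted_enrichment(
    membership: Mapping[str, float] | pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    _chunk: int = 2000,
) -> pd.DataFrame:
    """Membership-weighted over-representation by permutation.

    The score of a set is the sum of combined memberships of its members;
    the null is generated by permuting the membership vector over the
    universe (the index of ``membership``) ``n_perm`` times.  p-values use
    the add-one permutation estimator (1 + #{null >= observed}) / (1 + B),
    which is valid and never exactly zero.  Same seed, same p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    series = pd.Series(membership, dtype=float)
    universe = list(series.index)
    if not universe:
        raise ValueError("membership vector is empty")
    restricted = collection.restricted_to(universe)
    if len(restricted) == 0:
        raise ValueError("no gene set has members in the universe")
    m = series.to_numpy(float)
    gene_pos = {g: i for i, g in enumerate(universe)}
    names = sorted(restricted)
    indicator = np.zeros((len(names), len(universe)))
    for row, name in enumerate(names):
        indicator[row, [gene_pos[g] for g in restricted[name]]] = 1.0
    observed = indicator @ m

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=np.int64)
    done = 0
    while done < n_perm:
        batch = min(_chunk, n_perm - done)
        perms = rng.permuted(np.tile(m, (batch, 1)), axis=1)
        null = perms @ indicator.T
        exceed += (null >= observed[None, :] - 1e-12).sum(axis=0)
        done += batch
    p = (1.0 + exceed) / (1.0 + n_perm)
    table = pd.DataFrame(
        {
            "set": names,
            "size": [len(restricted[n]) for n in names],
            "overlap": [int(indicator[i].sum()) for i in range(len(names))],
            "score": observed,
            "p": p,
        }
    )
    table["q"] = _bh(table["p"].to_numpy())
    return table
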