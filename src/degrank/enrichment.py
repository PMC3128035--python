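"""Rank-average gene-set enrichment and cross-platform set similarity.

The enrichment score of a gene set is the mean rank of its member genes in
a gene-level ranked list; small scores indicate enrichment.  The
intersection-union ratio measures how similarly a named set is realised
across platforms with different measured gene universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .errors import DataError


@dataclass
class GeneSetCollection:
    """Named gene sets over a symbol universe."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            self.sets[name] = tuple(dict.fromkeys(members))  # dedupe, keep order

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; empty sets are dropped."""
        uni = set(universe)
        kept = {
            name: tuple(g for g in members if g in uni)
            for name, members in self.sets.items()
        }
        kept = {n: m for n, m in kept.items() if m}
        return GeneSetCollection(kept, dict(self.descriptions))

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets, desc = dio.read_gmt(path)
        return cls(sets, desc)

    def to_gmt(self, path: str | Path) -> None:
        dio.write_gmt(self.sets, path, self.descriptions)


def enrichment_score(ranks: pd.Series, members: Iterable[str]) -> float:
    """Mean rank of the member genes present in the ranked list.

    ``ranks`` is a gene-level rank vector (1 = most differentially
    expressed, average-rank ties).  Raises on an empty intersection; the
    table builder treats that as an excluded set rather than an error.
    """
    present = [g for g in dict.fromkeys(members) if g in ranks.index]
    if not present:
        raise DataError("gene set has no member in the ranked list")
    return float(ranks.loc[present].mean())


def enrichment_table(
    rank_lists: Mapping[str, pd.Series], collection: GeneSetCollection
) -> pd.DataFrame:
    """E_G score per set (rows) per named ranked list (columns).

    Sets with no member in a given list get NaN there; sets empty in every
    list are dropped.
    """
    data: dict[str, list[float]] = {}
    names = collection.names()
    for label, ranks in rank_lists.items():
        col = []
        for name in names:
            try:
                col.append(enrichment_score(ranks, collection.sets[name]))
            except DataError:
                col.append(np.nan)
        data[label] = col
    table = pd.DataFrame(data, index=pd.Index(names, name="gene_set"))
    return table.dropna(how="all")


def rank_gene_sets(scores: pd.Series) -> pd.Series:
    """Rank sets ascending by E_G with a stable name tie-break (1 = most
    enriched)."""
    s = scores.dropna()
    order = np.lexsort((s.index.to_numpy(dtype=str), s.to_numpy(dtype=float)))
    ranks = np.empty(len(s), dtype=float)
    ranks[order] = np.arange(1, len(s) + 1)
    return pd.Series(ranks, index=s.index, name="set_rank")


def iu_ratio(memberships: Sequence[Iterable[str]]) -> float:
    """|intersection| / |union| of one set's per-platform realisations."""
    if len(memberships) < 2:
        raise DataError("intersection-union ratio needs >= 2 platforms")
    sets = [set(m) for m in memberships]
    union = set.union(*sets)
    if not union:
        raise DataError("empty union across platforms")
    return len(set.intersection(*sets)) / len(union)


def iu_table(
    collection: GeneSetCollection, universes: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Intersection-union ratio per named set across platform universes."""
    unis = {p: set(u) for p, u in universes.items()}
    rows = []
    for name, members in collection.sets.items():
        realised = [[g for g in members if g in u] for u in unis.values()]
        if not any(realised):
            continue
        rows.append((name, iu_ratio(realised)))
    return pd.DataFrame(rows, columns=["gene_set", "iu_ratio"]).set_index("gene_set")
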