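"""Six-rank taxonomic lineages and lowest-common-ancestor assignment.

Lineages span the six fixed ranks phylum/division, class, order, family,
genus and species. A rank may be missing (``None``): missing information
neither supports nor contradicts a taxon during the LCA step, mirroring how
reference taxonomies with gaps are treated in similarity-based barcoding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Rank",
    "RANKS",
    "Lineage",
    "TaxonomyTable",
    "Assignment",
    "strict_lca",
    "relaxed_lca",
]


class Rank(enum.IntEnum):
    """The six evaluated taxonomic levels, ordered from highest to lowest."""

    PHYLUM = 0
    CLASS = 1
    ORDER = 2
    FAMILY = 3
    GENUS = 4
    SPECIES = 5

    @property
    def label(self) -> str:
        return _RANK_LABELS[self]


_RANK_LABELS = {
    Rank.PHYLUM: "phylum",
    Rank.CLASS: "class",
    Rank.ORDER: "order",
    Rank.FAMILY: "family",
    Rank.GENUS: "genus",
    Rank.SPECIES: "species",
}

RANKS: tuple[Rank, ...] = tuple(Rank)
N_RANKS = len(RANKS)


@dataclass(frozen=True)
class Lineage:
    """Taxon names at the six ranks; ``None`` marks a missing rank."""

    taxa: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != N_RANKS:
            raise ValueError(f"lineage needs {N_RANKS} ranks, got {len(self.taxa)}")
        for name in self.taxa:
            if name is not None and (not isinstance(name, str) or not name):
                raise ValueError("taxon names must be non-empty strings or None")

    @classmethod
    def of(cls, *taxa: Optional[str]) -> "Lineage":
        return cls(tuple(taxa))

    @classmethod
    def empty(cls) -> "Lineage":
        return cls((None,) * N_RANKS)

    def __getitem__(self, rank: Rank) -> Optional[str]:
        return self.taxa[rank]

    def is_complete(self) -> bool:
        return all(t is not None for t in self.taxa)

    def n_assigned(self) -> int:
        return sum(t is not None for t in self.taxa)


class TaxonomyTable:
    """Mapping from sequence id to :class:`Lineage`.

    Every reference sequence in a database must have exactly one entry.
    """

    def __init__(self, lineages: Mapping[str, Lineage] | None = None) -> None:
        self._lineages: dict[str, Lineage] = dict(lineages or {})

    def __getitem__(self, seqid: str) -> Lineage:
        try:
            return self._lineages[seqid]
        except KeyError:
            raise KeyError(f"sequence id {seqid!r} has no taxonomy entry") from None

    def __contains__(self, seqid: str) -> bool:
        return seqid in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __iter__(self):
        return iter(self._lineages)

    def items(self):
        return self._lineages.items()

    def add(self, seqid: str, lineage: Lineage) -> None:
        if seqid in self._lineages:
            raise ValueError(f"duplicate taxonomy entry for id {seqid!r}")
        self._lineages[seqid] = lineage

    def require_reference_complete(self) -> None:
        """Check the reference-database contract: genus and species present."""
        for seqid, lin in self._lineages.items():
            if lin[Rank.GENUS] is None or lin[Rank.SPECIES] is None:
                raise ValueError(
                    f"reference {seqid!r} lacks genus- or species-level information"
                )


@dataclass(frozen=True)
class Assignment:
    """Per-rank taxonomic identification of one query by one method."""

    query_id: str
    method: str
    result: Lineage
    supporting_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.result.n_assigned() > 0 and not self.supporting_ids:
            raise ValueError("assigned ranks require a non-empty supporting set")


def strict_lca(lineages: Iterable[Lineage]) -> Lineage:
    """Lowest-common-ancestor consensus of a collection of lineages.

    Proceeding from phylum downward, a rank is assigned when all lineages
    with information at that rank carry the same taxon name. A missing rank
    is a wildcard: it neither supports nor conflicts. The first rank with
    two or more distinct names is a conflict; that rank and every rank below
    it are left unassigned.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("strict_lca requires at least one lineage")
    out: list[Optional[str]] = [None] * N_RANKS
    for rank in RANKS:
        names = {lin[rank] for lin in lineages if lin[rank] is not None}
        if len(names) > 1:
            break
        if len(names) == 1:
            out[rank] = next(iter(names))
    return Lineage(tuple(out))


def relaxed_lca(lineages: Iterable[Lineage], min_support: float) -> Lineage:
    """LCA variant tolerating a bounded minority of conflicting lineages.

    At each rank, among lineages non-missing there, a taxon carried by at
    least ``min_support`` of them is assigned; the working set is then
    restricted to its carriers (plus lineages missing at the rank) before
    descending. ``min_support`` must exceed 0.5 so the qualifying taxon is
    unique. With ``min_support=1`` and no missing ranks this reduces to
    :func:`strict_lca`.
    """
    if not (0.5 < min_support <= 1.0):
        raise ValueError("min_support must be in (0.5, 1]")
    working = list(lineages)
    if not working:
        raise ValueError("relaxed_lca requires at least one lineage")
    out: list[Optional[str]] = [None] * N_RANKS
    for rank in RANKS:
        present = [lin for lin in working if lin[rank] is not None]
        if not present:
            continue
        counts: dict[str, int] = {}
        for lin in present:
            counts[lin[rank]] = counts.get(lin[rank], 0) + 1
        # min_support > 0.5 makes at most one name qualify
        name, best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if best < min_support * len(present):
            break
        out[rank] = name
        working = [lin for lin in working if lin[rank] in (None, name)]
    return Lineage(tuple(out))
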