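"""Synthetic reference databases with a known six-rank taxonomy.

The generator grows a balanced taxonomy (a fixed number of children at
each rank) and evolves sequences down it with a star-like substitution
model: each child's sequence is its parent's sequence with a fixed
proportion of sites substituted, the sites drawn without replacement and
each replaced by a uniformly chosen different base. Per-rank divergence
proportions therefore control how well the ranks are separated in
sequence space, which is what the assignment methods and the benchmark
need from a fixture. No indels, no rate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SequenceRecord
from .taxonomy import Lineage, Rank, RANKS, TaxonomyTable

__all__ = ["SimulationSpec", "simulate_taxonomy", "evolve_sequences"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic reference database.

    ``counts`` gives children per rank (phyla, classes per phylum, ...,
    species per genus); total species is their product. ``divergence``
    gives the substitution proportion applied on the branch entering each
    rank level, and ``within_species`` the proportion applied to each
    individual sequence record below its species consensus.
    """

    counts: tuple[int, int, int, int, int, int] = (2, 2, 2, 2, 2, 2)
    seqs_per_species: int = 1
    seq_length: int = 150
    divergence: tuple[float, ...] = (0.12, 0.10, 0.08, 0.06, 0.04, 0.02)
    within_species: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != len(RANKS):
            raise ValueError("counts needs one entry per rank")
        if any(c < 1 for c in self.counts):
            raise ValueError("all counts must be >= 1")
        if self.seqs_per_species < 1 or self.seq_length < 1:
            raise ValueError("seqs_per_species and seq_length must be >= 1")
        if len(self.divergence) != len(RANKS):
            raise ValueError("divergence needs one proportion per rank")
        for p in (*self.divergence, self.within_species):
            if not (0.0 <= p < 1.0):
                raise ValueError("divergence proportions must lie in [0, 1)")

    @property
    def n_species(self) -> int:
        return int(np.prod(self.counts))


def simulate_taxonomy(spec: SimulationSpec) -> list[Lineage]:
    """Full six-rank lineage of every species, in a fixed systematic order.

    Taxon names are dotted paths (``p0``, ``p0.c1``, ``p0.c1.o0`` ...), so
    names are unique across sibling groups. Deterministic for a fixed spec.
    """
    prefixes = "pcofgs"
    lineages: list[Lineage] = []

    def descend(rank_idx: int, path: list[str]) -> None:
        if rank_idx == len(RANKS):
            taxa = [".".join(path[: i + 1]) for i in range(len(RANKS))]
            lineages.append(Lineage(tuple(taxa)))
            return
        for child in range(spec.counts[rank_idx]):
            descend(rank_idx + 1, path + [f"{prefixes[rank_idx]}{child}"])

    descend(0, [])
    return lineages


def _mutate(seq: np.ndarray, proportion: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute round(proportion * length) sites, drawn without
    replacement, each to a uniformly chosen different base."""
    n_sub = int(round(proportion * seq.shape[0]))
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    sites = rng.choice(seq.shape[0], size=n_sub, replace=False)
    # shift by 1..3 mod 4: always a different base, uniform over the other 3
    out[sites] = (out[sites] + rng.integers(1, 4, size=n_sub)) % 4
    return out


def evolve_sequences(
    spec: SimulationSpec, skeleton: Sequence[Lineage] | None = None
) -> tuple[list[SequenceRecord], TaxonomyTable]:
    """Evolve one sequence set down the taxonomy of ``spec``.

    Starts from a uniformly random root sequence and applies the per-rank
    divergence on every branch, then emits ``seqs_per_species`` records per
    species with the within-species proportion applied independently to
    each. Record ids encode the species (``<species>_<i>``). Byte-identical
    output for a fixed spec.
    """
    if skeleton is None:
        skeleton = simulate_taxonomy(spec)
    rng = np.random.default_rng(spec.seed)
    root = rng.integers(0, 4, size=spec.seq_length, dtype=np.int64)

    records: list[SequenceRecord] = []
    table = TaxonomyTable()
    lineage_iter = iter(skeleton)

    def descend(rank_idx: int, seq: np.ndarray) -> None:
        if rank_idx == len(RANKS):
            lineage = next(lineage_iter)
            species = lineage[Rank.SPECIES]
            for i in range(spec.seqs_per_species):
                tip = _mutate(seq, spec.within_species, rng)
                residues = "".join(_BASES[tip])
                seqid = f"{species}_{i}"
                records.append(SequenceRecord(id=seqid, residues=residues))
                table.add(seqid, lineage)
            return
        for _child in range(spec.counts[rank_idx]):
            descend(rank_idx + 1, _mutate(seq, spec.divergence[rank_idx], rng))

    descend(0, root)
    return records, table
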