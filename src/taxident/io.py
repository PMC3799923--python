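"""Reading and writing the toolkit's file formats.

FASTA for reference databases and query sets (via Biopython), a flat
seven-column TSV for per-sequence lineages, and result TSVs for assignments
and benchmark evaluations. Sequences are normalised to the {A,C,G,T,N}
alphabet on input: case is folded, U maps to T, and every other IUPAC
ambiguity code collapses to N so that the alignment scorer faces a two-class
match/mismatch decision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .taxonomy import Lineage, Rank, RANKS, TaxonomyTable, Assignment

__all__ = [
    "SequenceRecord",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "write_assignments",
    "UNIDENTIFIED",
]

#: Token written for an unassigned rank in result tables.
UNIDENTIFIED = "unidentified"

_TAX_HEADER = ["seqid", "phylum", "class", "order", "family", "genus", "species"]

# fold case, U->T; every other IUPAC ambiguity code collapses to N
_NORMALIZE = str.maketrans(
    {
        "U": "T",
        **{c: "N" for c in "RYSWKMBDHV"},
    }
)


def normalize_residues(raw: str) -> str:
    """Uppercase, map U to T, collapse non-ACGT IUPAC codes to N.

    Idempotent; raises on characters outside the IUPAC DNA/RNA alphabet.
    """
    seq = raw.upper().translate(_NORMALIZE)
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One identified DNA sequence (reference or query)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if set(self.residues) - set("ACGTN"):
            raise ValueError(
                f"sequence {self.id!r} is not normalized; use normalize_residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into normalised records, preserving input order.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids and empty sequences are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        residues = normalize_residues(str(entry.seq))
        if not residues:
            raise ValueError(f"empty sequence for id {entry.id!r} in {path}")
        records.append(
            SequenceRecord(id=entry.id, residues=residues, description=entry.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 70 columns."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(bio)


def read_taxonomy_table(path: str | Path) -> TaxonomyTable:
    """Parse the seven-column lineage TSV (header required).

    Empty cells mark missing ranks; cells are whitespace-trimmed.
    """
    table = TaxonomyTable()
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: missing header line") from None
        if [h.strip() for h in header] != _TAX_HEADER:
            raise ValueError(
                f"{path}: line 1: expected header {_TAX_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_TAX_HEADER):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_TAX_HEADER)} columns, "
                    f"got {len(row)}"
                )
            seqid = row[0].strip()
            taxa = tuple(cell.strip() or None for cell in row[1:])
            try:
                table.add(seqid, Lineage(taxa))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return table


def write_taxonomy_table(table: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TAX_HEADER)
        for seqid, lin in table.items():
            writer.writerow([seqid] + [t or "" for t in lin.taxa])


def write_assignments(assignments: Sequence[Assignment], path: str | Path) -> None:
    """Write assignment results as TSV.

    Unassigned ranks are the literal token ``unidentified``; supporting
    neighbor ids are comma-joined in sorted order.
    """
    header = (
        ["queryid", "method"]
        + [r.label for r in RANKS]
        + ["n_neighbors", "neighbor_ids"]
    )
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for a in assignments:
            taxa = [a.result[r] or UNIDENTIFIED for r in RANKS]
            ids = sorted(a.supporting_ids)
            writer.writerow([a.query_id, a.method] + taxa + [len(ids), ",".join(ids)])
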