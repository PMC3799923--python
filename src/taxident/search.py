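"""Exhaustive similarity search over a reference database.

A deterministic local-alignment engine plays the role similarity-search
programs play in barcoding pipelines: every query is aligned against every
reference with an affine-gap Smith-Waterman scorer, and hits above a raw
score threshold are returned in a total, reproducible order. Raw score is
the similarity measure throughout: a larger score means a genetically
closer pair, so "nearest" always means "highest raw score".

The search engine is a pluggable contract (:class:`PairwiseAligner`); the
default :class:`ExactAligner` computes true alignments while a score-table
aligner can stand in for tests that are specified as score matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Protocol, Sequence

import numpy as np
from numba import njit

from .io import SequenceRecord

__all__ = [
    "ScoringScheme",
    "DEFAULT_SCHEME",
    "AlignmentHit",
    "AlignmentResult",
    "PairwiseAligner",
    "ExactAligner",
    "TableAligner",
    "align_local",
    "search_db",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine local-alignment scoring parameters.

    ``gap_open`` is the cost of a gap's first column and ``gap_extend`` of
    each further column, so a gap of length k costs
    ``gap_open + (k - 1) * gap_extend``. ``min_score`` is the raw-score
    admission threshold of the database search. Positions involving N
    always score ``mismatch_penalty``.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 20

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if self.min_score < 1:
            raise ValueError("min_score must be >= 1")


DEFAULT_SCHEME = ScoringScheme()


class AlignmentResult(NamedTuple):
    raw_score: int
    percent_identity: float
    alignment_length: int


@dataclass(frozen=True)
class AlignmentHit:
    """One database hit: subject id plus alignment statistics."""

    subject_id: str
    raw_score: int
    percent_identity: float
    alignment_length: int


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = a.shape[0], b.shape[0]
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), NEG, np.int64)  # horizontal: gap consuming b
    F = np.full((m + 1, n + 1), NEG, np.int64)  # vertical: gap consuming a
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            e = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            f = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _sw_traceback(H, E, F, a, b, match, mismatch, gap_open, gap_extend, i, j):
    """Trace one optimal path ending at (i, j); preference diagonal >
    vertical > horizontal. Returns (alignment_length, identical_columns)."""
    length = 0
    ident = 0
    state = 0  # 0=H, 1=F(vertical), 2=E(horizontal)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            ai = a[i - 1]
            bj = b[j - 1]
            s = match if (ai == bj and ai < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                length += 1
                if ai == bj and ai < 4:
                    ident += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            length += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
        else:
            length += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
    return length, ident


def align_local(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Optimal affine-gap local alignment of two normalised DNA strings.

    The raw score is never negative (the empty alignment scores 0).
    Identity and length come from one optimal traceback: among equal-score
    end cells the one whose traceback is longest wins, ties broken by the
    smallest (row, column); within a traceback, diagonal moves are preferred
    over vertical over horizontal. Swapping the inputs leaves the raw score
    unchanged.
    """
    if not a or not b:
        raise ValueError("align_local requires non-empty sequences")
    ca, cb = _encode(a), _encode(b)
    H, E, F = _sw_fill(
        ca, cb, scheme.match_reward, scheme.mismatch_penalty,
        scheme.gap_open, scheme.gap_extend,
    )
    best = int(H.max())
    if best <= 0:
        return AlignmentResult(0, 0.0, 0)
    rows, cols = np.nonzero(H == best)
    best_len = -1
    best_ident = 0
    # candidates scanned in row-major order: first max-length traceback wins
    for i, j in zip(rows.tolist(), cols.tolist()):
        length, ident = _sw_traceback(
            H, E, F, ca, cb, scheme.match_reward, scheme.mismatch_penalty,
            scheme.gap_open, scheme.gap_extend, i, j,
        )
        if length > best_len:
            best_len = length
            best_ident = ident
    return AlignmentResult(best, 100.0 * best_ident / best_len, best_len)


class PairwiseAligner(Protocol):
    """Contract of the search engine's pairwise scorer."""

    def align(self, a: SequenceRecord, b: SequenceRecord) -> AlignmentResult: ...


class ExactAligner:
    """Default engine: exact Smith-Waterman with a pair cache.

    The cache is keyed on residue strings, so it stays valid when the
    database is subset (e.g. leave-one-out) and can be shared across a
    whole benchmark run.
    """

    def __init__(self, scheme: ScoringScheme = DEFAULT_SCHEME) -> None:
        self.scheme = scheme
        self._cache: dict[tuple[str, str], AlignmentResult] = {}

    def align(self, a: SequenceRecord, b: SequenceRecord) -> AlignmentResult:
        key = (a.residues, b.residues)
        hit = self._cache.get(key)
        if hit is None:
            hit = align_local(a.residues, b.residues, self.scheme)
            self._cache[key] = hit
        return hit


class TableAligner:
    """Score-table engine for fixtures specified as score matrices.

    ``table`` maps unordered id pairs to raw scores (optionally
    ``(score, percent_identity)``); missing pairs score 0.
    """

    def __init__(self, table: dict) -> None:
        self._table: dict[frozenset, tuple[int, float]] = {}
        for pair, value in table.items():
            score, pid = value if isinstance(value, tuple) else (value, 100.0)
            self._table[frozenset(pair)] = (int(score), float(pid))

    def align(self, a: SequenceRecord, b: SequenceRecord) -> AlignmentResult:
        score, pid = self._table.get(frozenset((a.id, b.id)), (0, 0.0))
        return AlignmentResult(score, pid, max(len(a), len(b)))


def search_db(
    db: Sequence[SequenceRecord],
    query: SequenceRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_targets: Optional[int] = None,
    aligner: Optional[PairwiseAligner] = None,
) -> list[AlignmentHit]:
    """Align ``query`` against every database record and rank the hits.

    Exhaustive (no heuristic seeding): every record is scored, hits with
    raw score >= ``scheme.min_score`` are kept, sorted by raw score
    descending with ties broken by subject id ascending. ``max_targets``
    truncates the list but never splits a raw-score tie group. The query's
    own record, if present in the database, is not excluded.
    """
    ids = [r.id for r in db]
    if len(set(ids)) != len(ids):
        raise ValueError("database contains duplicate sequence ids")
    if max_targets is not None and max_targets < 1:
        raise ValueError("max_targets must be >= 1")
    engine = aligner if aligner is not None else ExactAligner(scheme)
    hits = []
    for rec in db:
        res = engine.align(query, rec)
        if res.raw_score >= scheme.min_score:
            hits.append(
                AlignmentHit(rec.id, res.raw_score, res.percent_identity,
                             res.alignment_length)
            )
    hits.sort(key=lambda h: (-h.raw_score, h.subject_id))
    if max_targets is not None and len(hits) > max_targets:
        k = max_targets
        boundary = hits[k - 1].raw_score
        while k < len(hits) and hits[k].raw_score == boundary:
            k += 1
        hits = hits[:k]
    return hits
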