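"""Taxonomic assignment methods.

Classical neighbor-retrieval rules (1-NN / k-NN, n%-NN, n%-k-NN) and the
two automatic-threshold methods, NNCauto and QCauto, which derive the
neighborhood radius from the data instead of a user-set k or identity
cutoff.

Both auto methods start the same way: the nearest-neighbor references A
(all tied top hits of the query Q) are found, then for each a in A the
"borderline" references B are found -- the closest references to a among
those strictly farther from a than Q is (raw score below score(Q, A)). The
borderline score defines the neighborhood radius: around A for NNCauto,
around Q (using the borderline closest to Q) for QCauto. The lowest common
ancestor of every retrieved lineage is the assignment. By construction the
query lies within the sequence-variation range of the reported taxon: the
radius always reaches at least one reference outside Q's own distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import SequenceRecord
from .search import (
    AlignmentHit,
    ExactAligner,
    PairwiseAligner,
    ScoringScheme,
    DEFAULT_SCHEME,
    search_db,
)
from .taxonomy import (
    Assignment,
    Lineage,
    TaxonomyTable,
    relaxed_lca,
    strict_lca,
)

__all__ = [
    "NeighborhoodTrace",
    "find_borderline",
    "assign_knn",
    "assign_percent_nn",
    "assign_nncauto",
    "assign_qcauto",
    "METHOD_NAMES",
]

METHOD_NAMES = ("1nn", "knn", "pnn", "pknn", "nncauto", "qcauto")


@dataclass(frozen=True)
class NeighborhoodTrace:
    """Diagnostic record of one auto-threshold assignment.

    ``threshold_score`` is the borderline score actually applied: the
    minimum per-neighbor score(A, B) for NNCauto (the loosest of the per-A
    radii) or score(Q, B) of the selected borderline for QCauto; ``None``
    when no borderline exists. ``neighborhood`` is the full set entering
    the LCA, so A and B are always contained in it.
    """

    query_id: str
    nearest_neighbors: frozenset[str]
    score_qa: Optional[int]
    borderlines: frozenset[str]
    threshold_score: Optional[int]
    neighborhood: frozenset[str]
    per_neighbor_thresholds: dict = field(default_factory=dict)


def find_borderline(
    hits_around_a: Sequence[AlignmentHit], score_qa: int
) -> tuple[set[str], Optional[int]]:
    """Borderline references of one nearest neighbor.

    Candidates are hits strictly farther from A than Q (raw score <
    ``score_qa``); all candidates sharing the maximal such score are
    borderline. Returns ``(set(), None)`` when no candidate exists.
    """
    candidates = [h for h in hits_around_a if h.raw_score < score_qa]
    if not candidates:
        return set(), None
    score_ab = max(h.raw_score for h in candidates)
    return {h.subject_id for h in candidates if h.raw_score == score_ab}, score_ab


def _lineages_of(ids, taxonomy: TaxonomyTable) -> list[Lineage]:
    try:
        return [taxonomy[i] for i in sorted(ids)]
    except KeyError as exc:
        raise KeyError(f"reference hit without taxonomy entry: {exc}") from None


def _lca(lineages, lca: str, min_support: float) -> Lineage:
    if lca == "strict":
        return strict_lca(lineages)
    if lca == "relaxed":
        return relaxed_lca(lineages, min_support)
    raise ValueError(f"unknown LCA variant {lca!r}")


def _unidentified(query_id: str, method: str) -> Assignment:
    return Assignment(query_id, method, Lineage.empty(), frozenset())


def assign_knn(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    k: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    lca: str = "strict",
    min_support: float = 1.0,
    aligner: Optional[PairwiseAligner] = None,
) -> Assignment:
    """k-nearest-neighbor assignment: LCA over the top-k hits.

    Tie groups at the k boundary are kept whole; with k=1 this is the
    classical best-hit (1-NN) method. No hits above the admission score
    leaves every rank unassigned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    method = "1nn" if k == 1 else f"{k}nn"
    hits = search_db(db, query, scheme, max_targets=k, aligner=aligner)
    if not hits:
        return _unidentified(query.id, method)
    ids = {h.subject_id for h in hits}
    result = _lca(_lineages_of(ids, taxonomy), lca, min_support)
    return Assignment(query.id, method, result, frozenset(ids))


def assign_percent_nn(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    n_percent: float,
    cap: Optional[int] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    lca: str = "strict",
    min_support: float = 1.0,
    aligner: Optional[PairwiseAligner] = None,
) -> Assignment:
    """n%-NN assignment: LCA over hits with identity >= ``n_percent``.

    A finite ``cap`` truncates the identity-filtered hits by raw-score
    order (tie groups kept whole), giving the n%-k-NN method. No
    qualifying hit leaves every rank unassigned.
    """
    if not (0.0 <= n_percent <= 100.0):
        raise ValueError("n_percent must be between 0 and 100")
    method = f"{n_percent:g}%nn" if cap is None else f"{n_percent:g}%-{cap}nn"
    hits = search_db(db, query, scheme, aligner=aligner)
    hits = [h for h in hits if h.percent_identity >= n_percent]
    if cap is not None and len(hits) > cap:
        boundary = hits[cap - 1].raw_score
        k = cap
        while k < len(hits) and hits[k].raw_score == boundary:
            k += 1
        hits = hits[:k]
    if not hits:
        return _unidentified(query.id, method)
    ids = {h.subject_id for h in hits}
    result = _lca(_lineages_of(ids, taxonomy), lca, min_support)
    return Assignment(query.id, method, result, frozenset(ids))


def _nearest_neighbors(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    aligner: PairwiseAligner,
) -> tuple[list[AlignmentHit], set[str], Optional[int]]:
    """Step I shared by the auto methods: all tied top hits of Q."""
    hits = search_db(db, query, scheme, aligner=aligner)
    if not hits:
        return hits, set(), None
    score_qa = hits[0].raw_score
    a_ids = {h.subject_id for h in hits if h.raw_score == score_qa}
    return hits, a_ids, score_qa


def assign_nncauto(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    lca: str = "strict",
    min_support: float = 1.0,
    aligner: Optional[PairwiseAligner] = None,
) -> tuple[Assignment, NeighborhoodTrace]:
    """Nearest-neighbor-centric auto-k-NN assignment.

    For each nearest neighbor a of the query, the database is searched
    around a; the borderline score of a bounds a's neighborhood, and the
    LCA is taken over the union of all nearest-neighbor, borderline and
    neighborhood lineages. Without any borderline the query is left
    unidentified at every rank.
    """
    if not db:
        raise ValueError("empty reference database")
    engine = aligner if aligner is not None else ExactAligner(scheme)
    _, a_ids, score_qa = _nearest_neighbors(query, db, scheme, engine)
    if not a_ids:
        trace = NeighborhoodTrace(query.id, frozenset(), None, frozenset(),
                                  None, frozenset())
        return _unidentified(query.id, "nncauto"), trace
    by_id = {r.id: r for r in db}
    borderlines: set[str] = set()
    neighborhood: set[str] = set(a_ids)
    thresholds: dict[str, int] = {}
    for a_id in sorted(a_ids):
        # steps II and III share one search around a
        hits_a = search_db(db, by_id[a_id], scheme, aligner=engine)
        b_ids, score_ab = find_borderline(hits_a, score_qa)
        if not b_ids:
            continue
        thresholds[a_id] = score_ab
        borderlines |= b_ids
        neighborhood |= {h.subject_id for h in hits_a if h.raw_score >= score_ab}
    if not borderlines:
        trace = NeighborhoodTrace(query.id, frozenset(a_ids), score_qa,
                                  frozenset(), None, frozenset(a_ids))
        return _unidentified(query.id, "nncauto"), trace
    neighborhood |= borderlines
    trace = NeighborhoodTrace(
        query.id, frozenset(a_ids), score_qa, frozenset(borderlines),
        min(thresholds.values()), frozenset(neighborhood), dict(thresholds),
    )
    result = _lca(_lineages_of(neighborhood, taxonomy), lca, min_support)
    return Assignment(query.id, "nncauto", result, frozenset(neighborhood)), trace


def assign_qcauto(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    lca: str = "strict",
    min_support: float = 1.0,
    aligner: Optional[PairwiseAligner] = None,
) -> tuple[Assignment, NeighborhoodTrace]:
    """Query-centric auto-k-NN assignment.

    Borderlines are found as in NNCauto, but the neighborhood is centred
    on the query: of all borderline candidates the one closest to Q sets
    the radius, and every hit of Q at least that close enters the LCA
    together with the nearest neighbors and the selected borderline.
    Without any borderline the query is left unidentified at every rank.
    """
    if not db:
        raise ValueError("empty reference database")
    engine = aligner if aligner is not None else ExactAligner(scheme)
    hits_q, a_ids, score_qa = _nearest_neighbors(query, db, scheme, engine)
    if not a_ids:
        trace = NeighborhoodTrace(query.id, frozenset(), None, frozenset(),
                                  None, frozenset())
        return _unidentified(query.id, "qcauto"), trace
    by_id = {r.id: r for r in db}
    candidates: set[str] = set()
    for a_id in sorted(a_ids):
        hits_a = search_db(db, by_id[a_id], scheme, aligner=engine)
        b_ids, _ = find_borderline(hits_a, score_qa)
        candidates |= b_ids
    if not candidates:
        trace = NeighborhoodTrace(query.id, frozenset(a_ids), score_qa,
                                  frozenset(), None, frozenset(a_ids))
        return _unidentified(query.id, "qcauto"), trace
    # borderline closest to the query sets the radius; scored directly so
    # candidates below the search admission threshold still get a score
    score_to_q = {
        b: engine.align(query, by_id[b]).raw_score for b in sorted(candidates)
    }
    score_qb = max(score_to_q.values())
    selected = min(b for b, s in score_to_q.items() if s == score_qb)
    neighborhood = {h.subject_id for h in hits_q if h.raw_score >= score_qb}
    neighborhood |= a_ids
    neighborhood.add(selected)
    trace = NeighborhoodTrace(
        query.id, frozenset(a_ids), score_qa, frozenset({selected}),
        score_qb, frozenset(neighborhood),
    )
    result = _lca(_lineages_of(neighborhood, taxonomy), lca, min_support)
    return Assignment(query.id, "qcauto", result, frozenset(neighborhood)), trace
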