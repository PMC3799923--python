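"""Cross-validation benchmark of the assignment methods.

The evaluation protocol: query sequences are sampled per taxonomic group
(one sequence per randomly chosen genus), optionally reduced to short
"mini-barcode" windows, and assigned against the reference database either
with the query retained (no-LOOCV, simulating a species already present in
the database) or with the query's own record removed (LOOCV, simulating an
unknown species). Each outcome is scored by two 0-6 indices: correctness
(ranks assigned and matching the truth) and incorrectness (ranks assigned
but wrong); every rank additionally falls in one of four categories so
that "unidentified" can be split into harmless and misleading cases.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord, UNIDENTIFIED
from .search import ExactAligner, PairwiseAligner, ScoringScheme, DEFAULT_SCHEME
from .taxonomy import Lineage, Rank, RANKS, TaxonomyTable
from .assign import (
    METHOD_NAMES,
    assign_knn,
    assign_nncauto,
    assign_percent_nn,
    assign_qcauto,
)

__all__ = [
    "CORRECT",
    "INCORRECT",
    "UNID_HIGHER_INCORRECT",
    "UNID_CLEAN",
    "CATEGORIES",
    "EvalRecord",
    "MethodConfig",
    "correctness_index",
    "incorrectness_index",
    "classify_per_level",
    "select_queries",
    "make_minibarcode",
    "run_crossvalidation",
    "summarize_frequencies",
    "BenchmarkSummary",
    "write_eval_table",
]

CORRECT = "correct"
INCORRECT = "incorrect"
UNID_HIGHER_INCORRECT = "unid_higher_incorrect"
UNID_CLEAN = "unid_clean"
CATEGORIES = (CORRECT, INCORRECT, UNID_HIGHER_INCORRECT, UNID_CLEAN)


def _check_truth(truth: Lineage) -> None:
    if not truth.is_complete():
        raise ValueError("truth lineage must be populated at every rank")


def correctness_index(truth: Lineage, assigned: Lineage) -> int:
    """Number of ranks assigned and matching the truth (0-6)."""
    _check_truth(truth)
    return sum(
        assigned[r] is not None and assigned[r] == truth[r] for r in RANKS
    )


def incorrectness_index(truth: Lineage, assigned: Lineage) -> int:
    """Number of ranks assigned but different from the truth (0-6)."""
    _check_truth(truth)
    return sum(
        assigned[r] is not None and assigned[r] != truth[r] for r in RANKS
    )


def classify_per_level(truth: Lineage, assigned: Lineage) -> tuple[str, ...]:
    """Per-rank outcome category.

    correct / incorrect where a taxon was assigned; unassigned ranks are
    ``unid_higher_incorrect`` when some higher rank was misassigned and
    ``unid_clean`` otherwise.
    """
    _check_truth(truth)
    cats: list[str] = []
    higher_incorrect = False
    for r in RANKS:
        if assigned[r] is None:
            cats.append(UNID_HIGHER_INCORRECT if higher_incorrect else UNID_CLEAN)
        elif assigned[r] == truth[r]:
            cats.append(CORRECT)
        else:
            cats.append(INCORRECT)
            higher_incorrect = True
    return tuple(cats)


@dataclass(frozen=True)
class EvalRecord:
    """Truth vs. assignment for one query."""

    query_id: str
    truth: Lineage
    assigned: Lineage
    correctness: int
    incorrectness: int
    category_per_rank: tuple[str, ...]

    @classmethod
    def evaluate(cls, query_id: str, truth: Lineage, assigned: Lineage) -> "EvalRecord":
        return cls(
            query_id=query_id,
            truth=truth,
            assigned=assigned,
            correctness=correctness_index(truth, assigned),
            incorrectness=incorrectness_index(truth, assigned),
            category_per_rank=classify_per_level(truth, assigned),
        )


def select_queries(
    taxonomy: TaxonomyTable,
    group_rank: Rank,
    per_group_limit: int,
    seed: int,
) -> list[str]:
    """Sample query ids: up to ``per_group_limit`` genera per group at
    ``group_rank``, one uniformly chosen sequence per sampled genus.

    Deterministic for a fixed seed; the result is sorted by id for a
    stable downstream order. Entries without a taxon at the group rank or
    at genus level are not eligible.
    """
    if per_group_limit < 1:
        raise ValueError("per_group_limit must be >= 1")
    groups: dict[str, dict[str, list[str]]] = {}
    for seqid, lin in taxonomy.items():
        group = lin[group_rank]
        genus = lin[Rank.GENUS]
        if group is None or genus is None:
            continue
        groups.setdefault(group, {}).setdefault(genus, []).append(seqid)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for group in sorted(groups):
        genera = sorted(groups[group])
        n = min(per_group_limit, len(genera))
        picked = rng.choice(len(genera), size=n, replace=False)
        for gi in sorted(picked.tolist()):
            ids = sorted(groups[group][genera[gi]])
            chosen.append(ids[int(rng.integers(len(ids)))])
    return sorted(chosen)


def make_minibarcode(record: SequenceRecord, window: int, seed: int) -> SequenceRecord:
    """Random contiguous window of ``window`` sites (a "mini-barcode").

    Sequences not longer than the window are returned unchanged. The
    offset is drawn from a stream keyed on (seed, record id), so the same
    query receives the same window in every method of one benchmark run.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    length = len(record.residues)
    if length <= window:
        return record
    rng = np.random.default_rng([seed, zlib.crc32(record.id.encode())])
    start = int(rng.integers(0, length - window, endpoint=True))
    return SequenceRecord(
        id=record.id,
        residues=record.residues[start : start + window],
        description=record.description,
    )


@dataclass(frozen=True)
class MethodConfig:
    """Configuration of one assignment method for a benchmark run.

    ``method`` is one of ``1nn, knn, pnn, pknn, nncauto, qcauto``. ``k``
    applies to knn; ``identity`` (percent) to pnn/pknn; ``cap`` to pknn
    (the n%-k-NN method). ``lca``/``min_support`` select the strict or
    relaxed LCA applied uniformly.
    """

    method: str
    k: int = 5
    identity: float = 97.0
    cap: Optional[int] = 100
    lca: str = "strict"
    min_support: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHOD_NAMES}"
            )

    def run(
        self,
        query: SequenceRecord,
        db: Sequence[SequenceRecord],
        taxonomy: TaxonomyTable,
        scheme: ScoringScheme = DEFAULT_SCHEME,
        aligner: Optional[PairwiseAligner] = None,
    ):
        kw = dict(scheme=scheme, lca=self.lca, min_support=self.min_support,
                  aligner=aligner)
        if self.method == "1nn":
            return assign_knn(query, db, taxonomy, k=1, **kw)
        if self.method == "knn":
            return assign_knn(query, db, taxonomy, k=self.k, **kw)
        if self.method == "pnn":
            return assign_percent_nn(query, db, taxonomy, self.identity,
                                     cap=None, **kw)
        if self.method == "pknn":
            return assign_percent_nn(query, db, taxonomy, self.identity,
                                     cap=self.cap, **kw)
        if self.method == "nncauto":
            return assign_nncauto(query, db, taxonomy, **kw)[0]
        return assign_qcauto(query, db, taxonomy, **kw)[0]


def run_crossvalidation(
    queries: Sequence[SequenceRecord],
    db: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    config: MethodConfig,
    mode: str = "noloocv",
    scheme: ScoringScheme = DEFAULT_SCHEME,
    aligner: Optional[PairwiseAligner] = None,
) -> list[EvalRecord]:
    """Assign every query and score it against its known lineage.

    In ``loocv`` mode exactly the query's own record (by id) is removed
    from the search database; conspecific and congeneric records remain.
    In ``noloocv`` mode the full database is used for every query.
    """
    if mode not in ("noloocv", "loocv"):
        raise ValueError(f"mode must be 'noloocv' or 'loocv', got {mode!r}")
    db_ids = {r.id for r in db}
    engine = aligner if aligner is not None else ExactAligner(scheme)
    records: list[EvalRecord] = []
    for query in queries:
        truth = taxonomy[query.id]
        if mode == "loocv":
            search_set = [r for r in db if r.id != query.id]
        else:
            if query.id not in db_ids:
                raise ValueError(
                    f"no-LOOCV requires query {query.id!r} in the database"
                )
            search_set = db
        assignment = config.run(query, search_set, taxonomy, scheme, engine)
        records.append(EvalRecord.evaluate(query.id, truth, assignment.result))
    return records


@dataclass(frozen=True)
class BenchmarkSummary:
    """Frequency tables over a set of evaluation records."""

    correctness_hist: np.ndarray  # 7 bins, scores 0..6
    incorrectness_hist: np.ndarray
    category_table: pd.DataFrame  # ranks x categories counts


def summarize_frequencies(records: Sequence[EvalRecord]) -> BenchmarkSummary:
    """Histograms of the two indices plus the per-rank category counts."""
    if not records:
        raise ValueError("no evaluation records to summarize")
    n_bins = len(RANKS) + 1
    chist = np.zeros(n_bins, dtype=int)
    ihist = np.zeros(n_bins, dtype=int)
    table = pd.DataFrame(
        0, index=[r.label for r in RANKS], columns=list(CATEGORIES), dtype=int
    )
    for rec in records:
        chist[rec.correctness] += 1
        ihist[rec.incorrectness] += 1
        for rank, cat in zip(RANKS, rec.category_per_rank):
            table.loc[rank.label, cat] += 1
    return BenchmarkSummary(chist, ihist, table)


def write_eval_table(records: Sequence[EvalRecord], path: str | Path) -> None:
    """Write per-query evaluation results as TSV."""
    header = (
        ["queryid"]
        + [f"truth_{r.label}" for r in RANKS]
        + [f"assigned_{r.label}" for r in RANKS]
        + ["correctness", "incorrectness"]
        + [f"category_{r.label}" for r in RANKS]
    )
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            writer.writerow(
                [rec.query_id]
                + [rec.truth[r] or "" for r in RANKS]
                + [rec.assigned[r] or UNIDENTIFIED for r in RANKS]
                + [rec.correctness, rec.incorrectness]
                + list(rec.category_per_rank)
            )


def write_summary_table(summary: BenchmarkSummary, path: str | Path) -> None:
    """Write the frequency summary as a small multi-section TSV."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["section", "key"] + list(CATEGORIES))
        for score, count in enumerate(summary.correctness_hist.tolist()):
            writer.writerow(["correctness_hist", score, count, "", "", ""])
        for score, count in enumerate(summary.incorrectness_hist.tolist()):
            writer.writerow(["incorrectness_hist", score, count, "", "", ""])
        for rank, row in summary.category_table.iterrows():
            writer.writerow(["category", rank] + [int(row[c]) for c in CATEGORIES])
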