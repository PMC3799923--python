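"""Shared fixtures: hand-traceable score-table databases and a separable
synthetic reference database."""

from __future__ import annotations

import numpy as np
import pytest

from taxident import (
    ExactAligner,
    Lineage,
    ScoringScheme,
    SequenceRecord,
    SimulationSpec,
    TableAligner,
    TaxonomyTable,
    evolve_sequences,
)


def L(*taxa):
    """Shorthand lineage: pass None for a missing rank."""
    return Lineage(tuple(taxa))


@pytest.fixture
def table_scheme():
    """Admission threshold 1, as in the score-table hand traces."""
    return ScoringScheme(match_reward=1, mismatch_penalty=-2, gap_open=-5,
                         gap_extend=-2, min_score=1)


def make_records(*ids):
    # distinct residues per id so records are valid; scores come from tables
    return [SequenceRecord(id=i, residues="ACGT") for i in ids]


@pytest.fixture
def trio_fixture():
    """Three references of one family: two species of genus G, one of genus H.

    Score tables realise the canonical auto-method trace: Q's nearest
    neighbor is R1, R1's borderline is R2, and R3 is a more distant genus.
    """
    query = SequenceRecord(id="Q", residues="ACGT")
    db = make_records("R1", "R2", "R3")
    taxonomy = TaxonomyTable(
        {
            "R1": L("P", "C", "O", "F", "G", "S1"),
            "R2": L("P", "C", "O", "F", "G", "S2"),
            "R3": L("P", "C", "O", "F", "H", "S3"),
        }
    )
    scores = {
        ("Q", "R1"): 10, ("Q", "R2"): 7, ("Q", "R3"): 3,
        ("R1", "R1"): 12, ("R1", "R2"): 8, ("R1", "R3"): 4,
    }
    return query, db, taxonomy, TableAligner(scores)


@pytest.fixture
def trio_distant_borderline():
    """Variant where the borderline is farther from Q than a third genus,
    separating the QCauto and NNCauto radii."""
    query = SequenceRecord(id="Q", residues="ACGT")
    db = make_records("R1", "R2", "R3")
    taxonomy = TaxonomyTable(
        {
            "R1": L("P", "C", "O", "F", "G", "S1"),
            "R2": L("P", "C", "O", "F", "G", "S2"),
            "R3": L("P", "C", "O", "F", "H", "S3"),
        }
    )
    scores = {
        ("Q", "R1"): 10, ("Q", "R2"): 2, ("Q", "R3"): 3,
        ("R1", "R1"): 12, ("R1", "R2"): 8, ("R1", "R3"): 4,
    }
    return query, db, taxonomy, TableAligner(scores)


SEPARABLE_SPEC = SimulationSpec(seed=20121115)
SEPARABLE_SCHEME = ScoringScheme()  # defaults: +1/-2, gaps -5/-2, min_score 20
N_BENCH_QUERIES = 20
BENCH_QUERY_SEED = 7


@pytest.fixture(scope="session")
def separable_db():
    """64-species, one-record-per-species database with per-rank divergence
    decreasing from 0.12 (phylum) to 0.02 (species), length 150."""
    records, taxonomy = evolve_sequences(SEPARABLE_SPEC)
    return records, taxonomy


@pytest.fixture(scope="session")
def bench_queries(separable_db):
    """20 seeded queries drawn from the database itself."""
    records, _ = separable_db
    rng = np.random.default_rng(BENCH_QUERY_SEED)
    idx = sorted(rng.choice(len(records), size=N_BENCH_QUERIES, replace=False))
    return [records[i] for i in idx]


@pytest.fixture(scope="session")
def shared_aligner():
    """One alignment cache for every benchmark-style test in the session."""
    return ExactAligner(SEPARABLE_SCHEME)
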