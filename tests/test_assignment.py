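"""Assignment methods: borderline search, k-NN, n%-NN, NNCauto, QCauto."""

import pytest

from taxident import (
    AlignmentHit,
    Lineage,
    ScoringScheme,
    SequenceRecord,
    TableAligner,
    TaxonomyTable,
    assign_knn,
    assign_nncauto,
    assign_percent_nn,
    assign_qcauto,
    find_borderline,
)
from taxident.taxonomy import Rank

from conftest import L, make_records


def hit(subject_id, score, pid=100.0, length=10):
    return AlignmentHit(subject_id, score, pid, length)


TABLE_SCHEME = ScoringScheme(1, -2, -5, -2, 1)


class TestFindBorderline:
    def test_single_borderline(self):
        hits = [hit("A", 12), hit("R2", 8), hit("R3", 4)]
        assert find_borderline(hits, 10) == ({"R2"}, 8)

    def test_no_farther_sequence(self):
        assert find_borderline([hit("A", 12)], 10) == (set(), None)

    def test_tied_borderlines(self):
        hits = [hit("A", 12), hit("R2", 8), hit("R4", 8), hit("R3", 4)]
        assert find_borderline(hits, 10) == ({"R2", "R4"}, 8)

    def test_farther_means_strictly_smaller_score(self):
        # a hit tied with Q's score is an additional nearest neighbor,
        # not a borderline candidate
        hits = [hit("A", 12), hit("R2", 10), hit("R3", 4)]
        assert find_borderline(hits, 10) == ({"R3"}, 4)


class TestKnn:
    def test_exact_match_k1_returns_full_lineage(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        a = assign_knn(query, db, taxonomy, k=1, scheme=TABLE_SCHEME,
                       aligner=aligner)
        assert a.result == taxonomy["R1"]
        assert a.supporting_ids == {"R1"}

    def test_k2_congeners_give_genus(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        a = assign_knn(query, db, taxonomy, k=2, scheme=TABLE_SCHEME,
                       aligner=aligner)
        assert a.result == L("P", "C", "O", "F", "G", None)

    def test_fewer_hits_than_k(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        a = assign_knn(query, db, taxonomy, k=5, scheme=TABLE_SCHEME,
                       aligner=aligner)
        # only 3 hits pass min_score; LCA spans both genera -> family
        assert a.result == L("P", "C", "O", "F", None, None)

    def test_no_hits_unidentified(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        strict = ScoringScheme(1, -2, -5, -2, 50)
        a = assign_knn(query, db, taxonomy, k=1, scheme=strict, aligner=aligner)
        assert a.result == Lineage.empty()
        assert a.supporting_ids == frozenset()

    def test_hit_without_taxonomy_entry_raises(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        bare = TaxonomyTable({"R1": taxonomy["R1"]})
        with pytest.raises(KeyError):
            assign_knn(query, db, bare, k=2, scheme=TABLE_SCHEME,
                       aligner=aligner)


class TestPercentNN:
    def _setup(self):
        query = SequenceRecord(id="Q", residues="ACGT")
        db = make_records("R1", "R2", "R3")
        taxonomy = TaxonomyTable(
            {
                "R1": L("P", "C", "O", "F", "G", "S1"),
                "R2": L("P", "C", "O", "F", "G", "S2"),
                "R3": L("P", "C", "O", "F", "H", "S3"),
            }
        )
        aligner = TableAligner(
            {
                ("Q", "R1"): (10, 100.0),
                ("Q", "R2"): (8, 97.5),
                ("Q", "R3"): (3, 88.0),
            }
        )
        return query, db, taxonomy, aligner

    def test_exact_duplicate_at_100_percent(self):
        query, db, taxonomy, aligner = self._setup()
        a = assign_percent_nn(query, db, taxonomy, 100.0, scheme=TABLE_SCHEME,
                              aligner=aligner)
        assert a.result == taxonomy["R1"]

    def test_97_percent_admits_congeners(self):
        query, db, taxonomy, aligner = self._setup()
        a = assign_percent_nn(query, db, taxonomy, 97.0, scheme=TABLE_SCHEME,
                              aligner=aligner)
        assert a.supporting_ids == {"R1", "R2"}
        assert a.result == L("P", "C", "O", "F", "G", None)

    def test_no_hit_reaches_cutoff(self):
        query, db, taxonomy, aligner = self._setup()
        aligner = TableAligner({("Q", "R1"): (10, 95.0)})
        a = assign_percent_nn(query, db, taxonomy, 99.0, scheme=TABLE_SCHEME,
                              aligner=aligner)
        assert a.result == Lineage.empty()

    def test_cap_truncates_like_knn(self):
        query, db, taxonomy, aligner = self._setup()
        capped = assign_percent_nn(query, db, taxonomy, 0.0, cap=1,
                                   scheme=TABLE_SCHEME, aligner=aligner)
        one_nn = assign_knn(query, db, taxonomy, k=1, scheme=TABLE_SCHEME,
                            aligner=aligner)
        assert capped.result == one_nn.result
        assert capped.supporting_ids == one_nn.supporting_ids


class TestNNCauto:
    def test_canonical_trace(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        a, trace = assign_nncauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                  aligner=aligner)
        assert trace.nearest_neighbors == {"R1"}
        assert trace.score_qa == 10
        assert trace.borderlines == {"R2"}
        assert trace.threshold_score == 8
        assert trace.neighborhood == {"R1", "R2"}
        assert a.result == L("P", "C", "O", "F", "G", None)

    def test_single_reference_db_unidentified(self):
        query = SequenceRecord(id="Q", residues="ACGT")
        db = make_records("R1")
        taxonomy = TaxonomyTable({"R1": L("P", "C", "O", "F", "G", "S1")})
        aligner = TableAligner({("Q", "R1"): 10, ("R1", "R1"): 12})
        a, trace = assign_nncauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                  aligner=aligner)
        assert a.result == Lineage.empty()
        assert trace.borderlines == set()

    def test_conspecific_borderline_allows_species_assignment(self):
        query = SequenceRecord(id="Q", residues="ACGT")
        db = make_records("R1", "R1b", "R2")
        taxonomy = TaxonomyTable(
            {
                "R1": L("P", "C", "O", "F", "G", "S1"),
                "R1b": L("P", "C", "O", "F", "G", "S1"),
                "R2": L("P", "C", "O", "F", "G", "S2"),
            }
        )
        aligner = TableAligner(
            {
                ("Q", "R1"): 10, ("Q", "R1b"): 9, ("Q", "R2"): 7,
                ("R1", "R1"): 12, ("R1", "R1b"): 9, ("R1", "R2"): 8,
            }
        )
        a, trace = assign_nncauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                  aligner=aligner)
        assert trace.borderlines == {"R1b"}
        assert trace.neighborhood == {"R1", "R1b"}
        assert a.result[Rank.SPECIES] == "S1"

    def test_borderline_stricter_than_query_radius(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        _, trace = assign_nncauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                  aligner=aligner)
        assert trace.threshold_score < trace.score_qa


class TestQCauto:
    def test_canonical_trace(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        a, trace = assign_qcauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                 aligner=aligner)
        assert trace.threshold_score == 7  # score of Q to the borderline R2
        assert trace.neighborhood == {"R1", "R2"}
        assert a.result == L("P", "C", "O", "F", "G", None)

    def test_query_radius_spans_more_than_neighbor_radius(
        self, trio_distant_borderline
    ):
        # QCauto's radius reaches R3 (a second genus) so it truncates to
        # family while NNCauto still reports the genus
        query, db, taxonomy, aligner = trio_distant_borderline
        qc, qtrace = assign_qcauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                   aligner=aligner)
        nn, _ = assign_nncauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                               aligner=aligner)
        assert qtrace.threshold_score == 2
        assert qtrace.neighborhood == {"R1", "R2", "R3"}
        assert qc.result == L("P", "C", "O", "F", None, None)
        assert nn.result == L("P", "C", "O", "F", "G", None)

    def test_lone_exact_duplicate_unidentified(self):
        query = SequenceRecord(id="Q", residues="ACGT")
        db = make_records("R1")
        taxonomy = TaxonomyTable({"R1": L("P", "C", "O", "F", "G", "S1")})
        aligner = TableAligner({("Q", "R1"): 4, ("R1", "R1"): 4})
        a, _ = assign_qcauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                             aligner=aligner)
        assert a.result == Lineage.empty()

    def test_trace_containment_invariants(self, trio_fixture):
        query, db, taxonomy, aligner = trio_fixture
        _, trace = assign_qcauto(query, db, taxonomy, scheme=TABLE_SCHEME,
                                 aligner=aligner)
        assert trace.nearest_neighbors <= trace.neighborhood
        assert trace.borderlines <= trace.neighborhood
        assert trace.threshold_score <= trace.score_qa


class TestNeighborhoodPropertiesOnRealAlignments:
    """The containment and radius invariants on true alignment scores."""

    def test_invariants_on_synthetic_db(self, separable_db, bench_queries,
                                        shared_aligner):
        from conftest import SEPARABLE_SCHEME

        records, taxonomy = separable_db
        db_wo = lambda q: [r for r in records if r.id != q.id]
        for query in bench_queries[:6]:
            db = db_wo(query)
            _, nn_trace = assign_nncauto(query, db, taxonomy,
                                         scheme=SEPARABLE_SCHEME,
                                         aligner=shared_aligner)
            _, qc_trace = assign_qcauto(query, db, taxonomy,
                                        scheme=SEPARABLE_SCHEME,
                                        aligner=shared_aligner)
            for trace in (nn_trace, qc_trace):
                assert trace.nearest_neighbors <= trace.neighborhood
                assert trace.borderlines <= trace.neighborhood
            if nn_trace.threshold_score is not None:
                assert nn_trace.threshold_score < nn_trace.score_qa
            if qc_trace.threshold_score is not None:
                assert qc_trace.threshold_score <= qc_trace.score_qa

    def test_qcauto_never_species_level_without_own_record(
        self, separable_db, bench_queries, shared_aligner
    ):
        # one record per species: the nearest neighbor and the borderline
        # are necessarily different species once the query is removed
        from conftest import SEPARABLE_SCHEME

        records, taxonomy = separable_db
        for query in bench_queries[:6]:
            db = [r for r in records if r.id != query.id]
            a, _ = assign_qcauto(query, db, taxonomy, scheme=SEPARABLE_SCHEME,
                                 aligner=shared_aligner)
            assert a.result[Rank.SPECIES] is None
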