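"""Classify a query against a reference database with several methods.

The query is a reference sequence trimmed to a 100-nt window ("mini-
barcode"), so it is similar but not identical to its own record.
"""

from taxident import (
    ExactAligner,
    DEFAULT_SCHEME,
    SimulationSpec,
    evolve_sequences,
    make_minibarcode,
    assign_knn,
    assign_percent_nn,
    assign_qcauto,
    UNIDENTIFIED,
)

records, taxonomy = evolve_sequences(SimulationSpec(seed=20121115))
query = make_minibarcode(records[10], window=100, seed=1)
engine = ExactAligner(DEFAULT_SCHEME)  # shared alignment cache

results = {
    "1-NN": assign_knn(query, records, taxonomy, k=1, aligner=engine),
    "5-NN": assign_knn(query, records, taxonomy, k=5, aligner=engine),
    "97%-NN": assign_percent_nn(query, records, taxonomy, 97.0, cap=100,
                                aligner=engine),
    "QCauto": assign_qcauto(query, records, taxonomy, aligner=engine)[0],
}

print(f"query {query.id} (truth: {' / '.join(taxonomy[query.id].taxa)})")
for name, a in results.items():
    taxa = " / ".join(t or UNIDENTIFIED for t in a.result.taxa)
    print(f"{name:8s} -> {taxa}  [{len(a.supporting_ids)} neighbors]")
# 1-NN names the full lineage of the single best hit; the wider-retrieval
# methods truncate to the lowest rank on which all their neighbors agree.
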