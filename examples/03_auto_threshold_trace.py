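"""Trace the automatic neighborhood radius of NNCauto and QCauto.

Both methods find the query's nearest neighbor A and then the "borderline"
reference B: the reference closest to A among those farther from A than the
query is. B sets the retrieval radius -- around A for NNCauto, around the
query for QCauto -- instead of a user-chosen k or identity cutoff.
"""

from taxident import (
    ExactAligner,
    DEFAULT_SCHEME,
    SimulationSpec,
    assign_nncauto,
    assign_qcauto,
    evolve_sequences,
)

records, taxonomy = evolve_sequences(SimulationSpec(seed=20121115))
query = records[3]
db = [r for r in records if r.id != query.id]  # unknown-species situation
engine = ExactAligner(DEFAULT_SCHEME)

for name, method in (("NNCauto", assign_nncauto), ("QCauto", assign_qcauto)):
    assignment, trace = method(query, db, taxonomy, aligner=engine)
    lowest = [t for t in assignment.result.taxa if t is not None]
    print(f"{name}: A={sorted(trace.nearest_neighbors)} "
          f"score(Q,A)={trace.score_qa} B={sorted(trace.borderlines)} "
          f"threshold={trace.threshold_score} "
          f"|N|={len(trace.neighborhood)}")
    print(f"  -> assigned down to: {lowest[-1] if lowest else 'unidentified'}")
# The threshold score is the raw alignment score at the borderline; every
# reference scoring at least that much enters the lowest-common-ancestor
# step, so the assignment is the lowest rank on which they all agree.
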