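"""Screen similarity-search hits and trim an alignment.

Builds a tiny hit table and alignment in memory, applies the standard
screening rules (identity >= 30 %, E-value < 1e-50, coverage >= 50 %,
column score >= 0.40) and prints what survives and why the rest fell.
"""

from famclade import (
    Alignment,
    FilterConfig,
    HitRecord,
    SequenceRecord,
    column_scores,
    filter_hits,
    gap_filter,
    trim_columns,
)


def hit(sid, pid, ev, alen):
    return HitRecord("query", sid, pid, alen, "0", "0", "1", str(alen),
                     "1", str(alen), ev, "100")


hits = [
    hit("good", 45.0, 1e-80, 90),    # passes every rule
    hit("too_diverged", 22.0, 1e-80, 90),
    hit("weak_evalue", 45.0, 1e-30, 90),
    hit("fragment", 45.0, 1e-80, 30),  # only 30 of 100 query columns
]
accepted, rejected = filter_hits(hits, {"query": 100}, FilterConfig())
print("accepted:", [h.subject_id for h in accepted])
for h, reason in rejected:
    print(f"rejected {h.subject_id}: failed the {reason} rule")

aln = Alignment(
    [
        SequenceRecord("good", "MKLVDELKKQGW"),
        SequenceRecord("cousin", "MKLVDDLKRQGW"),
        SequenceRecord("distant", "MKIVEDLRKQGW"),
        SequenceRecord("gappy", "MK----------"),  # 10/12 gaps: excluded
    ]
)
kept, excluded = gap_filter(aln)
print("\ngap filter excluded:", excluded, "(more than 30% of columns are gaps)")

trimmed, kept_cols = trim_columns(kept)
scores = column_scores(kept)
print(f"column trimming kept {len(kept_cols)} of {kept.length} columns")
print("per-column scores:", [round(float(s), 2) for s in scores])
# A score is the fraction of residue pairs in the column with a positive
# BLOSUM62 entry; columns below 0.40 are judged unreliable and removed.
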