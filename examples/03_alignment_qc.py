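"""Score alignment completeness and apply the pre-tree filtering rules."""

from nacfam.msa import AlignmentMatrix, completeness, dedup, filter_sequences, mask_columns

msa = AlignmentMatrix(
    ["g1", "g2", "g3", "g4", "g5"],
    [
        "MKVLWAALLVTFLAGCQA",
        "MKVLWAALLVTFLAGCQA",   # exact duplicate of g1
        "MKVLWAALLXXXLAGCQA",
        "MKXLWAAL------GCQA",
        "--------------GC--",   # barely overlaps anything
    ],
)
report = completeness(msa)
print(f"overall completeness Ca = {report.Ca:.3f}")

kept, removed = filter_sequences(msa, report, cij_cutoff=0.5)
print(f"removed (max Cij < 0.5) : {removed}")

masked = mask_columns(kept, completeness(kept), cc_cutoff=0.6)
print(f"sites after masking     : {masked.n_sites} of {msa.n_sites}")

unique, surplus = dedup(masked)
print(f"unique sequences        : {unique.n_rows}, surplus map {surplus}")

# Ca is the fraction of filled alignment cells; the three steps mirror the
# usual pre-phylogeny hygiene: drop sequences that share too few sites with
# any partner, mask sparse columns, and collapse identical rows (the surplus
# map re-attaches them next to their twin after tree inference).
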