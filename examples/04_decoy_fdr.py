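"""Estimate the false discovery rate with half-swap decoy exons.

Each decoy exon swaps the first and second halves of the real exon
sequence, destroying the true boundary context while preserving base
composition.  Junction calling against decoy boundary windows with
identical thresholds counts chance matches; FDR = decoy / target calls.
"""

from mawsplice import (
    ExonModel,
    ReferenceSet,
    build_decoy_boundary_index,
    compute_fdr,
    make_decoy_exons,
)

ref = ReferenceSet.from_dict({"chr1": "TTTTACGTTGCAGGTTTT"})
exon = ExonModel("exonA", "chr1", 4, 12, "+")  # sequence ACGTTGCA

decoy, = make_decoy_exons([exon], ref)
print(f"exon sequence:  ACGTTGCA")
print(f"decoy sequence: {decoy.decoy_seq}  (halves exchanged)")

bindex = build_decoy_boundary_index([decoy], window=4)
entry = bindex.entries[0]
print(f"decoy donor window (end): {entry.end_window}; "
      f"acceptor window (start): {entry.start_window}")

# With no decoy matches the FDR is 0; an undefined ratio (no target
# calls at all) is reported as None rather than 0.
report = compute_fdr(target_calls=[], decoy_calls=[])
print(f"FDR with no target calls: {report.fdr} (defined={report.defined})")
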