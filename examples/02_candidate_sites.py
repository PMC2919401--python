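"""Locate candidate splice sites on a read from its MAW occurrences.

A splice junction inside a genome-unexplainable read can only sit
strictly inside a MAW occurrence that overlaps no other occurrence, or
inside the shared part of overlapping occurrences.  The 9-nt read
below carries three MAWs; only three cuts survive the rule.
"""

from mawsplice import MAWRecord, bar_notation, canonical_form, enumerate_candidate_sites
from mawsplice.maws import MAWOccurrence

read = "ACCGGCACT"
occurrences = [
    MAWOccurrence(MAWRecord(w, canonical_form(w)), offset)
    for w, offset in (("ACC", 0), ("GCA", 4), ("CAC", 5))
]

sites = enumerate_candidate_sites(len(read), occurrences)
print(f"read: {read}")
print(f"MAW occurrences: ACC@0, GCA@4, CAC@5")
print(f"candidate cuts: {list(sites.cut_indices)}  "
      f"(occurrence groups: {sites.n_groups})")
print(f"bar notation: {bar_notation(read, sites)}")
# ACC overlaps nothing, so both its internal cuts (1, 2) qualify;
# GCA and CAC overlap on 'CA', whose single internal cut is 6.
# A cut index i means 'between characters i-1 and i'.
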