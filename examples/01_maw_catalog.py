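"""Enumerate the minimal absent words of a small reference.

A minimal absent word (MAW) is a string absent from the reference
whose two flank-drops (first or last character removed) are both
present.  MAWs are the 'splicing fingerprints' of the method: any read
the genome cannot explain must contain one.
"""

from mawsplice import ReferenceSet, build_index, enumerate_maws

ref = ReferenceSet.from_dict({"chr1": "ACGT"}, strand_mode="forward")
index = build_index(ref)
catalog = enumerate_maws(index, max_length=4)

print(f"reference: ACGT (forward strand only)")
print(f"MAW catalog ({len(catalog)} words): {sorted(catalog.words)}")
# The 4-letter text contains only the dimers AC, CG, GT, so the other
# 13 dimers are minimal absent words; no longer MAW exists because the
# flanks of any longer candidate are themselves absent.

for word in sorted(catalog.words)[:3]:
    print(f"  {word}: absent={not index.has_substring(word)}, "
          f"flanks present={index.has_substring(word[:-1])} / "
          f"{index.has_substring(word[1:])}")

# Under both-strands mode the catalog is closed under reverse
# complement, and each word carries a canonical (strand-free) form:
both = enumerate_maws(build_index(ReferenceSet.from_dict({"chr1": "ACGT"})), 4)
rec = sorted(both.records, key=lambda r: r.word)[0]
print(f"both-strands catalog size: {len(both)}; "
      f"example record word={rec.word} canonical={rec.canonical}")
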