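# Methods

## Model

Let *S* be the reference text. Unless forward-only mode is requested,
presence is evaluated over *S* together with its reverse complement,
and windows containing `N` are excluded (sequences are split at `N`
runs before indexing, so no fingerprint can arise from an assembly
gap). A word *w* with |*w*| ≥ 2 is a **minimal absent word** (MAW) if
*w* is absent while *w*[1:] and *w*[:−1] are both present. Length-1
absent letters are excluded: minimality requires both flank-drops to
be testable, and a single letter has none. Under both-strands mode the
MAW set is closed under reverse complement, so each word is stored
with a canonical form (the lexicographic minimum of the word and its
reverse complement) that serves as the cluster key.

Three consequences drive the pipeline. (i) Any absent word contains a
MAW, so a read the genome cannot explain carries at least one
fingerprint, and contrapositively a read with no catalog MAW (catalog
cap ≥ read length) is an exact genomic substring. (ii) In a read that
spans a single novel junction, the flanking sequence on either side of
the cut is genomic, so every MAW occurrence in the read straddles the
cut. (iii) The cut can only lie strictly inside an occurrence that
overlaps no other occurrence, or strictly inside the intersection of
overlapping occurrences — this defines the candidate cut set.

## Data structures

The substring index is a suffix automaton over the N-free segments
joined with a separator character; queries are restricted to
`{A,C,G,T}` and can never cross a separator, so membership in the
joined text equals membership in some segment. Query cost is
proportional to the word length. The automaton is built lazily; batch
consumers work directly on the segments:

* **MAW enumeration** advances a k-mer frontier with vectorised
  integer codes. For each length k, candidates are a·u over all
  present (k−1)-mers u and bases a (every MAW's suffix is a present
  (k−1)-mer, so this is exhaustive), filtered for absence at length k
  and presence of the length-(k−1) prefix. Only observed substrings
  are touched, never all 4^k words. The loop is gated on the
  (k−1)-frontier, not the k-frontier, because a MAW can exceed the
  longest segment by one (both flanks full-length segments).
* **Mappability** uses pigeonhole seeding: the read is split into
  max_mismatches+1 contiguous parts; any window within the budget must
  contain one part exactly. Part hits come from sorted k-mer position
  indexes per chromosome and are verified by vectorised Hamming
  comparison, on both strands. Substitutions only — indels are not
  modelled for 25-mers. Genomic `N` counts as a mismatch to every
  base.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| maw_max_len | read length | MAW catalog cap; longer MAWs cannot occur in a read |
| max_mm_filter | 2 | Hamming radius for the "explainable by genome" drop |
| min_cluster_size | 5 | distinct reads required to emit a cluster |
| min_depth | 5 | per-column read depth kept in a consensus |
| max_read_mismatch | 1 | member/consensus disagreement before pruning |
| min_overlap | 10 nt | exact overlap required to merge two consensi |
| min_match | 5 nt | minimum prefix/suffix length matched to an exon boundary |
| max_mm_per_side | 1 | boundary-match mismatch budget, per side |
| boundary_window | 40 nt | exon end/start window length (clamped to short exons) |
| flank | 24 nt | per-side length of exported junction sequences (48-mers) |

Consensus construction stacks members gap-free at the offset of the
key MAW (members whose occurrence is the reverse complement of the
canonical form are re-oriented first), takes a per-column majority
with ties broken A < C < G < T, restricts to the maximal contiguous
run of depth ≥ min_depth columns containing the anchor, prunes members
above the mismatch budget and iterates to a fixed point (cap 10
iterations). Merging requires an *exact* overlap ≥ min_overlap
(suffix–prefix or containment, either orientation); a conflicted
overlap region simply fails the exactness test and the pair stays
separate. Merged depths are column-wise sums and candidate cut sets
are unioned with coordinates lifted.

## Design choices where the design was open

* "Up to 1 mismatch at either boundary" is read as ≤ 1 mismatch on
  *each* side of the cut, not 1 in total; the per-side budget is
  configurable.
* A read whose occurrences form more than one disjoint group cannot
  arise from a single splicing event; such reads are *flagged*
  (`multi_group`), not discarded, because cuts in every group are
  still well-defined and the worked example itself has two groups.
* For overlap groups with ≥ 3 members the candidate cuts are the union
  of interior cuts of each overlapping *pair* (a global-intersection
  mode is available); the pairwise reading is the literal extension of
  the two-MAW case.
* Donor/acceptor pairing is unconstrained by chromosome or gene;
  `same_chrom`/`same_gene` restriction flags exist. Self-pairs are
  flagged, not dropped. Deduplication is on the exact genomic
  coordinate pair, support counting distinct read IDs.
* Decoys swap exon halves at ⌊L/2⌋ (second half first, hence the
  longer half leads for odd lengths); decoy boundary windows come from
  the decoy sequence itself, and the decoy pass runs separately from
  the target pass with the identical configuration — the FDR is the
  ratio of distinct decoy calls to distinct target calls, and is
  reported as undefined (not zero) when there are no target calls.
* Depth trimming keeps one contiguous qualifying run containing the
  anchor rather than all qualifying columns; a consensus with no such
  run is discarded.
* Reads containing `N` are dropped at load time and counted in the
  filtration report.

## Synthetic data

The generator emulates the target input regime: an i.i.d. uniform
genome (default 200 kb), non-overlapping exons (default 100, lengths
80–200 nt, separated by at least one read length), junctions joining
distinct exon pairs split into *near* and *distant* classes (default
30 junctions, half with inter-exon gap ≥ 20 kb — a desk-scale stand-in
for genome-scale intron distances), fixed-length 25-nt spanning reads
with uniform cut offsets (≥ 1 nt on each side), i.i.d. substitution
errors (default 0.5%), half the reads reverse-complemented, and
background reads sampled from the genome. Everything derives from one
seed and the truth set records per-read provenance (origin junction,
offset, orientation, injected error positions), so any read can be
reconstructed. An optional repeat-injection knob copies a genomic
segment several times to exercise the mappability filter.

What the simulation does *not* model: repeat structure and low
complexity sequence (beyond the optional knob), indels, quality
scores, expression-level variation, SNPs against the reference, and
annotation errors. Passing tests on this data therefore demonstrate
the algorithmic guarantees (fingerprint and splice-site properties,
exact-coordinate recovery, decoy behaviour under the null) rather than
performance on real tissue libraries, where repeats and genome
variants are the dominant failure modes.

Two systematic effects are expected and intentional. Spanning reads
overhanging the junction by only 1–2 nt are usually within the
2-mismatch Hamming radius of the window aligned on their long side and
are removed by the mappability filter — this is the filter working as
designed, and it does not impede junction recovery because central
offsets dominate. And at 0.5% error, reads with ≥ 2 errors are pruned
at the consensus stage (≈ 0.7% of reads), which the 5-fold depth
requirement absorbs easily at high coverage.

## Problem sizes and numerics

The shipped experiments run a 200 kb genome (≈ 730 k catalog MAWs at
cap 25), 10,000 reads, and 30–50 junctions; a full pipeline pass takes
well under a minute on one core. Reported sensitivities use strict
coordinate matching (a called junction must hit both true cut
coordinates exactly; a ± 2 nt lenient mode exists). All iteration
orders are deterministic (sorted cluster keys, stable merges, fixed
tie-breaks), so a seed fixes every output byte.

## Known limitations

Approximate (mismatch-tolerant) MAW matching is not implemented; a
sequencing error inside the only straddling MAW of a read hides that
read from its cluster. Junctions whose boundary context is repeated
elsewhere in the genome produce ambiguous calls (all reported). Exons
shorter than min_match cannot anchor a boundary match. Paired-end
information and known-transcript annotation filtering are out of
scope.
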