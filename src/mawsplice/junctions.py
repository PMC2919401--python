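"""Junction calling: match consensus prefix/suffix against exon
boundary windows.

Each candidate cut splits a consensus into a prefix and a suffix.  The
prefix is compared against the transcript-sense *end* window of every
exon (donor side) and the suffix against every *start* window
(acceptor side); a junction is called when both sides match with at
most one mismatch each and a matched length of at least ``min_match``
nucleotides.  There is no constraint on the genomic distance between
the two exons -- distant and cross-chromosome pairs are called exactly
like adjacent ones.

All genomic coordinates are 0-based half-open; the called junction
coordinates are the donor exon's transcript-end boundary and the
acceptor exon's transcript-start boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ConsensusSequence
from .maws import encode_seq
from .reference import ReferenceSet, revcomp

DEFAULT_BOUNDARY_WINDOW = 40
DEFAULT_MIN_MATCH = 5
DEFAULT_MAX_MM_PER_SIDE = 1
DEFAULT_FLANK = 24

_PAD = 99  # never equals a base code (0..3) or N (4)


@dataclass(frozen=True)
class ExonModel:
    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"exon {self.exon_id}: invalid interval [{self.start},{self.end})")
        if self.end - self.start < 2:
            raise ValueError(f"exon {self.exon_id}: length must be >= 2")
        if self.strand not in "+-":
            raise ValueError(f"exon {self.exon_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


def exon_transcript_seq(exon: ExonModel, ref: ReferenceSet) -> str:
    """Exon sequence in transcript sense (reverse-complemented for -)."""
    chrom_seq = ref.get(exon.chrom)
    if exon.end > len(chrom_seq):
        raise ValueError(
            f"exon {exon.exon_id} extends beyond {exon.chrom} "
            f"({exon.end} > {len(chrom_seq)})"
        )
    seq = chrom_seq[exon.start:exon.end]
    return revcomp(seq) if exon.strand == "-" else seq


def read_exons_bed(path: str | Path) -> list[ExonModel]:
    """Exon models from a BED6 file (name column = exon id)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return [
        ExonModel(exon_id=str(r.name), chrom=str(r.chrom), start=int(r.start),
                  end=int(r.end), strand=str(r.strand))
        for r in df.itertuples(index=False)
    ]


def read_exons_gtf(path: str | Path) -> list[ExonModel]:
    """Exon features from a GTF file; honours gene_id and exon_id."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    exons = []
    for i, r in enumerate(df.itertuples(index=False)):
        exon_id = getattr(r, "exon_id", None) or f"exon{i}"
        gene_id = getattr(r, "gene_id", None)
        exons.append(ExonModel(
            exon_id=str(exon_id), chrom=str(r.Chromosome), start=int(r.Start),
            end=int(r.End), strand=str(r.Strand), gene_id=gene_id,
        ))
    return exons


@dataclass(frozen=True)
class BoundaryEntry:
    """Donor/acceptor windows and junction coordinates for one exon."""

    exon_id: str
    chrom: str
    strand: str
    gene_id: str | None
    end_window: str  # last W nt in transcript sense (donor side)
    start_window: str  # first W nt in transcript sense (acceptor side)
    donor_coord: int  # genomic boundary of the transcript end
    acceptor_coord: int  # genomic boundary of the transcript start
    start: int
    end: int
    source: str = "target"


class BoundaryIndex:
    """Padded code matrices over exon boundary windows enabling
    vectorised <=1-mismatch prefix/suffix matching across all exons."""

    def __init__(self, entries: list[BoundaryEntry], window: int) -> None:
        self.entries = entries
        self.window = window
        n = len(entries)
        self._end_mat = np.full((n, window), _PAD, dtype=np.int64)
        self._start_mat = np.full((n, window), _PAD, dtype=np.int64)
        for i, e in enumerate(entries):
            ev = encode_seq(e.end_window)
            sv = encode_seq(e.start_window)
            self._end_mat[i, window - len(ev):] = ev  # right-aligned
            self._start_mat[i, :len(sv)] = sv  # left-aligned

    def match_donors(self, prefix: str, max_mm: int) -> list[tuple[int, int]]:
        """(entry index, mismatches) for end windows whose suffix matches
        the prefix (truncated to the window length if longer)."""
        p = min(len(prefix), self.window)
        if p == 0 or not self.entries:
            return []
        pv = encode_seq(prefix[-p:])
        mm = np.count_nonzero(self._end_mat[:, self.window - p:] != pv, axis=1)
        return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mm)[0]]

    def match_acceptors(self, suffix: str, max_mm: int) -> list[tuple[int, int]]:
        p = min(len(suffix), self.window)
        if p == 0 or not self.entries:
            return []
        sv = encode_seq(suffix[:p])
        mm = np.count_nonzero(self._start_mat[:, :p] != sv, axis=1)
        return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mm)[0]]


def build_boundary_index(
    exons: list[ExonModel],
    ref: ReferenceSet,
    window: int = DEFAULT_BOUNDARY_WINDOW,
) -> BoundaryIndex:
    """Extract transcript-sense boundary windows for every exon.

    Exons shorter than ``window`` contribute their full length on both
    sides.  The donor coordinate is the genomic position of the
    transcript end (``end`` for + exons, ``start`` for -), the acceptor
    coordinate that of the transcript start.
    """
    entries = []
    for exon in exons:
        tx = exon_transcript_seq(exon, ref)
        w = min(window, len(tx))
        donor = exon.end if exon.strand == "+" else exon.start
        acceptor = exon.start if exon.strand == "+" else exon.end
        entries.append(BoundaryEntry(
            exon_id=exon.exon_id, chrom=exon.chrom, strand=exon.strand,
            gene_id=exon.gene_id, end_window=tx[-w:], start_window=tx[:w],
            donor_coord=donor, acceptor_coord=acceptor,
            start=exon.start, end=exon.end,
        ))
    return BoundaryIndex(entries, window)


@dataclass
class JunctionCall:
    donor_exon_id: str
    acceptor_exon_id: str
    donor_chrom: str
    acceptor_chrom: str
    donor_coord: int
    acceptor_coord: int
    donor_strand: str
    acceptor_strand: str
    cut_index: int
    support: int
    supporting_reads: frozenset[str]
    mismatches: tuple[int, int]  # (prefix side, suffix side)
    distance: int | None  # genomic gap; None across chromosomes
    cross_chrom: bool
    self_pair: bool
    source: str = "target"
    gene_pair: tuple[str | None, str | None] = (None, None)

    @property
    def key(self) -> tuple:
        return (self.donor_chrom, self.donor_coord,
                self.acceptor_chrom, self.acceptor_coord)


def _distance(a: BoundaryEntry, b: BoundaryEntry) -> tuple[int | None, bool]:
    if a.chrom != b.chrom:
        return None, True
    if a.start < b.start:
        lo_end, hi_start = a.end, b.start
    else:
        lo_end, hi_start = b.end, a.start
    return max(0, hi_start - lo_end), False


def match_junction(
    consensus: ConsensusSequence | str,
    cut: int,
    bindex: BoundaryIndex,
    min_match: int = DEFAULT_MIN_MATCH,
    max_mm_per_side: int = DEFAULT_MAX_MM_PER_SIDE,
    same_gene: bool = False,
    same_chrom: bool = False,
    support_reads: frozenset[str] | None = None,
    source: str = "target",
) -> list[JunctionCall]:
    """All (donor, acceptor) exon pairs compatible with splitting the
    consensus at ``cut``.  Cuts whose prefix or suffix is shorter than
    ``min_match`` yield no calls (skipped, not an error).

    Orientation handling is the caller's job: this matches the
    consensus exactly as given (see :func:`call_junctions`, which tries
    both orientations).
    """
    seq = consensus.seq if isinstance(consensus, ConsensusSequence) else consensus
    if not (0 < cut < len(seq)):
        raise ValueError(f"cut {cut} outside sequence of length {len(seq)}")
    prefix, suffix = seq[:cut], seq[cut:]
    if len(prefix) < min_match or len(suffix) < min_match:
        return []
    donors = bindex.match_donors(prefix, max_mm_per_side)
    if not donors:
        return []
    acceptors = bindex.match_acceptors(suffix, max_mm_per_side)
    calls = []
    if support_reads is None and isinstance(consensus, ConsensusSequence):
        support_reads = consensus.read_ids
    for di, dmm in donors:
        d = bindex.entries[di]
        for ai, amm in acceptors:
            a = bindex.entries[ai]
            if same_chrom and d.chrom != a.chrom:
                continue
            if same_gene and (d.gene_id is None or d.gene_id != a.gene_id):
                continue
            dist, cross = _distance(d, a)
            calls.append(JunctionCall(
                donor_exon_id=d.exon_id, acceptor_exon_id=a.exon_id,
                donor_chrom=d.chrom, acceptor_chrom=a.chrom,
                donor_coord=d.donor_coord, acceptor_coord=a.acceptor_coord,
                donor_strand=d.strand, acceptor_strand=a.strand,
                cut_index=cut, support=len(support_reads or frozenset()),
                supporting_reads=support_reads or frozenset(),
                mismatches=(dmm, amm), distance=dist, cross_chrom=cross,
                self_pair=(d.exon_id == a.exon_id), source=source,
            ))
    return calls


def call_junctions(
    consensi: list[ConsensusSequence],
    bindex: BoundaryIndex,
    min_match: int = DEFAULT_MIN_MATCH,
    max_mm_per_side: int = DEFAULT_MAX_MM_PER_SIDE,
    same_gene: bool = False,
    same_chrom: bool = False,
    source: str = "target",
) -> list[JunctionCall]:
    """Union of junction matches over all consensi, candidate cuts and
    both consensus orientations, deduplicated on the exact genomic cut
    coordinate pair with support summed over distinct reads."""
    merged: dict[tuple, JunctionCall] = {}
    reads_by_key: dict[tuple, set[str]] = {}
    for cons in consensi:
        cuts = cons.candidate_cuts.cut_indices if cons.candidate_cuts else ()
        variants = [(cons.seq, cuts)]
        variants.append((revcomp(cons.seq), tuple(len(cons.seq) - c for c in cuts)))
        for seq, vcuts in variants:
            for cut in vcuts:
                if not (0 < cut < len(seq)):
                    continue
                for call in match_junction(
                    seq, cut, bindex, min_match=min_match,
                    max_mm_per_side=max_mm_per_side, same_gene=same_gene,
                    same_chrom=same_chrom, support_reads=cons.read_ids,
                    source=source,
                ):
                    key = call.key
                    reads_by_key.setdefault(key, set()).update(call.supporting_reads)
                    prev = merged.get(key)
                    if prev is None or sum(call.mismatches) < sum(prev.mismatches):
                        merged[key] = call
    out = []
    for key in sorted(merged):
        call = merged[key]
        reads = frozenset(reads_by_key[key])
        call.supporting_reads = reads
        call.support = len(reads)
        out.append(call)
    return out


def export_junction_flanks(
    calls: list[JunctionCall],
    bindex: BoundaryIndex,
    flank: int = DEFAULT_FLANK,
) -> list[tuple[str, str]]:
    """(name, sequence) pairs concatenating the last ``flank`` nt of the
    donor exon with the first ``flank`` nt of the acceptor exon, in
    transcript sense.  Flanks longer than an exon are clamped to the
    exon with a warning."""
    import warnings

    by_id = {e.exon_id: e for e in bindex.entries}
    records = []
    for call in calls:
        donor = by_id[call.donor_exon_id]
        acceptor = by_id[call.acceptor_exon_id]
        if flank > len(donor.end_window) or flank > len(acceptor.start_window):
            warnings.warn(
                f"flank {flank} clamped to exon length for junction "
                f"{call.donor_exon_id}-{call.acceptor_exon_id}"
            )
        left = donor.end_window[-flank:]
        right = acceptor.start_window[:flank]
        name = (f"{call.donor_exon_id}|{call.acceptor_exon_id}|"
                f"{call.donor_chrom}:{call.donor_coord}|"
                f"{call.acceptor_chrom}:{call.acceptor_coord}")
        records.append((name, left + right))
    return records


def junction_table(calls: list[JunctionCall]) -> pd.DataFrame:
    """Calls as a tidy table (0-based half-open coordinates)."""
    rows = [{
        "donor_exon": c.donor_exon_id,
        "acceptor_exon": c.acceptor_exon_id,
        "donor_chrom": c.donor_chrom,
        "donor_coord": c.donor_coord,
        "acceptor_chrom": c.acceptor_chrom,
        "acceptor_coord": c.acceptor_coord,
        "donor_strand": c.donor_strand,
        "acceptor_strand": c.acceptor_strand,
        "support": c.support,
        "prefix_mm": c.mismatches[0],
        "suffix_mm": c.mismatches[1],
        "distance": -1 if c.distance is None else c.distance,
        "cross_chrom": c.cross_chrom,
        "self_pair": c.self_pair,
        "source": c.source,
    } for c in calls]
    return pd.DataFrame(rows, columns=[
        "donor_exon", "acceptor_exon", "donor_chrom", "donor_coord",
        "acceptor_chrom", "acceptor_coord", "donor_strand", "acceptor_strand",
        "support", "prefix_mm", "suffix_mm", "distance", "cross_chrom",
        "self_pair", "source",
    ])
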