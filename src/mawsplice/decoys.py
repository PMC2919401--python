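"""Decoy exon models and decoy-based false discovery rate.

A decoy exon swaps the first and second halves of the real exon
sequence (second half first).  Junction matching against decoy
boundary windows, with thresholds identical to the target pass,
estimates how often boundary matches arise by chance; the FDR is the
ratio of distinct decoy calls to distinct target calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .junctions import (
    DEFAULT_BOUNDARY_WINDOW,
    BoundaryEntry,
    BoundaryIndex,
    ExonModel,
    JunctionCall,
    exon_transcript_seq,
)
from .reference import ReferenceSet


@dataclass(frozen=True)
class DecoyExonModel:
    """Half-swapped decoy derived from a real exon.

    ``decoy_seq`` is ``s[L//2:] + s[:L//2]`` of the transcript-sense
    exon sequence ``s`` (for odd lengths the second half is the longer
    one); it is a permutation of the original bases, and re-applying
    the swap restores the original for even lengths.
    """

    origin_exon_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str | None
    decoy_seq: str

    @property
    def exon_id(self) -> str:
        return f"decoy:{self.origin_exon_id}"


def make_decoy_exons(exons: list[ExonModel], ref: ReferenceSet) -> list[DecoyExonModel]:
    """One half-swap decoy per exon; exons shorter than 2 nt are
    skipped with a warning."""
    decoys = []
    for exon in exons:
        if exon.length < 2:
            warnings.warn(f"exon {exon.exon_id} too short for a decoy; skipped")
            continue
        s = exon_transcript_seq(exon, ref)
        half = len(s) // 2
        decoys.append(DecoyExonModel(
            origin_exon_id=exon.exon_id, chrom=exon.chrom, start=exon.start,
            end=exon.end, strand=exon.strand, gene_id=exon.gene_id,
            decoy_seq=s[half:] + s[:half],
        ))
    return decoys


def build_decoy_boundary_index(
    decoys: list[DecoyExonModel],
    window: int = DEFAULT_BOUNDARY_WINDOW,
) -> BoundaryIndex:
    """Boundary windows taken from the decoy sequences themselves (not
    the reference); coordinates carry over from the origin exon so that
    deduplication works identically to the target pass."""
    entries = []
    for d in decoys:
        w = min(window, len(d.decoy_seq))
        donor = d.end if d.strand == "+" else d.start
        acceptor = d.start if d.strand == "+" else d.end
        entries.append(BoundaryEntry(
            exon_id=d.exon_id, chrom=d.chrom, strand=d.strand, gene_id=d.gene_id,
            end_window=d.decoy_seq[-w:], start_window=d.decoy_seq[:w],
            donor_coord=donor, acceptor_coord=acceptor,
            start=d.start, end=d.end, source="decoy",
        ))
    return BoundaryIndex(entries, window)


@dataclass(frozen=True)
class FDRReport:
    n_target_calls: int
    n_decoy_calls: int

    @property
    def fdr(self) -> float | None:
        """Decoy/target ratio; None (undefined, not zero) without targets."""
        if self.n_target_calls == 0:
            return None
        return self.n_decoy_calls / self.n_target_calls

    @property
    def defined(self) -> bool:
        return self.n_target_calls > 0

    def to_dict(self) -> dict:
        return {
            "n_target_calls": self.n_target_calls,
            "n_decoy_calls": self.n_decoy_calls,
            "fdr": self.fdr,
            "defined": self.defined,
        }


def compute_fdr(target_calls: list[JunctionCall],
                decoy_calls: list[JunctionCall]) -> FDRReport:
    """FDR from two call lists produced with identical thresholds.

    Counts are of distinct junctions (the call lists are already
    deduplicated on coordinate pairs by the caller).
    """
    n_target = len({c.key for c in target_calls})
    n_decoy = len({c.key for c in decoy_calls})
    return FDRReport(n_target_calls=n_target, n_decoy_calls=n_decoy)
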