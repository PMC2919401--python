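"""Reference sequence container and DNA string helpers.

A :class:`ReferenceSet` holds the genome (or any set of reference
sequences) against which substring presence, minimal absent words and
read mappability are all evaluated.  Presence can be assessed on the
forward strand only or on both strands (the default, matching how
genomic sequence is normally treated).

Windows containing ``N`` are never considered "present": before any
indexing the sequences are split at runs of ``N`` into clean
``{A,C,G,T}`` segments, so no fingerprint can arise from an assembly
gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

DNA_ALPHABET = "ACGT"
_VALID_REF_CHARS = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD_ONLY = "forward"
BOTH_STRANDS = "both"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_form(word: str) -> str:
    """Lexicographic minimum of a word and its reverse complement."""
    rc = revcomp(word)
    return word if word <= rc else rc


class ReferenceError(ValueError):
    """Raised for malformed reference input."""


@dataclass(frozen=True)
class ReferenceSet:
    """An ordered collection of named reference sequences.

    Parameters
    ----------
    sequences:
        Tuple of ``(name, sequence)`` pairs.  Sequences must be
        non-empty, uppercase ``{A,C,G,T,N}`` strings with unique names.
    strand_mode:
        ``"both"`` (default) treats a word as present if it occurs on
        either strand; ``"forward"`` restricts presence to the literal
        forward text.
    """

    sequences: tuple[tuple[str, str], ...]
    strand_mode: str = BOTH_STRANDS

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ReferenceError("reference set must contain at least one sequence")
        if self.strand_mode not in (FORWARD_ONLY, BOTH_STRANDS):
            raise ReferenceError(f"unknown strand_mode: {self.strand_mode!r}")
        names = [name for name, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ReferenceError("reference sequence names must be unique")
        for name, seq in self.sequences:
            if not seq:
                raise ReferenceError(f"reference sequence {name!r} is empty")
            bad = set(seq) - _VALID_REF_CHARS
            if bad:
                raise ReferenceError(
                    f"reference sequence {name!r} contains invalid characters: "
                    f"{sorted(bad)} (allowed: A,C,G,T,N; input must be uppercase)"
                )

    @classmethod
    def from_dict(cls, seqs: dict[str, str] | Iterable[tuple[str, str]],
                  strand_mode: str = BOTH_STRANDS) -> "ReferenceSet":
        items = seqs.items() if isinstance(seqs, dict) else seqs
        return cls(tuple((n, s.upper()) for n, s in items), strand_mode)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.sequences)

    def get(self, name: str) -> str:
        for n, s in self.sequences:
            if n == name:
                return s
        raise KeyError(name)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def clean_segments(self, include_revcomp: bool | None = None) -> list[str]:
        """N-free segments of the reference text.

        Each sequence is split at runs of ``N``; if ``include_revcomp``
        (default: True when ``strand_mode == "both"``) the reverse
        complement of every segment is appended, so that a word is a
        substring of some segment iff it is present per strand mode.
        """
        if include_revcomp is None:
            include_revcomp = self.strand_mode == BOTH_STRANDS
        segments: list[str] = []
        for _, seq in self.sequences:
            segments.extend(chunk for chunk in seq.split("N") if chunk)
        if include_revcomp:
            segments.extend(revcomp(s) for s in segments[:])
        return segments


def load_fasta(path: str | Path, strand_mode: str = BOTH_STRANDS) -> ReferenceSet:
    """Load a (multi-record) FASTA file into a :class:`ReferenceSet`."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ReferenceError(f"no FASTA records found in {path}")
    return ReferenceSet(tuple(records), strand_mode)
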