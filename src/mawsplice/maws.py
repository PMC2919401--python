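"""Minimal absent words: enumeration and occurrence search.

A word ``w`` (|w| >= 2) is a *minimal absent word* (MAW) of a text if
``w`` itself is absent while both ``w[1:]`` and ``w[:-1]`` are present.
MAWs act as splicing fingerprints: any read that cannot be explained by
the reference contains at least one MAW, and every MAW it contains must
straddle the novel junction.

Enumeration walks k-mer length frontiers with vectorised integer
codes: for each length ``k`` the candidate set is ``a + u`` over all
present ``(k-1)``-mers ``u`` and bases ``a`` (every MAW's suffix is a
present ``(k-1)``-mer, so nothing is missed), checked for absence and
for presence of the length-``(k-1)`` prefix.  This touches only
observed substrings, never all ``4^k`` words.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .index import SubstringIndex
from .reference import BOTH_STRANDS, canonical_form, revcomp

_BASES = "ACGT"
# byte value -> 2-bit code; everything non-ACGT maps to 4 (invalid)
_CODE_LUT = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE_LUT[ord(_b)] = _i


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> int64 array of 2-bit base codes (non-ACGT -> 4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(code: int, length: int) -> str:
    chars = []
    for shift in range(2 * (length - 1), -2, -2):
        chars.append(_BASES[(code >> shift) & 3])
    return "".join(chars)


@dataclass(frozen=True)
class MAWRecord:
    """One minimal absent word with its canonical (strand-free) form."""

    word: str
    canonical: str

    @property
    def length(self) -> int:
        return len(self.word)


@dataclass(frozen=True)
class MAWOccurrence:
    """A catalog MAW found inside a read or consensus sequence."""

    maw: MAWRecord
    read_offset: int

    @property
    def orientation(self) -> str:
        """'+' when the matched substring is the canonical form."""
        return "+" if self.maw.word == self.maw.canonical else "-"

    @property
    def interval(self) -> tuple[int, int]:
        return self.read_offset, self.read_offset + self.maw.length


class MAWCatalog:
    """The set of minimal absent words of a reference, up to a length cap.

    Under both-strands mode the catalog is closed under reverse
    complement (the reverse complement of a MAW is itself a MAW), and
    each word carries the canonical form used as the cluster key.
    """

    def __init__(self, words: set[str], max_length: int, strand_mode: str) -> None:
        self.max_length = max_length
        self.strand_mode = strand_mode
        self.records: frozenset[MAWRecord] = frozenset(
            MAWRecord(word=w, canonical=canonical_form(w)) for w in words
        )

    @property
    def words(self) -> set[str]:
        return {r.word for r in self.records}

    @cached_property
    def _by_length(self) -> dict[int, dict[str, MAWRecord]]:
        out: dict[int, dict[str, MAWRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.length, {})[rec.word] = rec
        return out

    @property
    def lengths(self) -> list[int]:
        return sorted(self._by_length)

    @property
    def min_length(self) -> int | None:
        return min(self._by_length) if self._by_length else None

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def write(self, path, tsv: bool = False) -> None:
        """Plain-text catalog: one word per line, or word<TAB>canonical<TAB>length."""
        with open(path, "w") as fh:
            for rec in sorted(self.records, key=lambda r: (r.length, r.word)):
                if tsv:
                    fh.write(f"{rec.word}\t{rec.canonical}\t{rec.length}\n")
                else:
                    fh.write(rec.word + "\n")

    @classmethod
    def read(cls, path, strand_mode: str = BOTH_STRANDS) -> "MAWCatalog":
        words = set()
        with open(path) as fh:
            for line in fh:
                w = line.split("\t")[0].strip()
                if w:
                    words.add(w)
        max_len = max((len(w) for w in words), default=2)
        return cls(words, max_len, strand_mode)


def _present_codes(seg_vals: list[np.ndarray], k: int,
                   prev: list[np.ndarray] | None) -> list[np.ndarray]:
    """Per-segment rolling k-mer codes, advanced from the (k-1) state."""
    if prev is None:  # k == 1
        return [v.copy() for v in seg_vals]
    out = []
    for vals, p in zip(seg_vals, prev):
        if len(p) <= 1:
            out.append(np.empty(0, dtype=np.int64))
        else:
            out.append((p[:-1] << 2) + vals[k - 1:])
    return out


def enumerate_maws(index: SubstringIndex, max_length: int) -> MAWCatalog:
    """Enumerate all MAWs of length 2..max_length of the indexed text.

    Presence is evaluated per the index's strand mode (the segment list
    already includes reverse complements under both-strands mode).
    """
    if max_length < 2:
        raise ValueError("max_length must be >= 2")
    seg_vals = [encode_seq(s) for s in index.segments]
    words: set[str] = set()
    prev_codes = _present_codes(seg_vals, 1, None)
    p_prev = np.unique(np.concatenate(prev_codes)) if prev_codes else np.empty(0, np.int64)
    for k in range(2, max_length + 1):
        if not len(p_prev):
            break
        # NB: p_k may be empty while MAWs of length k still exist (both
        # flanks full-length segments), so only p_prev gates the loop.
        cur_codes = _present_codes(seg_vals, k, prev_codes)
        nonempty = [c for c in cur_codes if len(c)]
        p_k = (np.unique(np.concatenate(nonempty)) if nonempty
               else np.empty(0, dtype=np.int64))
        # candidates a+u for every present (k-1)-mer u and base a
        shift = 2 * (k - 1)
        cand = (np.arange(4, dtype=np.int64)[:, None] << shift) + p_prev[None, :]
        cand = cand.ravel()
        absent = ~np.isin(cand, p_k)
        prefix_present = np.isin(cand >> 2, p_prev)
        for code in cand[absent & prefix_present]:
            words.add(_decode(int(code), k))
        prev_codes, p_prev = cur_codes, p_k
    return MAWCatalog(words, max_length, index.strand_mode)


def find_maw_occurrences(read: str, catalog: MAWCatalog) -> list[MAWOccurrence]:
    """All occurrences of catalog MAWs inside ``read``.

    Under both-strands mode the catalog already contains both a word
    and its reverse complement, so a read in either orientation is
    matched directly.  Result is sorted by offset, then word length.
    """
    hits: list[MAWOccurrence] = []
    n = len(read)
    for length, table in catalog._by_length.items():
        if length > n:
            continue
        for off in range(n - length + 1):
            rec = table.get(read[off:off + length])
            if rec is not None:
                hits.append(MAWOccurrence(maw=rec, read_offset=off))
    hits.sort(key=lambda o: (o.read_offset, o.maw.length, o.maw.word))
    return hits
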