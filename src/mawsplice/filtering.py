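"""Short-read loading and filtration.

Reads explainable by the reference are discarded: a read is dropped if
it has no MAW occurrence (it is then a substring of the reference, or
carries no usable fingerprint) or if some reference window on either
strand is within a small Hamming distance (default 2 substitutions) of
it.  What survives is the candidate set of junction-spanning reads,
each carrying its MAW occurrence list.

The mismatch search uses pigeonhole seeding: the read is split into
``max_mismatches + 1`` contiguous parts, so any window within the
mismatch budget must contain at least one part exactly; exact part hits
are located with a sorted k-mer index and verified by vectorised
Hamming comparison.  Substitutions only -- indels are not modelled for
25-mers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .index import SubstringIndex
from .maws import MAWCatalog, MAWOccurrence, encode_seq, find_maw_occurrences
from .reference import revcomp


class ReadFormatError(ValueError):
    """Malformed or inconsistent read input."""


@dataclass(frozen=True)
class ShortRead:
    read_id: str
    seq: str


@dataclass
class ReadSet:
    """Reads accepted at load plus load-stage counts."""

    reads: list[ShortRead]
    n_records: int = 0
    n_dropped_n: int = 0

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


@dataclass
class FiltrationReport:
    n_input: int
    n_dropped_n: int
    n_dropped_no_maw: int
    n_dropped_mappable: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (self.n_dropped_n + self.n_dropped_no_maw
                 + self.n_dropped_mappable + self.n_retained)
        if total != self.n_input:
            raise ValueError("filtration counts do not sum to n_input")

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_input == 0:
            return {k: 0.0 for k in
                    ("dropped_n", "dropped_no_maw", "dropped_mappable", "retained")}
        return {
            "dropped_n": self.n_dropped_n / self.n_input,
            "dropped_no_maw": self.n_dropped_no_maw / self.n_input,
            "dropped_mappable": self.n_dropped_mappable / self.n_input,
            "retained": self.n_retained / self.n_input,
        }

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_n": self.n_dropped_n,
            "n_dropped_no_maw": self.n_dropped_no_maw,
            "n_dropped_mappable": self.n_dropped_mappable,
            "n_retained": self.n_retained,
            "fractions": self.fractions,
        }


@dataclass(frozen=True)
class RetainedRead:
    """A read that passed filtration, with its MAW occurrences."""

    read: ShortRead
    occurrences: tuple[MAWOccurrence, ...]


def _detect_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ReadFormatError(f"cannot infer read format from {path}; pass format explicitly")


def load_reads(path: str | Path, format: str | None = None) -> ReadSet:
    """Load fixed-length short reads from FASTQ or FASTA.

    Reads containing ``N`` are dropped here (counted in the read set);
    qualities are ignored.  Heterogeneous read lengths are an error
    naming the offending record.
    """
    fmt = format or _detect_format(path)
    if fmt not in ("fastq", "fasta"):
        raise ReadFormatError(f"unsupported read format: {fmt!r}")
    reads: list[ShortRead] = []
    n_records = 0
    n_dropped_n = 0
    read_len: int | None = None
    for rec in SeqIO.parse(str(path), fmt):
        n_records += 1
        seq = str(rec.seq).upper()
        if read_len is None and "N" not in seq:
            read_len = len(seq)
        if read_len is not None and len(seq) != read_len:
            raise ReadFormatError(
                f"read {rec.id!r} has length {len(seq)}, expected {read_len}"
            )
        if "N" in seq:
            n_dropped_n += 1
            continue
        bad = set(seq) - set("ACGT")
        if bad:
            raise ReadFormatError(f"read {rec.id!r} contains invalid characters {sorted(bad)}")
        reads.append(ShortRead(read_id=rec.id, seq=seq))
    return ReadSet(reads=reads, n_records=n_records, n_dropped_n=n_dropped_n)


# ---------------------------------------------------------------------------
# Hamming mappability via pigeonhole seeds


class _ChromArray:
    """Encoded chromosome with sorted k-mer code indexes per seed length."""

    def __init__(self, seq: str) -> None:
        self.vals = encode_seq(seq)  # N -> 4, mismatches everything
        self._seed_index: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def seed_index(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        cached = self._seed_index.get(k)
        if cached is not None:
            return cached
        vals = self.vals
        n = len(vals)
        if n < k:
            empty = np.empty(0, dtype=np.int64)
            self._seed_index[k] = (empty, empty)
            return self._seed_index[k]
        bad = (vals > 3).astype(np.int64)
        badcum = np.concatenate(([0], np.cumsum(bad)))
        valid = (badcum[k:] - badcum[:-k]) == 0
        # rolling code; invalid windows keep garbage but are masked out
        code = np.zeros(n - k + 1, dtype=np.int64)
        for j in range(k):
            code = (code << 2) | np.where(vals[j:n - k + 1 + j] > 3, 0, vals[j:n - k + 1 + j])
        positions = np.nonzero(valid)[0]
        code = code[positions]
        order = np.argsort(code, kind="stable")
        self._seed_index[k] = (code[order], positions[order])
        return self._seed_index[k]


def _split_parts(length: int, n_parts: int) -> list[tuple[int, int]]:
    """Contiguous (offset, part_length) split, first parts get the remainder."""
    base, rem = divmod(length, n_parts)
    parts = []
    off = 0
    for i in range(n_parts):
        plen = base + (1 if i < rem else 0)
        parts.append((off, plen))
        off += plen
    return parts


def _chrom_arrays(index: SubstringIndex) -> list[_ChromArray]:
    cache = index._mappability_cache
    if "chroms" not in cache:
        cache["chroms"] = [_ChromArray(seq) for _, seq in index.source]
    return cache["chroms"]


def _oriented_queries(index: SubstringIndex, seq: str) -> list[str]:
    if index.strand_mode == "both":
        return [seq, revcomp(seq)]
    return [seq]


def is_mappable_within(read: ShortRead | str, index: SubstringIndex,
                       max_mismatches: int = 2) -> bool:
    """True iff some reference window (per strand mode) is within
    Hamming distance ``max_mismatches`` of the read.

    Substitutions only; windows containing ``N`` count the ``N``
    positions as mismatches.
    """
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    seq = read.seq if isinstance(read, ShortRead) else read
    length = len(seq)
    chroms = _chrom_arrays(index)
    for query in _oriented_queries(index, seq):
        qvals = encode_seq(query)
        parts = _split_parts(length, max_mismatches + 1)
        if any(plen == 0 for _, plen in parts):
            parts = [(0, length)]  # read shorter than the part count
        for chrom in chroms:
            n = len(chrom.vals)
            if n < length:
                continue
            for off, plen in parts:
                codes, positions = chrom.seed_index(plen)
                if not len(codes):
                    continue
                part_code = 0
                for v in qvals[off:off + plen]:
                    part_code = (part_code << 2) | int(v)
                lo = np.searchsorted(codes, part_code, side="left")
                hi = np.searchsorted(codes, part_code, side="right")
                for pos in positions[lo:hi]:
                    start = int(pos) - off
                    if start < 0 or start + length > n:
                        continue
                    mism = int(np.count_nonzero(chrom.vals[start:start + length] != qvals))
                    if mism <= max_mismatches:
                        return True
    return False


def filter_reads(
    reads: ReadSet | list[ShortRead],
    index: SubstringIndex,
    catalog: MAWCatalog,
    max_mismatches: int = 2,
) -> tuple[list[RetainedRead], FiltrationReport]:
    """Keep reads that carry a MAW fingerprint and are not explainable
    by the reference within ``max_mismatches`` substitutions.

    Stage order: the cheap MAW-containment test first, then the Hamming
    mappability search on the survivors.
    """
    if isinstance(reads, ReadSet):
        read_list = reads.reads
        n_dropped_n = reads.n_dropped_n
        n_input = reads.n_records
    else:
        read_list = list(reads)
        n_dropped_n = 0
        n_input = len(read_list)
    retained: list[RetainedRead] = []
    n_no_maw = 0
    n_mappable = 0
    for read in read_list:
        occs = find_maw_occurrences(read.seq, catalog)
        if not occs:
            n_no_maw += 1
            continue
        if is_mappable_within(read, index, max_mismatches):
            n_mappable += 1
            continue
        retained.append(RetainedRead(read=read, occurrences=tuple(occs)))
    report = FiltrationReport(
        n_input=n_input,
        n_dropped_n=n_dropped_n,
        n_dropped_no_maw=n_no_maw,
        n_dropped_mappable=n_mappable,
        n_retained=len(retained),
    )
    return retained, report
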