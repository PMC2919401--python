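"""Independent brute-force oracles used to validate the implementation.

Everything here works by naive scanning or literal predicate
evaluation and deliberately shares no code with the package internals.
"""

from __future__ import annotations

from itertools import product

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def all_substrings(texts: list[str], max_len: int) -> set[str]:
    out: set[str] = set()
    for text in texts:
        n = len(text)
        for i in range(n):
            for k in range(1, min(max_len, n - i) + 1):
                out.add(text[i:i + k])
    return out


def brute_maws(texts: list[str], max_len: int, both_strands: bool) -> set[str]:
    """All minimal absent words by direct candidate testing.

    Candidates are a+u+b over observed substrings u (plus the empty
    word for length 2); a word whose inner part is itself absent cannot
    have present flanks, so nothing is missed.
    """
    if both_strands:
        texts = texts + [rc(t) for t in texts]
    present = all_substrings(texts, max_len)
    maws: set[str] = set()
    inner_words: set[str] = {""} | {u for u in present if len(u) <= max_len - 2}
    for u in inner_words:
        for a, b in product("ACGT", repeat=2):
            w = a + u + b
            if w not in present and w[:-1] in present and w[1:] in present:
                maws.add(w)
    return maws


def sliding_hamming_mappable(seqs: list[str], read: str, max_mm: int,
                             both_strands: bool) -> bool:
    """Exhaustive window scan: is some window within Hamming max_mm?"""
    queries = [read, rc(read)] if both_strands else [read]
    L = len(read)
    for q in queries:
        for seq in seqs:
            for i in range(len(seq) - L + 1):
                window = seq[i:i + L]
                mm = sum(1 for x, y in zip(q, window) if x != y or x == "N" or y == "N")
                if mm <= max_mm:
                    return True
    return False


def brute_candidate_sites(intervals: list[tuple[int, int]]) -> set[int]:
    """Literal splice-site predicate on occurrence intervals: a cut is a
    candidate iff it lies strictly inside an occurrence that overlaps no
    other occurrence, or strictly inside the intersection of some
    overlapping pair."""
    ivals = sorted(set(intervals))

    def overlaps(a, b):
        return max(a[0], b[0]) < min(a[1], b[1])

    cuts: set[int] = set()
    for a in ivals:
        others = [b for b in ivals if b != a]
        if not any(overlaps(a, b) for b in others):
            cuts.update(range(a[0] + 1, a[1]))
        else:
            for b in others:
                if overlaps(a, b):
                    lo, hi = max(a[0], b[0]), min(a[1], b[1])
                    cuts.update(range(lo + 1, hi))
    return cuts


def consensus_by_hand(reads_with_offsets: list[tuple[str, int]]):
    """Column-wise majority and depth of a gap-free stack; ties to the
    alphabetically smallest base.  Offsets are column positions of each
    read's first base in a shared frame."""
    lo = min(off for _, off in reads_with_offsets)
    hi = max(off + len(seq) for seq, off in reads_with_offsets)
    seq_out = []
    depth_out = []
    for col in range(lo, hi):
        votes: dict[str, int] = {}
        for seq, off in reads_with_offsets:
            j = col - off
            if 0 <= j < len(seq):
                votes[seq[j]] = votes.get(seq[j], 0) + 1
        depth = sum(votes.values())
        best = min(sorted(votes), key=lambda b: (-votes[b], b)) if votes else "N"
        seq_out.append(best)
        depth_out.append(depth)
    return "".join(seq_out), depth_out, lo
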