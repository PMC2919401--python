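"""Candidate splice sites on a read or consensus from its MAW occurrences.

A *cut index* ``i`` denotes the boundary between characters ``i-1`` and
``i`` (0-based; equivalently the number of characters left of the cut).
For a read that cannot be explained by the reference, a splice junction
can only sit strictly inside a MAW occurrence that overlaps no other
occurrence, or strictly inside the shared part of overlapping
occurrences.  Occurrence intervals are half-open; touching intervals do
not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .maws import MAWOccurrence

PAIRWISE_UNION = "pairwise-union"
GLOBAL_INTERSECTION = "global-intersection"


@dataclass(frozen=True)
class CandidateSiteSet:
    """Sorted candidate cut indices plus the occurrence-group count.

    ``multi_group`` flags reads whose occurrences fall into more than
    one disjoint group: such a read cannot arise from a single splicing
    event, but it is flagged rather than discarded (cuts from every
    group are still reported).
    """

    cut_indices: tuple[int, ...]
    n_groups: int

    @property
    def multi_group(self) -> bool:
        return self.n_groups > 1

    def __iter__(self):
        return iter(self.cut_indices)

    def __len__(self) -> int:
        return len(self.cut_indices)

    def __contains__(self, cut: int) -> bool:
        return cut in self.cut_indices


def _intervals(occurrences: Iterable[MAWOccurrence]) -> list[tuple[int, int]]:
    return sorted({occ.interval for occ in occurrences})


def _overlap_groups(ivals: Sequence[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Partition sorted half-open intervals into maximal transitively-
    overlapping groups (strict overlap; touching does not chain)."""
    groups: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    cur_end = -1
    for s, e in ivals:
        if cur and s < cur_end:
            cur.append((s, e))
            cur_end = max(cur_end, e)
        else:
            if cur:
                groups.append(cur)
            cur = [(s, e)]
            cur_end = e
    if cur:
        groups.append(cur)
    return groups


def enumerate_candidate_sites(
    seq_length: int,
    occurrences: Iterable[MAWOccurrence],
    overlap_mode: str = PAIRWISE_UNION,
) -> CandidateSiteSet:
    """Candidate cut indices permitted by the occurrence intervals.

    For a singleton group ``[s, e)`` every internal cut ``s+1 .. e-1``
    is a candidate.  For a group of overlapping occurrences, candidates
    are the cuts interior to the intersection of each overlapping pair
    (``overlap_mode="pairwise-union"``, the default) or interior to the
    common intersection of the whole group
    (``overlap_mode="global-intersection"``).
    """
    if seq_length < 2:
        raise ValueError("seq_length must be >= 2")
    ivals = _intervals(occurrences)
    for s, e in ivals:
        if s < 0 or e > seq_length:
            raise ValueError(f"occurrence [{s},{e}) out of bounds for length {seq_length}")
    cuts: set[int] = set()
    groups = _overlap_groups(ivals)
    for group in groups:
        if len(group) == 1:
            s, e = group[0]
            cuts.update(range(s + 1, e))
        elif overlap_mode == PAIRWISE_UNION:
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    a = max(group[i][0], group[j][0])
                    b = min(group[i][1], group[j][1])
                    if a < b:  # the pair actually overlaps
                        cuts.update(range(a + 1, b))
        elif overlap_mode == GLOBAL_INTERSECTION:
            a = max(s for s, _ in group)
            b = min(e for _, e in group)
            if a < b:
                cuts.update(range(a + 1, b))
        else:
            raise ValueError(f"unknown overlap_mode: {overlap_mode!r}")
    return CandidateSiteSet(cut_indices=tuple(sorted(cuts)), n_groups=len(groups))


def group_disjointness(occurrences: Iterable[MAWOccurrence]) -> int:
    """Number of maximal transitively-overlapping occurrence groups.

    A count above 1 means the read cannot correspond to a single
    splicing event; callers may use this as a flag.
    """
    return len(_overlap_groups(_intervals(occurrences)))


def bar_notation(seq: str, sites: CandidateSiteSet) -> str:
    """Render a sequence with '|' bars at candidate cuts (debug aid)."""
    out = []
    for i, ch in enumerate(seq):
        if i in sites.cut_indices:
            out.append("|")
        out.append(ch)
    return "".join(out)
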