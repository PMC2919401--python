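"""Clustering of retained reads by shared MAW fingerprint and
consensus construction.

Reads sharing a canonical MAW are stacked gap-free at the offset of
that MAW (members whose occurrence is the reverse complement of the
canonical form are re-oriented first), a per-column majority base is
taken, and the consensus is restricted to the maximal contiguous run
of columns covered by at least ``min_depth`` reads that contains the
anchor MAW.  Members disagreeing with the consensus in more than
``max_read_mismatch`` positions are pruned and the consensus rebuilt to
a fixed point.  Clusters whose consensus sequences share a long exact
overlap are merged, with depths summed column-wise.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .maws import MAWCatalog, encode_seq, find_maw_occurrences
from .reference import canonical_form, revcomp
from .sites import CandidateSiteSet, enumerate_candidate_sites

_BASES = "ACGT"

DEFAULT_MIN_CLUSTER_SIZE = 5
DEFAULT_MIN_DEPTH = 5
DEFAULT_MAX_READ_MISMATCH = 1
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_ITERATIONS = 10


@dataclass(frozen=True)
class ClusterMember:
    """One read as it sits in a cluster, orientation-normalised so the
    key MAW reads forward at ``anchor_offset``."""

    read_id: str
    seq: str  # oriented sequence
    anchor_offset: int  # position of the key MAW within ``seq``
    orientation: str  # '+' if stored as sequenced, '-' if reverse-complemented


@dataclass
class ReadCluster:
    key: str  # canonical MAW
    members: list[ClusterMember]
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE

    @property
    def size(self) -> int:
        return len({m.read_id for m in self.members})


@dataclass
class ConsensusSequence:
    """Depth-trimmed majority consensus of a read cluster.

    ``member_offsets`` maps each retained member to the column of the
    consensus where the member's first base sits (may extend the member
    beyond either end of the consensus; only overlapping columns are
    compared or counted).
    """

    seq: str
    depth: np.ndarray
    anchor_span: tuple[int, int]
    key: str
    members: list[ClusterMember]
    member_offsets: list[int]
    candidate_cuts: CandidateSiteSet | None = None

    @property
    def support(self) -> int:
        return len({m.read_id for m in self.members})

    @property
    def read_ids(self) -> frozenset[str]:
        return frozenset(m.read_id for m in self.members)


def cluster_by_maw(retained, min_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> list[ReadCluster]:
    """Group retained reads by the canonical form of their MAW occurrences.

    A read with occurrences of k distinct canonical MAWs joins all k
    clusters; only clusters with at least ``min_size`` distinct reads
    are emitted, sorted by key for determinism.
    """
    buckets: dict[str, list[ClusterMember]] = {}
    for rr in retained:
        seen: set[str] = set()
        for occ in rr.occurrences:
            canon = occ.maw.canonical
            if canon in seen:
                continue
            seen.add(canon)
            if occ.maw.word == canon:
                member = ClusterMember(
                    read_id=rr.read.read_id, seq=rr.read.seq,
                    anchor_offset=occ.read_offset, orientation="+",
                )
            else:
                # re-orient so the canonical form reads forward
                flipped = revcomp(rr.read.seq)
                offset = len(rr.read.seq) - (occ.read_offset + occ.maw.length)
                member = ClusterMember(
                    read_id=rr.read.read_id, seq=flipped,
                    anchor_offset=offset, orientation="-",
                )
            buckets.setdefault(canon, []).append(member)
    clusters = [
        ReadCluster(key=key, members=members, min_size=min_size)
        for key, members in sorted(buckets.items())
        if len({m.read_id for m in members}) >= min_size
    ]
    return clusters


def _stack_counts(members: list[ClusterMember], offsets: list[int]
                  ) -> tuple[np.ndarray, int]:
    """Base-count matrix (4 x ncols) of a gap-free stack.

    ``offsets`` give each member's start column in an arbitrary shared
    frame; returns the counts over the occupied column range and the
    frame coordinate of column 0 of the matrix.
    """
    lo = min(offsets)
    hi = max(off + len(m.seq) for m, off in zip(members, offsets))
    counts = np.zeros((4, hi - lo), dtype=np.int32)
    for m, off in zip(members, offsets):
        vals = encode_seq(m.seq)
        cols = np.arange(off - lo, off - lo + len(vals))
        counts[vals, cols] += 1
    return counts, lo


def _majority(counts: np.ndarray) -> tuple[str, np.ndarray]:
    depth = counts.sum(axis=0)
    # ties break to the smallest base index: A < C < G < T
    best = counts.argmax(axis=0)
    seq = "".join(_BASES[b] for b in best)
    return seq, depth


def _qualified_run(depth: np.ndarray, min_depth: int,
                   anchor: tuple[int, int]) -> tuple[int, int] | None:
    """Maximal contiguous run of columns with depth >= min_depth fully
    containing the half-open anchor interval, or None."""
    ok = depth >= min_depth
    n = len(ok)
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if i <= anchor[0] and anchor[1] <= j:
                return i, j
            i = j
        else:
            i += 1
    return None


def _mismatches_in_window(member: ClusterMember, start_col: int,
                          cons_vals: np.ndarray) -> int:
    """Mismatches between the member and consensus over their overlap."""
    mvals = encode_seq(member.seq)
    a = max(0, -start_col)
    b = min(len(mvals), len(cons_vals) - start_col)
    if a >= b:
        return 0
    return int(np.count_nonzero(mvals[a:b] != cons_vals[start_col + a:start_col + b]))


def build_consensus(
    cluster: ReadCluster,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_read_mismatch: int = DEFAULT_MAX_READ_MISMATCH,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    catalog: MAWCatalog | None = None,
) -> ConsensusSequence | None:
    """Majority consensus of a cluster, or None if no qualifying run
    containing the anchor survives (or support drops below min_size).
    """
    members = list(cluster.members)
    key_len = len(cluster.key)
    for _ in range(max_iterations):
        if len({m.read_id for m in members}) < cluster.min_size:
            return None
        # shared frame: column 0 = first base of the anchor MAW
        offsets = [-m.anchor_offset for m in members]
        counts, frame_lo = _stack_counts(members, offsets)
        seq, depth = _majority(counts)
        anchor = (-frame_lo, -frame_lo + key_len)
        run = _qualified_run(depth, min_depth, anchor)
        if run is None:
            return None
        run_lo, run_hi = run
        cons_seq = seq[run_lo:run_hi]
        cons_vals = encode_seq(cons_seq)
        keep: list[ClusterMember] = []
        for m, off in zip(members, offsets):
            start_col = off - frame_lo - run_lo
            if _mismatches_in_window(m, start_col, cons_vals) <= max_read_mismatch:
                keep.append(m)
        if len(keep) == len(members):
            if len({m.read_id for m in keep}) < cluster.min_size:
                return None
            member_offsets = [-m.anchor_offset - frame_lo - run_lo for m in keep]
            cuts = None
            if catalog is not None:
                occs = find_maw_occurrences(cons_seq, catalog)
                cuts = enumerate_candidate_sites(len(cons_seq), occs) \
                    if len(cons_seq) >= 2 else CandidateSiteSet((), 0)
            return ConsensusSequence(
                seq=cons_seq,
                depth=depth[run_lo:run_hi].copy(),
                anchor_span=(anchor[0] - run_lo, anchor[1] - run_lo),
                key=cluster.key,
                members=keep,
                member_offsets=member_offsets,
                candidate_cuts=cuts,
            )
        members = keep
    return None


# ---------------------------------------------------------------------------
# Cluster merging


def _best_exact_overlap(a: str, b: str, min_overlap: int) -> int | None:
    """Shift of ``b`` relative to ``a`` giving the longest exact overlap
    of length >= min_overlap, or None.  Covers suffix-prefix overlap in
    both directions and containment."""
    best_shift = None
    best_len = min_overlap - 1
    for shift in range(-(len(b) - 1), len(a)):
        lo = max(0, shift)
        hi = min(len(a), shift + len(b))
        olen = hi - lo
        if olen <= best_len:
            continue
        if a[lo:hi] == b[lo - shift:hi - shift]:
            best_len = olen
            best_shift = shift
    return best_shift


def _flip_consensus(cons: ConsensusSequence) -> ConsensusSequence:
    n = len(cons.seq)
    key_len = len(cons.key)
    members = [
        ClusterMember(
            read_id=m.read_id, seq=revcomp(m.seq),
            anchor_offset=len(m.seq) - (m.anchor_offset + key_len),
            orientation="-" if m.orientation == "+" else "+",
        )
        for m in cons.members
    ]
    offsets = [n - (off + len(m.seq)) for m, off in zip(cons.members, cons.member_offsets)]
    cuts = cons.candidate_cuts
    if cuts is not None:
        cuts = CandidateSiteSet(tuple(sorted(n - c for c in cuts.cut_indices)), cuts.n_groups)
    return ConsensusSequence(
        seq=revcomp(cons.seq),
        depth=cons.depth[::-1].copy(),
        anchor_span=(n - cons.anchor_span[1], n - cons.anchor_span[0]),
        key=cons.key,
        members=members,
        member_offsets=offsets,
        candidate_cuts=cuts,
    )


def _merge_pair(a: ConsensusSequence, b: ConsensusSequence,
                min_overlap: int, min_depth: int) -> ConsensusSequence | None:
    """Merge ``b`` into ``a`` if their consensi share an exact overlap
    >= min_overlap in either orientation of ``b``."""
    for b_or in (b, _flip_consensus(b)):
        shift = _best_exact_overlap(a.seq, b_or.seq, min_overlap)
        if shift is None:
            continue
        members = a.members + b_or.members
        offsets = a.member_offsets + [off + shift for off in b_or.member_offsets]
        counts, frame_lo = _stack_counts(members, offsets)
        seq, depth = _majority(counts)
        anchor = (a.anchor_span[0] - frame_lo, a.anchor_span[1] - frame_lo)
        run = _qualified_run(depth, min_depth, anchor)
        if run is None:
            continue
        run_lo, run_hi = run
        cuts: set[int] = set()
        n_groups = 0
        for cons, delta in ((a, 0), (b_or, shift)):
            if cons.candidate_cuts is None:
                continue
            n_groups = max(n_groups, cons.candidate_cuts.n_groups)
            for c in cons.candidate_cuts.cut_indices:
                lifted = c + delta - frame_lo - run_lo
                if 0 < lifted < run_hi - run_lo:
                    cuts.add(lifted)
        return ConsensusSequence(
            seq=seq[run_lo:run_hi],
            depth=depth[run_lo:run_hi].copy(),
            anchor_span=(anchor[0] - run_lo, anchor[1] - run_lo),
            key=a.key,
            members=members,
            member_offsets=[off - frame_lo - run_lo for off in offsets],
            candidate_cuts=CandidateSiteSet(tuple(sorted(cuts)), n_groups)
            if (a.candidate_cuts is not None or b_or.candidate_cuts is not None)
            else None,
        )
    return None


def merge_clusters(
    consensi: list[ConsensusSequence],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[ConsensusSequence]:
    """Repeatedly merge consensus pairs sharing an exact overlap of at
    least ``min_overlap`` nt (either orientation, containment included)
    until no pair is mergeable.  Depths are column-wise sums of the
    member stacks; the merged consensus is re-trimmed to ``min_depth``
    and candidate cut sets are unioned with coordinates lifted.
    """
    result: list[ConsensusSequence] = []
    queue = deque(consensi)
    while queue:
        cur = queue.popleft()
        for idx, existing in enumerate(result):
            candidate = _merge_pair(existing, cur, min_overlap, min_depth)
            if candidate is not None:
                # the merged consensus may enable further merges
                del result[idx]
                queue.append(candidate)
                break
        else:
            result.append(cur)
    return result
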