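from __future__ import annotations

import numpy as np
import pytest

from mawsplice import (
    MAWRecord,
    ReferenceSet,
    ShortRead,
    build_consensus,
    build_index,
    canonical_form,
    enumerate_maws,
)
from mawsplice.clustering import ClusterMember, ReadCluster
from mawsplice.maws import MAWOccurrence

_BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ref_forward() -> ReferenceSet:
    return ReferenceSet.from_dict({"chr1": "ACGT"}, strand_mode="forward")


@pytest.fixture
def seeded_ref(rng) -> ReferenceSet:
    return ReferenceSet.from_dict({"chr1": random_dna(rng, 1000)})


def make_occurrences(words_at: list[tuple[str, int]]) -> list[MAWOccurrence]:
    """Occurrence list from (word, offset) pairs without a catalog."""
    return [
        MAWOccurrence(maw=MAWRecord(word=w, canonical=canonical_form(w)), read_offset=off)
        for w, off in words_at
    ]


def make_cluster(key: str, reads_with_offsets: list[tuple[str, str, int]],
                 min_size: int = 5) -> ReadCluster:
    """Cluster from (read_id, oriented seq, anchor offset) triples."""
    members = [
        ClusterMember(read_id=rid, seq=seq, anchor_offset=off, orientation="+")
        for rid, seq, off in reads_with_offsets
    ]
    return ReadCluster(key=key, members=members, min_size=min_size)


def consensus_of_identical(key: str | None, seq: str, n: int, start_id: int = 0,
                           catalog=None, min_depth: int = 5, cuts=None):
    """Consensus built from n identical stacked reads (test helper).

    ``key=None`` anchors on the first two bases; ``cuts`` installs an
    explicit candidate cut set.
    """
    if key is None:
        key = seq[:2]
    anchor = seq.find(key)
    assert anchor >= 0
    cluster = make_cluster(
        key, [(f"m{start_id + i}", seq, anchor) for i in range(n)], min_size=min(n, 5)
    )
    cons = build_consensus(cluster, min_depth=min_depth, catalog=catalog)
    assert cons is not None
    if cuts is not None:
        from mawsplice.sites import CandidateSiteSet
        cons.candidate_cuts = CandidateSiteSet(tuple(sorted(cuts)), 1)
    return cons
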