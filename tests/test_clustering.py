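"""Clustering by canonical MAW, consensus building, and merging."""

import numpy as np
import pytest

from mawsplice import (
    ReferenceSet,
    ShortRead,
    build_consensus,
    build_index,
    cluster_by_maw,
    enumerate_maws,
    filter_reads,
    merge_clusters,
    revcomp,
)
from mawsplice.filtering import RetainedRead
from mawsplice.maws import MAWCatalog, find_maw_occurrences
from conftest import consensus_of_identical, make_cluster
from _oracles import consensus_by_hand


def retained_from(seqs, catalog):
    out = []
    for i, seq in enumerate(seqs):
        occs = find_maw_occurrences(seq, catalog)
        out.append(RetainedRead(read=ShortRead(f"r{i}", seq), occurrences=tuple(occs)))
    return out


@pytest.fixture
def ca_tg_catalog():
    return MAWCatalog({"CA", "TG"}, max_length=4, strand_mode="both")


class TestClusterByMaw:
    def test_six_reads_form_one_cluster(self, ca_tg_catalog):
        reads = ["ACTGA", "CCTGC", "GCTGT", "TCTGA", "ACTGC", "GCTGG"]
        clusters = cluster_by_maw(retained_from(reads, ca_tg_catalog), min_size=5)
        assert len(clusters) == 1
        assert clusters[0].size == 6

    def test_below_threshold_not_emitted(self, ca_tg_catalog):
        reads = ["ACTGA", "CCTGC", "GCTGT", "TCTGA"]
        assert cluster_by_maw(retained_from(reads, ca_tg_catalog), min_size=5) == []

    def test_revcomp_reads_share_canonical_cluster(self, ca_tg_catalog):
        """TG-bearing and CA-bearing reads are the two orientations of
        the same fingerprint and land in one cluster, re-oriented."""
        reads = ["CTTG", "TTGA", "TGAG", "CAAG", "TCAA", "CTCA"]
        clusters = cluster_by_maw(retained_from(reads, ca_tg_catalog), min_size=5)
        assert len(clusters) == 1
        cluster = clusters[0]
        assert cluster.key == "CA"
        assert cluster.size == 6
        for m in cluster.members:
            assert m.seq[m.anchor_offset:m.anchor_offset + 2] == "CA"

    def test_multi_maw_read_joins_all_clusters(self):
        catalog = MAWCatalog({"AAA", "TTT", "CCC", "GGG"}, 3, "forward")
        reads = ["AAACCC"] * 5
        clusters = cluster_by_maw(retained_from(reads, catalog), min_size=5)
        assert sorted(c.key for c in clusters) == ["AAA", "CCC"]


class TestBuildConsensus:
    def test_identical_reads(self):
        cons = consensus_of_identical("CA", "GGCATT", 5)
        assert cons.seq == "GGCATT"
        assert list(cons.depth) == [5] * 6
        assert cons.support == 5
        assert cons.anchor_span == (2, 4)

    def test_staggered_reads_match_hand_stack(self):
        """Six error-free staggered reads: consensus equals the column
        majority restricted to depth-qualified columns."""
        true = "ACGGTTCACGATTGCCAGGTA"  # "CA" anchor at index 6
        offsets = [0, 1, 2, 3, 4, 5]
        reads = [true[o:o + 15] for o in offsets]
        anchor = 6
        cluster = make_cluster("CA", [
            (f"r{i}", seq, anchor - off) for i, (seq, off) in enumerate(zip(reads, offsets))
        ])
        cons = build_consensus(cluster, min_depth=5)
        hand_seq, hand_depth, lo = consensus_by_hand(list(zip(reads, offsets)))
        qualified = [i for i, d in enumerate(hand_depth) if d >= 5]
        expect = hand_seq[qualified[0]:qualified[-1] + 1]
        assert cons.seq == expect
        assert cons.seq == true[4:16]  # columns 4..15 covered by >=5 reads

    def test_discordant_member_pruned(self):
        seq = "GGCATTGGCC"
        bad = "GGCATTGGAA"  # two mismatches at the tail
        cluster = make_cluster("CA", [(f"r{i}", seq, 2) for i in range(5)]
                               + [("rbad", bad, 2)])
        cons = build_consensus(cluster, min_depth=5)
        assert cons.support == 5
        assert "rbad" not in cons.read_ids
        assert cons.seq == seq

    def test_pruning_reaches_fixed_point(self):
        seq = "GGCATTGGCC"
        bad = "GGCATTGGAA"
        cluster = make_cluster("CA", [(f"r{i}", seq, 2) for i in range(6)]
                               + [(f"b{i}", bad, 2) for i in range(2)])
        cons = build_consensus(cluster, min_depth=5)
        from mawsplice.maws import encode_seq
        cv = encode_seq(cons.seq)
        for m, off in zip(cons.members, cons.member_offsets):
            mv = encode_seq(m.seq)
            a, b = max(0, -off), min(len(mv), len(cv) - off)
            assert int(np.count_nonzero(mv[a:b] != cv[off + a:off + b])) <= 1

    def test_support_collapse_returns_none(self):
        seq = "GGCATTGGCC"
        bad = "GGCATTGGAA"
        cluster = make_cluster("CA", [(f"r{i}", seq, 2) for i in range(4)]
                               + [("rbad", bad, 2)])
        assert build_consensus(cluster, min_depth=5) is None

    def test_tie_breaks_to_alphabetical_base(self):
        """Equal votes resolve A < C < G < T deterministically."""
        cluster = make_cluster("CA", [
            ("r1", "GGCAT", 2), ("r2", "GGCAT", 2), ("r3", "GGCAG", 2),
            ("r4", "GGCAG", 2), ("r5", "GGCAC", 2), ("r6", "GGCAC", 2),
        ])
        cons = build_consensus(cluster, min_depth=5, max_read_mismatch=1)
        assert cons.seq[-1] == "C"  # C,G,T tie 2-2-2 -> C


class TestMergeClusters:
    def test_identical_consensi_merge_and_double_depth(self):
        a = consensus_of_identical("CA", "GGCATTGGCCAT", 5, start_id=0)
        b = consensus_of_identical("CA", "GGCATTGGCCAT", 5, start_id=10)
        merged = merge_clusters([a, b], min_overlap=10)
        assert len(merged) == 1
        assert merged[0].seq == "GGCATTGGCCAT"
        assert list(merged[0].depth) == [10] * 12

    def test_fourteen_nt_prefix_overlap_merges(self):
        a = consensus_of_identical("TA", "ACGTACGTACGTAC", 5, start_id=0)
        b = consensus_of_identical("TA", "ACGTACGTACGTACGG", 5, start_id=10)
        merged = merge_clusters([a, b], min_overlap=10)
        assert len(merged) == 1
        assert merged[0].seq == "ACGTACGTACGTACGG"

    def test_short_overlap_not_merged(self):
        a = consensus_of_identical("CA", "GGGGCACGTAC", 5, start_id=0)
        b = consensus_of_identical("CA", "CACGTACTTTTTT", 5, start_id=10)
        # exact suffix-prefix overlap "CACGTAC" has length 7 < 10
        merged = merge_clusters([a, b], min_overlap=10)
        assert len(merged) == 2

    def test_conflicting_overlap_not_merged(self):
        a = consensus_of_identical("CA", "AAAACAAAAAGGGG", 5, start_id=0)
        b = consensus_of_identical("CA", "AAAACAAAAACCCC", 5, start_id=10)
        merged = merge_clusters([a, b], min_overlap=11)
        assert len(merged) == 2

    def test_revcomp_orientation_merges(self):
        a = consensus_of_identical("CA", "GGCATTGGCCATT", 5, start_id=0)
        b = consensus_of_identical("TG", revcomp("GGCATTGGCCATT"), 5, start_id=10)
        merged = merge_clusters([a, b], min_overlap=10)
        assert len(merged) == 1
        assert merged[0].support == 10

    def test_idempotence(self):
        consensi = [
            consensus_of_identical("TA", "ACGTACGTACGTAC", 5, start_id=0),
            consensus_of_identical("TA", "ACGTACGTACGTACGG", 5, start_id=10),
            consensus_of_identical("CA", "TTTTTCATTTTTT", 5, start_id=20),
        ]
        once = merge_clusters(consensi, min_overlap=10)
        twice = merge_clusters(once, min_overlap=10)
        assert [(c.seq, list(c.depth)) for c in once] == \
            [(c.seq, list(c.depth)) for c in twice]


class TestEndToEndClustering:
    def test_error_free_junction_cluster_recovers_truth(self):
        """With error-free spanning reads the consensus equals the true
        junction sequence over depth-qualified columns."""
        rng = np.random.default_rng(5)
        from conftest import random_dna
        genome = random_dna(rng, 4000)
        ref = ReferenceSet.from_dict({"chr1": genome})
        idx = build_index(ref)
        catalog = enumerate_maws(idx, 25)
        junction = genome[1000:1024] + genome[3000:3024]
        reads = [ShortRead(f"j{i}", junction[off:off + 25])
                 for i, off in enumerate(range(4, 20))]
        retained, _ = filter_reads(reads, idx, catalog)
        assert len(retained) >= 5
        clusters = cluster_by_maw(retained, min_size=5)
        assert clusters
        for cluster in clusters:
            cons = build_consensus(cluster, min_depth=5, catalog=catalog)
            if cons is None:
                continue
            assert cons.seq in junction
            assert all(d >= 5 for d in cons.depth)
            assert cons.support >= 5
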