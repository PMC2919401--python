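"""Boundary windows, junction matching, dedup, flank export, readers."""

import numpy as np
import pytest

from mawsplice import (
    ExonModel,
    ReferenceSet,
    build_boundary_index,
    call_junctions,
    export_junction_flanks,
    match_junction,
    read_exons_bed,
    read_exons_gtf,
    revcomp,
)
from mawsplice.junctions import exon_transcript_seq
from conftest import consensus_of_identical, random_dna


@pytest.fixture
def genome(rng):
    return random_dna(rng, 2000)


@pytest.fixture
def ref(genome):
    return ReferenceSet.from_dict({"chr1": genome})


class TestBoundaryIndex:
    def test_plus_strand_window_coordinates(self, ref, genome):
        exon = ExonModel("e1", "chr1", 10, 20, "+")
        bindex = build_boundary_index([exon], ref, window=4)
        entry = bindex.entries[0]
        assert entry.end_window == genome[16:20]
        assert entry.start_window == genome[10:14]
        assert entry.donor_coord == 20
        assert entry.acceptor_coord == 10

    def test_minus_strand_windows_reverse_complemented(self, ref, genome):
        exon = ExonModel("e1", "chr1", 10, 20, "-")
        bindex = build_boundary_index([exon], ref, window=4)
        entry = bindex.entries[0]
        tx = revcomp(genome[10:20])
        assert entry.end_window == tx[-4:] == revcomp(genome[10:14])
        assert entry.start_window == tx[:4] == revcomp(genome[16:20])
        assert entry.donor_coord == 10
        assert entry.acceptor_coord == 20

    def test_short_exon_clamped_to_full_length(self, ref, genome):
        exon = ExonModel("e1", "chr1", 10, 13, "+")
        bindex = build_boundary_index([exon], ref, window=40)
        entry = bindex.entries[0]
        assert entry.end_window == entry.start_window == genome[10:13]

    def test_exon_outside_chromosome_rejected(self, ref):
        with pytest.raises(ValueError, match="beyond"):
            build_boundary_index([ExonModel("e1", "chr1", 1990, 2010, "+")], ref)


def _junction_setup(genome, ref, cut_left=12):
    """Two exons and a consensus spanning their junction."""
    donor = ExonModel("don", "chr1", 100, 180, "+")
    acceptor = ExonModel("acc", "chr1", 1500, 1580, "+")
    bindex = build_boundary_index([donor, acceptor], ref)
    junction = genome[180 - cut_left:180] + genome[1500:1500 + 12]
    return donor, acceptor, bindex, junction


class TestMatchJunction:
    def test_true_junction_exact_match(self, genome, ref):
        donor, acceptor, bindex, junction = _junction_setup(genome, ref)
        calls = match_junction(junction, 12, bindex,
                               support_reads=frozenset({"r1"}))
        keys = {(c.donor_exon_id, c.acceptor_exon_id) for c in calls}
        assert ("don", "acc") in keys
        true = [c for c in calls if c.donor_exon_id == "don"][0]
        assert true.mismatches == (0, 0)
        assert true.donor_coord == 180
        assert true.acceptor_coord == 1500
        assert true.distance == 1500 - 180

    def test_one_mismatch_each_side_tolerated(self, genome, ref):
        donor, acceptor, bindex, junction = _junction_setup(genome, ref)
        mutated = list(junction)
        mutated[3] = "ACGT"[("ACGT".index(mutated[3]) + 1) % 4]
        mutated[20] = "ACGT"[("ACGT".index(mutated[20]) + 1) % 4]
        calls = match_junction("".join(mutated), 12, bindex,
                               support_reads=frozenset({"r1"}))
        true = [c for c in calls if c.donor_exon_id == "don"]
        assert true and true[0].mismatches == (1, 1)

    def test_short_prefix_skipped(self, genome, ref):
        _, _, bindex, junction = _junction_setup(genome, ref)
        assert match_junction(junction[8:], 4, bindex,
                              support_reads=frozenset()) == []

    def test_ambiguous_donor_reported_twice(self, rng):
        """Two exons with identical end windows both appear as donors."""
        core = random_dna(rng, 60)
        genome = random_dna(rng, 200) + core + random_dna(rng, 200) + core \
            + random_dna(rng, 200)
        ref = ReferenceSet.from_dict({"chr1": genome})
        e1 = ExonModel("e1", "chr1", 200, 260, "+")
        e2 = ExonModel("e2", "chr1", 460, 520, "+")
        acc = ExonModel("a", "chr1", 600, 660, "+")
        bindex = build_boundary_index([e1, e2, acc], ref)
        junction = core[-12:] + genome[600:612]
        calls = match_junction(junction, 12, bindex, support_reads=frozenset())
        donors = sorted(c.donor_exon_id for c in calls if c.acceptor_exon_id == "a")
        assert donors == ["e1", "e2"]

    def test_cut_bounds_validated(self, genome, ref):
        _, _, bindex, junction = _junction_setup(genome, ref)
        with pytest.raises(ValueError):
            match_junction(junction, 0, bindex, support_reads=frozenset())


class TestCallJunctions:
    def test_duplicate_coordinates_merged_with_read_union(self, genome, ref):
        donor, acceptor, bindex, junction = _junction_setup(genome, ref)
        a = consensus_of_identical(None, junction, 5, start_id=0, cuts=[12])
        b = consensus_of_identical(None, junction, 5, start_id=3, cuts=[12])
        calls = call_junctions([a, b], bindex)
        true = [c for c in calls if (c.donor_exon_id, c.acceptor_exon_id) == ("don", "acc")]
        assert len(true) == 1
        # ids m3..m7 overlap between the two consensi: union is 8 distinct reads
        assert true[0].support == 8

    def test_reverse_complement_consensus_calls_same_junction(self, genome, ref):
        donor, acceptor, bindex, junction = _junction_setup(genome, ref)
        fwd = consensus_of_identical(None, junction, 5, cuts=[12])
        rev = consensus_of_identical(None, revcomp(junction), 5, cuts=[12])
        keys_fwd = {c.key for c in call_junctions([fwd], bindex)}
        keys_rev = {c.key for c in call_junctions([rev], bindex)}
        assert keys_fwd == keys_rev

    def test_matched_sides_reverify_against_reference(self, genome, ref):
        """Every emitted call re-verifies at <=1 mismatch per side against
        windows sliced directly from the reference."""
        donor, acceptor, bindex, junction = _junction_setup(genome, ref)
        cons = consensus_of_identical(None, junction, 5, cuts=[12])
        calls = call_junctions([cons], bindex)
        assert calls
        by_id = {e.exon_id: e for e in bindex.entries}
        for call in calls:
            d, a = by_id[call.donor_exon_id], by_id[call.acceptor_exon_id]
            cut = call.cut_index
            ok = False
            for oriented in (cons.seq, revcomp(cons.seq)):
                prefix, suffix = oriented[:cut], oriented[cut:]
                p = min(len(prefix), len(d.end_window))
                s = min(len(suffix), len(a.start_window))
                mm_p = sum(x != y for x, y in zip(prefix[-p:], d.end_window[-p:]))
                mm_s = sum(x != y for x, y in zip(suffix[:s], a.start_window[:s]))
                if mm_p <= 1 and mm_s <= 1:
                    ok = True
            assert ok

    def test_empty_consensus_list(self, genome, ref):
        _, _, bindex, _ = _junction_setup(genome, ref)
        assert call_junctions([], bindex) == []


class TestFlankExport:
    def test_flanks_match_direct_reference_slicing(self, genome, ref):
        donor, acceptor, bindex, junction = _junction_setup(genome, ref)
        cons = consensus_of_identical(None, junction, 5, cuts=[12])
        calls = [c for c in call_junctions([cons], bindex)
                 if (c.donor_exon_id, c.acceptor_exon_id) == ("don", "acc")]
        records = export_junction_flanks(calls, bindex, flank=24)
        assert len(records) == 1
        _, seq = records[0]
        assert seq == genome[180 - 24:180] + genome[1500:1500 + 24]
        assert len(seq) == 48

    def test_flank_clamped_on_short_exon_with_warning(self, ref, genome):
        donor = ExonModel("d", "chr1", 100, 115, "+")
        acceptor = ExonModel("a", "chr1", 300, 380, "+")
        bindex = build_boundary_index([donor, acceptor], ref)
        call_list = call_junctions(
            [consensus_of_identical(None, genome[105:115] + genome[300:310], 5,
                                     cuts=[10])], bindex)
        target = [c for c in call_list
                  if (c.donor_exon_id, c.acceptor_exon_id) == ("d", "a")]
        with pytest.warns(UserWarning, match="clamped"):
            records = export_junction_flanks(target, bindex, flank=24)
        assert records[0][1] == genome[100:115] + genome[300:324]

    def test_empty_calls_empty_output(self, genome, ref):
        _, _, bindex, _ = _junction_setup(genome, ref)
        assert export_junction_flanks([], bindex) == []


class TestExonReaders:
    def test_bed6_roundtrip(self, tmp_path):
        p = tmp_path / "exons.bed"
        p.write_text("chr1\t10\t20\texonA\t0\t+\nchr2\t5\t50\texonB\t0\t-\n")
        exons = read_exons_bed(p)
        assert [(e.exon_id, e.chrom, e.start, e.end, e.strand) for e in exons] == [
            ("exonA", "chr1", 10, 20, "+"), ("exonB", "chr2", 5, 50, "-")]

    def test_gtf_exons_with_gene_ids(self, tmp_path):
        p = tmp_path / "exons.gtf"
        p.write_text(
            'chr1\tsim\texon\t11\t20\t.\t+\t.\tgene_id "g1"; exon_id "e1";\n'
            'chr1\tsim\tCDS\t11\t20\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsim\texon\t31\t40\t.\t-\t.\tgene_id "g1"; exon_id "e2";\n')
        exons = read_exons_gtf(p)
        assert [(e.exon_id, e.start, e.end, e.strand, e.gene_id) for e in exons] == [
            ("e1", 10, 20, "+", "g1"), ("e2", 30, 40, "-", "g1")]

    def test_minus_strand_transcript_seq(self, ref, genome):
        exon = ExonModel("e", "chr1", 50, 60, "-")
        assert exon_transcript_seq(exon, ref) == revcomp(genome[50:60])
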