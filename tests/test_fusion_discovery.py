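import numpy as np
import pytest

from splicefuse.fusion_discovery import (
    BreakpointWindow,
    FusionCandidate,
    Side,
    build_fusion_contig,
    detect_fusion_pattern,
    map_segments_to_contigs,
    narrow_by_mate,
    normalize_junction,
    refine_fusion_point,
)
from splicefuse.io_model import Genome, RunConfig, revcomp
from splicefuse.segment_aligner import SegmentAlignment, split_read
from splicefuse.stitching import Block
from tests.conftest import random_genome


def oracle_refine(genome, left, right, middle):
    """Independent exhaustive-split oracle, written directly from strings."""
    m = len(middle)
    lseq, rseq = genome[left.chrom], genome[right.chrom]
    best = None
    for s in range(m + 1):
        if left.strand == "+":
            if left.end + s > len(lseq):
                continue
            ref_l = lseq[left.end : left.end + s]
        else:
            if left.start - s < 0:
                continue
            ref_l = revcomp(lseq[left.start - s : left.start])
        rest = m - s
        if right.strand == "+":
            if right.start - rest < 0:
                continue
            ref_r = rseq[right.start - rest : right.start]
        else:
            if right.end + rest > len(rseq):
                continue
            ref_r = revcomp(rseq[right.end : right.end + rest])
        mm = sum(a != b for a, b in zip(middle[:s], ref_l))
        mm += sum(a != b for a, b in zip(middle[s:], ref_r))
        if best is None or (mm, s) < best:
            best = (mm, s)
    return best


class TestDetectFusionPattern:
    def _hits(self, *placements):
        return [
            [SegmentAlignment(c, p, s, 0, i, ln) for (c, p, s, ln) in group]
            for i, group in enumerate(placements)
        ]

    def test_inter_chromosome_pattern(self, config):
        segments = ["A" * 25, "C" * 25, "G" * 25]
        hits = self._hits([("chrA", 1000, "+", 25)], [],
                          [("chrB", 5000, "+", 25)])
        (pat,) = detect_fusion_pattern(segments, hits, config)
        # middle covers the unmapped segment plus the anchor trim zones
        assert pat.middle == "A" * 2 + "C" * 25 + "G" * 2
        assert pat.left.chrom == "chrA" and pat.right.chrom == "chrB"
        assert pat.left.segment_length == 23  # trimmed by max mismatches

    def test_collinear_no_pattern(self, config):
        segments = ["A" * 25] * 3
        hits = self._hits([("chrA", 1000, "+", 25)],
                          [("chrA", 1025, "+", 25)],
                          [("chrA", 1050, "+", 25)])
        assert detect_fusion_pattern(segments, hits, config) == []

    def test_opposite_strand_inversion_pattern(self, config):
        segments = ["A" * 25, "C" * 25]
        hits = self._hits([("chrA", 1000, "+", 25)],
                          [("chrA", 2000, "-", 25)])
        (pat,) = detect_fusion_pattern(segments, hits, config)
        assert pat.right.strand == "-"

    def test_distant_same_strand_pattern(self, config):
        segments = ["A" * 25, "C" * 25]
        hits = self._hits([("chrA", 1000, "+", 25)],
                          [("chrA", 500_000, "+", 25)])
        assert len(detect_fusion_pattern(segments, hits, config)) == 1

    def test_multimap_bound_respected(self, config):
        segments = ["A" * 25, "C" * 25]
        too_many = [("chrA", p, "+", 25) for p in (0, 100, 200)]  # M+1 hits
        hits = self._hits(too_many, [("chrB", 5000, "+", 25)])
        assert detect_fusion_pattern(segments, hits, config) == []

    def test_cross_product_of_retained_hits(self, config):
        segments = ["A" * 25, "C" * 25]
        hits = self._hits(
            [("chrA", 1000, "+", 25), ("chrA", 3000, "+", 25)],
            [("chrB", 5000, "+", 25), ("chrB", 7000, "+", 25)],
        )
        assert len(detect_fusion_pattern(segments, hits, config)) == 4


class TestRefineFusionPoint:
    def _anchors(self, genome, pos_l, pos_r, m_left):
        """Anchors flanking a junction at chrA:pos_l -> chrB:pos_r."""
        left = SegmentAlignment("chrA", pos_l - 22 - m_left + 1, "+", 0, 0, 23)
        return left

    def test_constructed_identity(self, small_genome):
        g = small_genome
        # middle = 12 bases after the left anchor + 13 bases before the right
        left = SegmentAlignment("chrA", 1000, "+", 0, 0, 25)
        right = SegmentAlignment("chrB", 4000, "+", 0, 2, 25)
        middle = g["chrA"][1025:1037] + g["chrB"][3987:4000]
        cand, split, mm = refine_fusion_point(g, left, right, middle)
        assert (split, mm) == (12, 0)
        assert cand.left == Side("chrA", 1036, "+")
        assert cand.right == Side("chrB", 3987, "+")

    def test_one_substitution_same_split(self, small_genome):
        g = small_genome
        left = SegmentAlignment("chrA", 1000, "+", 0, 0, 25)
        right = SegmentAlignment("chrB", 4000, "+", 0, 2, 25)
        mid = list(g["chrA"][1025:1037] + g["chrB"][3987:4000])
        mid[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mid[5]]
        middle = "".join(mid)
        cand, split, mm = refine_fusion_point(g, left, right, middle)
        oracle = oracle_refine(g, left, right, middle)
        assert (mm, split) == oracle
        assert mm == 1

    def test_tie_break_smallest_split(self):
        # both halves identical: every split has 0 mismatches
        g = Genome({"chrA": "A" * 200, "chrB": "A" * 200})
        left = SegmentAlignment("chrA", 10, "+", 0, 0, 20)
        right = SegmentAlignment("chrB", 100, "+", 0, 2, 20)
        cand, split, mm = refine_fusion_point(g, left, right, "A" * 10)
        assert (split, mm) == (0, 0)
        assert oracle_refine(g, left, right, "A" * 10) == (0, 0)

    def test_oracle_equivalence_random(self, rng):
        genome = random_genome(rng, {"chrA": 5_000, "chrB": 5_000})
        for _ in range(40):
            m = int(rng.integers(0, 61))
            la = SegmentAlignment("chrA", int(rng.integers(100, 4000)),
                                  "+-"[int(rng.integers(0, 2))], 0, 0, 23)
            ra = SegmentAlignment("chrB", int(rng.integers(100, 4000)),
                                  "+-"[int(rng.integers(0, 2))], 0, 2, 23)
            middle = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, m))
            got = refine_fusion_point(genome, la, ra, middle)
            expect = oracle_refine(genome, la, ra, middle)
            if got is None:
                assert expect is None
            else:
                assert (got[2], got[1]) == expect

    def test_empty_middle(self, small_genome):
        left = SegmentAlignment("chrA", 1000, "+", 0, 0, 25)
        right = SegmentAlignment("chrB", 4000, "+", 0, 1, 25)
        cand, split, mm = refine_fusion_point(small_genome, left, right, "")
        assert (split, mm) == (0, 0)
        assert cand.left.pos == 1024 and cand.right.pos == 4000

    def test_minus_strand_breakpoints(self, small_genome):
        g = small_genome
        # left anchor on '-': transcript continues toward lower coordinates
        left = SegmentAlignment("chrA", 2000, "-", 0, 0, 25)
        right = SegmentAlignment("chrB", 4000, "+", 0, 2, 25)
        middle = revcomp(g["chrA"][1990:2000]) + g["chrB"][3995:4000]
        cand, split, mm = refine_fusion_point(g, left, right, middle)
        assert (split, mm) == (10, 0)
        assert cand.left == Side("chrA", 1990, "-")
        assert cand.right == Side("chrB", 3995, "+")


class TestBuildFusionContig:
    def test_default_length_44(self, small_genome, config):
        cand = FusionCandidate(Side("chrA", 5000, "+"), Side("chrB", 3000, "+"))
        contig = build_fusion_contig(small_genome, cand, config.flank_length)
        assert len(contig.sequence) == 44
        assert contig.junction_offset == 22
        assert contig.sequence[:22] == small_genome["chrA"][4979:5001]
        assert contig.sequence[22:] == small_genome["chrB"][3000:3022]

    def test_flank_10_gives_20(self, small_genome):
        cand = FusionCandidate(Side("chrA", 5000, "+"), Side("chrB", 3000, "+"))
        contig = build_fusion_contig(small_genome, cand, 10)
        assert len(contig.sequence) == 20

    def test_inversion_right_half_revcomp(self, small_genome):
        g = small_genome
        cand = FusionCandidate(Side("chrA", 5000, "+"), Side("chrA", 8000, "-"))
        contig = build_fusion_contig(g, cand, 22)
        assert contig.sequence[22:] == revcomp(g["chrA"][7979:8001])
        # re-simulate the fused transcript across the junction
        fused = g["chrA"][4979:5001] + revcomp(g["chrA"][7979:8001])
        assert contig.sequence == fused

    def test_breakpoint_near_end_dropped(self, small_genome):
        cand = FusionCandidate(Side("chrA", 5, "+"), Side("chrB", 3000, "+"))
        assert build_fusion_contig(small_genome, cand, 22) is None


class TestMapSegmentsToContigs:
    @pytest.fixture
    def setup(self, small_genome, config):
        cand = FusionCandidate(Side("chrA", 5000, "+"), Side("chrB", 3000, "+"))
        contig = build_fusion_contig(small_genome, cand, config.flank_length)
        fused = small_genome["chrA"][4951:5001] + small_genome["chrB"][3000:3050]
        return contig, fused, config

    @pytest.mark.parametrize("overlap,retained", [(1, False), (2, False),
                                                  (3, True), (6, True)])
    def test_junction_overlap_boundary(self, setup, overlap, retained):
        contig, fused, config = setup
        # 25-bp segment whose last `overlap` bases cross the junction
        seg = fused[50 + overlap - 25 : 50 + overlap]
        hits = map_segments_to_contigs([contig], [seg], config)[0]
        assert bool(hits) == retained

    def test_segment_in_one_half_rejected(self, setup):
        contig, fused, config = setup
        seg = fused[10:35]  # 15 bases short of the junction
        assert map_segments_to_contigs([contig], [seg], config)[0] == []

    def test_translated_blocks_reproduce_read(self, setup, small_genome):
        contig, fused, config = setup
        seg = fused[40:65]  # 10 left + 15 right
        (hit,) = map_segments_to_contigs([contig], [seg], config)[0]
        assert hit.left_read_len == 10
        block_a, block_b = hit.blocks
        recovered = (small_genome[block_a.chrom][block_a.start : block_a.end]
                     + small_genome[block_b.chrom][block_b.start : block_b.end])
        assert recovered == seg
        assert hit.mismatches == 0

    def test_revcomp_segment_maps_with_mirrored_blocks(self, setup, small_genome):
        contig, fused, config = setup
        seg = revcomp(fused[40:65])
        (hit,) = map_segments_to_contigs([contig], [seg], config)[0]
        # read order now traverses the right side first, on flipped strands
        block_a, block_b = hit.blocks
        assert block_a.chrom == "chrB" and block_a.strand == "-"
        assert block_b.chrom == "chrA" and block_b.strand == "-"
        assert hit.left_read_len == 15
        recovered = revcomp(
            small_genome[block_b.chrom][block_b.start : block_b.end]
            + small_genome[block_a.chrom][block_a.start : block_a.end]
        )
        assert recovered == seg
        # the observed candidate is the canonical form of the same junction
        assert hit.candidate == contig.source.canonical()


class TestNarrowByMate:
    def test_plus_strand_arithmetic(self):
        partner = Block("chrA", 9950, 10_000, "+")
        win = narrow_by_mate(partner, 200, 30)
        assert (win.chrom, win.low, win.high) == ("chrA", 10_170, 10_230)

    def test_sd_zero_single_point(self):
        partner = Block("chrA", 9950, 10_000, "+")
        win = narrow_by_mate(partner, 200, 0)
        assert win.low == win.high == 10_200

    def test_clipped_to_chromosome(self):
        partner = Block("chrA", 9950, 10_000, "+")
        win = narrow_by_mate(partner, 200, 30, chrom_length=10_100)
        assert win.high == 10_099

    def test_minus_strand_mirrored(self):
        partner = Block("chrA", 10_000, 10_050, "-")
        win = narrow_by_mate(partner, 200, 30)
        assert (win.low, win.high) == (9_770, 9_830)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            BreakpointWindow("chrA", 10, 5)


class TestCandidateGeometry:
    def test_kind_classification(self):
        inter = FusionCandidate(Side("chrA", 10, "+"), Side("chrB", 20, "+"))
        inv = FusionCandidate(Side("chrA", 10, "+"), Side("chrA", 500_000, "-"))
        intra = FusionCandidate(Side("chrA", 10, "+"), Side("chrA", 100_010, "+"))
        rt = FusionCandidate(Side("chrA", 10, "+"), Side("chrA", 90_000, "+"))
        assert inter.kind() == "inter"
        assert inv.kind() == "inversion"
        assert intra.kind() == "intra"
        assert rt.kind() == "read_through"

    def test_canonical_is_mirror_invariant(self):
        cand = FusionCandidate(Side("chrB", 100, "+"), Side("chrA", 200, "-"))
        assert cand.canonical() == cand.mirrored().canonical()
        assert cand.mirrored().mirrored() == cand

    def test_normalize_merges_microhomology(self):
        # junction inside a shared 'AC' repeat: 3 equivalent coordinates
        g = Genome({"chrA": "TTTTTTTTTTGGAC" + "TTTTTTTTTT",
                    "chrB": "CCCCCCCCCCACGG" + "CCCCCCCCCC"})
        # fused transcript ...GGAC|GG... == ...GG|ACGG...
        a = FusionCandidate(Side("chrA", 13, "+"), Side("chrB", 12, "+"))
        b = FusionCandidate(Side("chrA", 11, "+"), Side("chrB", 10, "+"))
        assert normalize_junction(g, a) == normalize_junction(g, b)

    def test_normalize_keeps_distinct_junctions(self, small_genome):
        a = FusionCandidate(Side("chrA", 5000, "+"), Side("chrB", 3000, "+"))
        b = FusionCandidate(Side("chrA", 5600, "+"), Side("chrB", 3600, "+"))
        na, nb = (normalize_junction(small_genome, c) for c in (a, b))
        assert na != nb
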