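"""Detect candidate fusions from segment alignment patterns of IUM reads,
refine breakpoints to base-pair precision, build spliced fusion contigs, and
re-map segments against them.

Breakpoint convention: ``left.pos`` is the last transcribed base on the left
side and ``right.pos`` the first on the right side, both 0-based on the
forward strand of their chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Optional

from splicefuse.io_model import Genome, RunConfig, revcomp
from splicefuse.segment_aligner import KmerIndex, SegmentAlignment, align_exactish
from splicefuse.stitching import Block

log = logging.getLogger(__name__)

_FLIP = {"+": "-", "-": "+"}


@dataclass(frozen=True, order=True)
class Side:
    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True, order=True)
class FusionCandidate:
    left: Side
    right: Side

    def mirrored(self) -> "FusionCandidate":
        """The same physical junction read from the opposite transcript strand."""
        return FusionCandidate(
            Side(self.right.chrom, self.right.pos, _FLIP[self.right.strand]),
            Side(self.left.chrom, self.left.pos, _FLIP[self.left.strand]),
        )

    def canonical(self) -> "FusionCandidate":
        """Strand-symmetric representative used for dedup and support counting."""
        return min(self, self.mirrored())

    def kind(self, min_intra_distance: int = 100_000) -> str:
        """inter | inversion | intra | read_through."""
        if self.left.chrom != self.right.chrom:
            return "inter"
        if self.left.strand != self.right.strand:
            return "inversion"
        if abs(self.left.pos - self.right.pos) >= min_intra_distance:
            return "intra"
        return "read_through"


@dataclass
class SplicedFusionContig:
    """``2 * flank_length`` bases reading across the junction in transcript
    orientation; the junction sits at offset ``junction_offset``."""

    sequence: str
    source: FusionCandidate
    junction_offset: int


@dataclass(frozen=True)
class BreakpointWindow:
    chrom: str
    low: int
    high: int

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("window low > high")


@dataclass(frozen=True)
class FusionPattern:
    """Anchor pair flanking an unmapped (or junction-bleeding) stretch."""

    left: SegmentAlignment   # trimmed left anchor
    right: SegmentAlignment  # trimmed right anchor
    middle: str              # read bases between the trimmed anchors


@dataclass(frozen=True)
class ContigHit:
    """A segment hit on a spliced fusion contig, translated back to a pair of
    genomic blocks in read order."""

    segment_index: int
    blocks: tuple[Block, Block]
    candidate: FusionCandidate  # canonical
    mismatches: int
    left_read_len: int  # read bases of this segment before the junction


# ---------------------------------------------------------------------------
# Pattern detection
# ---------------------------------------------------------------------------

def _fusion_like(a: SegmentAlignment, b: SegmentAlignment, config: RunConfig) -> bool:
    if a.chrom != b.chrom:
        return True
    if a.strand != b.strand:
        return True
    # same chromosome, same strand: only far-apart placements qualify; the
    # anchor separation approximates the breakpoint separation to within a
    # read length, so allow that much slack and let classification decide
    slack = 4 * config.segment_length
    if a.strand == "+":
        sep = b.start - a.end
    else:
        sep = a.start - b.end
    return abs(sep) >= config.min_intra_distance - slack


def _trim_left_anchor(hit: SegmentAlignment, t: int) -> SegmentAlignment:
    """Drop the last t read bases of a left anchor (possible junction bleed)."""
    if hit.strand == "+":
        return SegmentAlignment(hit.chrom, hit.start, "+", hit.mismatches,
                                hit.segment_index, hit.segment_length - t)
    return SegmentAlignment(hit.chrom, hit.start + t, "-", hit.mismatches,
                            hit.segment_index, hit.segment_length - t)


def _trim_right_anchor(hit: SegmentAlignment, t: int) -> SegmentAlignment:
    """Drop the first t read bases of a right anchor."""
    if hit.strand == "+":
        return SegmentAlignment(hit.chrom, hit.start + t, "+", hit.mismatches,
                                hit.segment_index, hit.segment_length - t)
    return SegmentAlignment(hit.chrom, hit.start, "-", hit.mismatches,
                            hit.segment_index, hit.segment_length - t)


def detect_fusion_pattern(
    segments: list[str],
    seg_hits: list[list[SegmentAlignment]],
    config: RunConfig,
) -> list[FusionPattern]:
    """Enumerate anchor pairs of an IUM read whose placements look like a
    fusion: different chromosomes, same chromosome at >= min_intra_distance,
    or same chromosome on opposite strands (inversion).

    Anchors are consecutive mapped segments (everything between them
    unmapped); each anchor is trimmed by max_segment_mismatches read bases at
    its junction-facing end, because a segment still maps when only a few of
    its bases cross the fusion point.  Patterns are emitted over the
    cross-product of retained multi-hits.
    """
    bound = config.multimap_bound
    usable = [
        hits if 0 < len(hits) <= bound else []
        for hits in seg_hits
    ]
    mapped = [i for i, hits in enumerate(usable) if hits]
    starts = []
    pos = 0
    for seg in segments:
        starts.append(pos)
        pos += len(seg)
    read = "".join(segments)
    t = config.max_segment_mismatches
    patterns: list[FusionPattern] = []
    for a, b in zip(mapped, mapped[1:]):
        mid_lo = starts[a] + len(segments[a]) - t
        mid_hi = starts[b] + t
        if mid_lo < 0 or mid_hi > len(read) or mid_lo > mid_hi:
            continue
        middle = read[mid_lo:mid_hi]
        for hl, hr in product(usable[a], usable[b]):
            if not _fusion_like(hl, hr, config):
                continue
            patterns.append(
                FusionPattern(_trim_left_anchor(hl, t), _trim_right_anchor(hr, t),
                              middle)
            )
    return patterns


# ---------------------------------------------------------------------------
# Breakpoint refinement
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y or x == "N" for x, y in zip(a, b))


def refine_fusion_point(
    genome: Genome,
    left_anchor: SegmentAlignment,
    right_anchor: SegmentAlignment,
    middle_sequence: str,
) -> Optional[tuple[FusionCandidate, int, int]]:
    """Find the base-pair fusion point by splitting the middle sequence.

    Over all splits ``s = 0..m`` the prefix ``middle[:s]`` is compared with
    the s genome bases continuing past the left anchor (in transcript
    orientation) and the suffix with the ``m - s`` bases preceding the right
    anchor; the split minimising total mismatches wins, ties broken by the
    smallest split index.  Returns None when the flanks run off a chromosome
    end for every split.
    """
    m = len(middle_sequence)
    lseq = genome[left_anchor.chrom]
    rseq = genome[right_anchor.chrom]

    if left_anchor.strand == "+":
        avail_l = min(m, len(lseq) - left_anchor.end)
        cont_l = lseq[left_anchor.end : left_anchor.end + avail_l]
    else:
        avail_l = min(m, left_anchor.start)
        cont_l = revcomp(lseq[left_anchor.start - avail_l : left_anchor.start])
    if right_anchor.strand == "+":
        avail_r = min(m, right_anchor.start)
        cont_r = rseq[right_anchor.start - avail_r : right_anchor.start]
    else:
        avail_r = min(m, len(rseq) - right_anchor.end)
        cont_r = revcomp(rseq[right_anchor.end : right_anchor.end + avail_r])

    best: Optional[tuple[int, int]] = None  # (mismatches, split)
    for s in range(0, m + 1):
        if s > avail_l or (m - s) > avail_r:
            continue
        mm = _hamming(middle_sequence[:s], cont_l[:s])
        suffix_ref = cont_r[avail_r - (m - s) :] if m - s else ""
        mm += _hamming(middle_sequence[s:], suffix_ref)
        if best is None or (mm, s) < best:
            best = (mm, s)
    if best is None:
        return None
    mm, s = best

    if left_anchor.strand == "+":
        pos_l = left_anchor.end + s - 1
    else:
        pos_l = left_anchor.start - s
    if right_anchor.strand == "+":
        pos_r = right_anchor.start - (m - s)
    else:
        pos_r = right_anchor.end + (m - s) - 1
    if not (0 <= pos_l < len(lseq) and 0 <= pos_r < len(rseq)):
        return None
    candidate = FusionCandidate(
        Side(left_anchor.chrom, pos_l, left_anchor.strand),
        Side(right_anchor.chrom, pos_r, right_anchor.strand),
    )
    return candidate, s, mm


def _tx_base(genome: Genome, chrom: str, pos: int, strand: str) -> Optional[str]:
    """Base at forward position `pos` read in transcript orientation."""
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        return None
    base = seq[pos]
    return base if strand == "+" else base.translate(_COMP_TABLE)


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def _shift(candidate: FusionCandidate, delta: int) -> FusionCandidate:
    """Move the junction `delta` bases along the transcript (same strands)."""
    left, right = candidate.left, candidate.right
    dl = delta if left.strand == "+" else -delta
    dr = delta if right.strand == "+" else -delta
    return FusionCandidate(
        Side(left.chrom, left.pos + dl, left.strand),
        Side(right.chrom, right.pos + dr, right.strand),
    )


def _equivalent_shift(genome: Genome, candidate: FusionCandidate,
                      direction: int) -> Optional[FusionCandidate]:
    """The candidate shifted one base along the transcript when that shift
    yields a byte-identical fused sequence (junction microhomology)."""
    left, right = candidate.left, candidate.right
    if direction < 0:
        # the base leaving the left side must equal the base entering the right
        leaving = _tx_base(genome, left.chrom, left.pos, left.strand)
        step = -1 if right.strand == "+" else 1
        entering = _tx_base(genome, right.chrom, right.pos + step, right.strand)
    else:
        step = 1 if left.strand == "+" else -1
        leaving = _tx_base(genome, left.chrom, left.pos + step, left.strand)
        entering = _tx_base(genome, right.chrom, right.pos, right.strand)
    if leaving is None or entering is None or leaving != entering:
        return None
    shifted = _shift(candidate, direction)
    for side in (shifted.left, shifted.right):
        if not 0 <= side.pos < len(genome[side.chrom]):
            return None
    return shifted


def normalize_junction(genome: Genome, candidate: FusionCandidate,
                       max_shift: int = 64) -> FusionCandidate:
    """Unique representative among breakpoint coordinates that spell the same
    fused sequence.

    When the bases flanking a junction repeat across it, several coordinate
    pairs describe an identical fusion transcript; distinct observations then
    refine to different (all correct) coordinates.  All equivalent
    representations are enumerated by sliding the junction through the
    microhomology in both directions, and the lexicographically smallest
    canonical form is returned, so equivalent candidates always merge.
    Genuinely distinct nearby junctions are never merged: equivalence requires
    byte-identical sequence.
    """
    reps = {candidate.canonical()}
    for direction in (-1, 1):
        cur = candidate
        for _ in range(max_shift):
            cur = _equivalent_shift(genome, cur, direction)
            if cur is None:
                break
            reps.add(cur.canonical())
    return min(reps)


# ---------------------------------------------------------------------------
# Spliced fusion contigs
# ---------------------------------------------------------------------------

def build_fusion_contig(
    genome: Genome,
    candidate: FusionCandidate,
    flank_length: int,
) -> Optional[SplicedFusionContig]:
    """Concatenate flank_length bases flanking each breakpoint, in transcript
    orientation, into a 2*flank_length contig; None when a flank runs off a
    chromosome end (candidate dropped with a warning)."""
    left, right = candidate.left, candidate.right
    lseq, rseq = genome[left.chrom], genome[right.chrom]
    if left.strand == "+":
        if left.pos + 1 < flank_length:
            log.warning("dropping candidate %s: left flank off chromosome", candidate)
            return None
        half_l = lseq[left.pos - flank_length + 1 : left.pos + 1]
    else:
        if left.pos + flank_length > len(lseq):
            log.warning("dropping candidate %s: left flank off chromosome", candidate)
            return None
        half_l = revcomp(lseq[left.pos : left.pos + flank_length])
    if right.strand == "+":
        if right.pos + flank_length > len(rseq):
            log.warning("dropping candidate %s: right flank off chromosome", candidate)
            return None
        half_r = rseq[right.pos : right.pos + flank_length]
    else:
        if right.pos + 1 < flank_length:
            log.warning("dropping candidate %s: right flank off chromosome", candidate)
            return None
        half_r = revcomp(rseq[right.pos - flank_length + 1 : right.pos + 1])
    return SplicedFusionContig(half_l + half_r, candidate, flank_length)


def _contig_block(side: Side, offsets: tuple[int, int], is_left: bool,
                  flank: int, flip: bool) -> Block:
    """Genome block for contig-coordinate interval ``offsets`` (half-open)
    within one contig half; ``flip`` mirrors the strand for '-' contig hits."""
    lo, hi = offsets
    if is_left:
        if side.strand == "+":
            gstart, gend = side.pos - (flank - 1) + lo, side.pos - (flank - 1) + hi
            strand = "+"
        else:
            gstart, gend = side.pos + (flank - hi), side.pos + (flank - lo)
            strand = "-"
    else:
        r_lo, r_hi = lo - flank, hi - flank
        if side.strand == "+":
            gstart, gend = side.pos + r_lo, side.pos + r_hi
            strand = "+"
        else:
            gstart, gend = side.pos - r_hi + 1, side.pos - r_lo + 1
            strand = "-"
    if flip:
        strand = _FLIP[strand]
    return Block(side.chrom, gstart, gend, strand)


class ContigIndex:
    """k-mer index over a set of spliced fusion contigs, with junction-overlap
    filtering and translation of hits back to genomic block pairs."""

    def __init__(self, contigs: list[SplicedFusionContig], config: RunConfig):
        self.contigs = contigs
        self.config = config
        from splicefuse.io_model import Genome as _G
        names = [f"__contig{i}" for i in range(len(contigs))]
        self._names = names
        if contigs:
            mini = _G({n: c.sequence for n, c in zip(names, contigs)})
            k = max(4, min(
                config.segment_length // (config.max_segment_mismatches + 1),
                min(len(c.sequence) for c in contigs),
            ))
            self._index = KmerIndex(mini, k)
            self._mini = mini
        else:
            self._index = None
            self._mini = None

    def map_segment(self, seq: str, segment_index: int = 0) -> list[ContigHit]:
        if self._index is None or len(seq) < self._index.k:
            return []
        cfg = self.config
        hits = align_exactish(self._index, self._mini, seq,
                              cfg.max_segment_mismatches, segment_index=segment_index)
        out: list[ContigHit] = []
        for hit in hits:
            ci = int(hit.chrom[len("__contig"):])
            contig = self.contigs[ci]
            J = contig.junction_offset
            s, e = hit.start, hit.end
            if J - s < cfg.min_contig_overlap or e - J < cfg.min_contig_overlap:
                continue
            cand = contig.source
            flank = contig.junction_offset
            left_block = _contig_block(cand.left, (s, J), True, flank,
                                       flip=hit.strand == "-")
            right_block = _contig_block(cand.right, (J, e), False, flank,
                                        flip=hit.strand == "-")
            if hit.strand == "+":
                blocks = (left_block, right_block)
                left_read_len = J - s
            else:
                # read-order traversal is right half first, mirrored
                blocks = (right_block, left_block)
                left_read_len = e - J
            out.append(ContigHit(segment_index, blocks, cand.canonical(),
                                 hit.mismatches, left_read_len))
        return out


def map_segments_to_contigs(
    contigs: list[SplicedFusionContig],
    segments: list[str],
    config: RunConfig,
) -> list[list[ContigHit]]:
    """Map each segment against every contig; a hit is retained only if it
    crosses the junction by at least min_contig_overlap bases on both sides."""
    index = ContigIndex(contigs, config)
    return [index.map_segment(seq, i) for i, seq in enumerate(segments)]


# ---------------------------------------------------------------------------
# Paired-end narrowing
# ---------------------------------------------------------------------------

def narrow_by_mate(
    partner_alignment,
    expected_inner_distance: int,
    inner_distance_sd: int,
    chrom_length: Optional[int] = None,
) -> BreakpointWindow:
    """Window where a mate-implied fusion point may lie: the inner mate
    distance +/- its standard deviation downstream of the mapped partner's
    3'-most coordinate, in fragment orientation."""
    block = partner_alignment.blocks[-1] if hasattr(partner_alignment, "blocks") \
        else partner_alignment
    chrom = block.chrom
    if block.strand == "+":
        anchor = block.end
        low = anchor + expected_inner_distance - inner_distance_sd
        high = anchor + expected_inner_distance + inner_distance_sd
    else:
        anchor = block.start
        low = anchor - expected_inner_distance - inner_distance_sd
        high = anchor - expected_inner_distance + inner_distance_sd
    low = max(0, low)
    if chrom_length is not None:
        high = min(high, chrom_length - 1)
        low = min(low, max(0, chrom_length - 1))
    high = max(high, low)
    return BreakpointWindow(chrom, low, high)
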