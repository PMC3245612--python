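"""The false-positive filter cascade that reduces raw fusion candidates to
supported fusions: anchor, multimap, distance classification, per-dataset
support thresholds, flanking-repeat elimination, annotation requirement and
the 600-bp coverage-window check."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from splicefuse.fusion_discovery import FusionCandidate
from splicefuse.io_model import GeneAnnotation, Genome, RunConfig, revcomp
from splicefuse.stitching import FullAlignment

log = logging.getLogger(__name__)

_FLIP = {"+": "-", "-": "+"}


@dataclass
class FusionSupport:
    spanning_reads: int = 0
    supporting_pairs: int = 0
    contradicting_reads: int = 0
    pair_distance_sum: int = 0  # summed end-to-junction distances (for ranking)
    spanning_distance_sum: int = 0

    def __post_init__(self) -> None:
        if min(self.spanning_reads, self.supporting_pairs,
               self.contradicting_reads) < 0:
            raise ValueError("support counts must be >= 0")


@dataclass(frozen=True)
class SupportPreset:
    """Per-dataset support thresholds.

    ``rule == "conj"``: spanning >= min_spanning AND pairs >= min_pairs AND
    spanning + pairs >= min_sum.  ``rule == "disj"``: (spanning >=
    min_spanning AND pairs >= min_pairs) OR spanning + pairs >= min_sum.
    """

    name: str
    min_spanning: int
    min_pairs: int
    min_sum: int
    rule: str = "conj"


PRESETS: dict[str, SupportPreset] = {
    # two supporting pairs and spanning + pairs >= 5
    "breast": SupportPreset("breast", 0, 2, 5, "conj"),
    # spanning + pairs >= 10
    "vcap": SupportPreset("vcap", 0, 0, 10, "conj"),
    # (three spanning and two pairs) or spanning + pairs >= 10
    "uhr_paired": SupportPreset("uhr_paired", 3, 2, 10, "disj"),
    # two spanning reads
    "uhr_single": SupportPreset("uhr_single", 2, 0, 0, "conj"),
}


def preset_from_config(config: RunConfig) -> SupportPreset:
    if config.support_preset == "custom":
        return SupportPreset("custom", config.min_spanning, config.min_pairs,
                             config.min_sum, "disj")
    try:
        return PRESETS[config.support_preset]
    except KeyError:
        raise ValueError(f"unknown support preset {config.support_preset!r}")


# ---------------------------------------------------------------------------
# Per-read filters
# ---------------------------------------------------------------------------

def anchor_filter(alignment: FullAlignment, config: RunConfig) -> bool:
    """A read mapping across a fusion point must have at least min_anchor
    bases on both sides with no more than max_anchor_mismatches mismatches."""
    if alignment.fusion is None:
        raise ValueError("anchor filter applies to fusion-spanning alignments")
    left, right = alignment.side_read_lengths()
    return (min(left, right) >= config.min_anchor
            and alignment.mismatches <= config.max_anchor_mismatches)


def multimap_filter(hit_count: int, config: RunConfig) -> bool:
    """Keep a read only when it has at most M genomic mappings."""
    return hit_count <= config.multimap_bound


def classify_candidate(candidate: FusionCandidate, config: RunConfig) -> str:
    """inter | intra | rejected; inversions count as intra, same-strand
    same-chromosome pairs closer than min_intra_distance (read-throughs) are
    rejected."""
    kind = candidate.kind(config.min_intra_distance)
    if kind == "inter":
        return "inter"
    if kind in ("intra", "inversion"):
        return "intra"
    return "rejected"


# ---------------------------------------------------------------------------
# Support counting
# ---------------------------------------------------------------------------

def _alignment_side(aln: FullAlignment, candidate: FusionCandidate,
                    config: RunConfig) -> Optional[tuple[str, int]]:
    """Which side of the (canonical) candidate a selected alignment supports.

    Returns ("span", dist), ("left", dist) or ("right", dist), else None.
    In fragment geometry the transcript-left end always reads in the left
    side's transcript orientation and the right end against the right side's,
    so the relative strand is checked alongside position.
    """
    if aln.fusion is not None:
        if aln.fusion.canonical() == candidate:
            left_len, _ = aln.side_read_lengths()
            return "span", left_len
        return None
    maxd = config.max_pair_distance
    chroms = {b.chrom for b in aln.blocks}
    if len(chroms) != 1:
        return None
    chrom = aln.blocks[0].chrom
    strand = aln.blocks[0].strand
    lo = min(b.start for b in aln.blocks)
    hi = max(b.end for b in aln.blocks)
    left, right = candidate.left, candidate.right
    if chrom == left.chrom and strand == left.strand:
        if left.strand == "+" and hi <= left.pos + 1:
            d = left.pos + 1 - hi
            if d <= maxd:
                return "left", d
        if left.strand == "-" and lo >= left.pos:
            d = lo - left.pos
            if d <= maxd:
                return "left", d
    if chrom == right.chrom and strand == _FLIP[right.strand]:
        if right.strand == "+" and lo >= right.pos:
            d = lo - right.pos
            if d <= maxd:
                return "right", d
        if right.strand == "-" and hi <= right.pos + 1:
            d = right.pos + 1 - hi
            if d <= maxd:
                return "right", d
    return None


def _crosses_breakpoint(aln: FullAlignment, side, min_anchor: int) -> bool:
    for block in aln.blocks:
        if block.chrom != side.chrom:
            continue
        if block.start <= side.pos < block.end:
            # bases strictly before and strictly after the breakpoint base
            if (side.pos - block.start >= min_anchor
                    and block.end - 1 - side.pos >= min_anchor):
                return True
    return False


def count_support(
    candidate: FusionCandidate,
    selected_alignments: list[FullAlignment],
    pairs: list[tuple[Optional[FullAlignment], Optional[FullAlignment]]],
    config: RunConfig,
) -> FusionSupport:
    """Count spanning reads, supporting pairs and contradicting reads.

    Spanning reads are selected alignments whose fusion event matches the
    candidate exactly (merge tolerance 0).  Supporting pairs have their two
    ends on the two sides in fusion-implied orientation within
    fragment-length bounds; a spanning read inside a supporting pair
    increments both counts.  Contradicting reads are gap-free selected
    alignments crossing either breakpoint with at least min_anchor bases on
    both sides.
    """
    cand = candidate.canonical()
    spanning = 0
    contradicting = 0
    spanning_dist = 0
    for aln in selected_alignments:
        if aln.fusion is not None:
            if aln.fusion.canonical() == cand:
                spanning += 1
                left_len, _ = aln.side_read_lengths()
                spanning_dist += left_len
        elif aln.is_gap_free:
            if (_crosses_breakpoint(aln, cand.left, config.min_anchor)
                    or _crosses_breakpoint(aln, cand.right, config.min_anchor)):
                contradicting += 1
    supporting_pairs = 0
    pair_dist = 0
    for a1, a2 in pairs:
        if a1 is None or a2 is None:
            continue
        s1 = _alignment_side(a1, cand, config)
        s2 = _alignment_side(a2, cand, config)
        if s1 is None or s2 is None:
            continue
        sides = {s1[0], s2[0]}
        if sides == {"left", "right"} or ("span" in sides and len(sides) >= 1):
            supporting_pairs += 1
            pair_dist += s1[1] + s2[1]
    return FusionSupport(spanning, supporting_pairs, contradicting,
                         pair_dist, spanning_dist)


def support_filter(support: FusionSupport, preset: SupportPreset) -> bool:
    """Per-dataset thresholds on spanning reads and supporting pairs."""
    span, pairs = support.spanning_reads, support.supporting_pairs
    total = span + pairs
    if preset.rule == "conj":
        return (span >= preset.min_spanning and pairs >= preset.min_pairs
                and total >= preset.min_sum)
    if preset.rule == "disj":
        return ((span >= preset.min_spanning and pairs >= preset.min_pairs)
                or total >= preset.min_sum)
    raise ValueError(f"unknown preset rule {preset.rule!r}")


# ---------------------------------------------------------------------------
# Candidate-level filters
# ---------------------------------------------------------------------------

def _kmer_placements(genome: Genome, kmer: str) -> list[tuple[str, int]]:
    """All exact placements of a k-mer or its reverse complement."""
    out: list[tuple[str, int]] = []
    for probe in {kmer, revcomp(kmer)}:
        for name in genome.names:
            seq = genome[name]
            i = seq.find(probe)
            while i != -1:
                out.append((name, i))
                i = seq.find(probe, i + 1)
    return sorted(set(out))


def flanking_kmers(genome: Genome, candidate: FusionCandidate,
                   k: int) -> Optional[tuple[str, str]]:
    """The k-mer ending at the left breakpoint and the k-mer starting at the
    right breakpoint, in transcript orientation; None when a breakpoint is
    closer than k to a chromosome end."""
    left, right = candidate.left, candidate.right
    lseq, rseq = genome[left.chrom], genome[right.chrom]
    if left.strand == "+":
        if left.pos + 1 < k:
            return None
        kl = lseq[left.pos - k + 1 : left.pos + 1]
    else:
        if left.pos + k > len(lseq):
            return None
        kl = revcomp(lseq[left.pos : left.pos + k])
    if right.strand == "+":
        if right.pos + k > len(rseq):
            return None
        kr = rseq[right.pos : right.pos + k]
    else:
        if right.pos + 1 < k:
            return None
        kr = revcomp(rseq[right.pos - k + 1 : right.pos + 1])
    return kl, kr


def repeat_filter(genome: Genome, candidate: FusionCandidate,
                  config: RunConfig) -> bool:
    """Eliminate candidates whose two junction-flanking k-mers (default 23 bp)
    co-occur within repeat_max_distance on one chromosome anywhere in the
    genome: such junctions are most likely repeat artifacts.

    Returns True to keep the candidate, False to eliminate it.
    """
    kmers = flanking_kmers(genome, candidate, config.repeat_kmer)
    if kmers is None:
        log.warning("repeat filter skipped for %s: breakpoint too close to a "
                    "chromosome end", candidate)
        return True
    kl, kr = kmers
    places_l = _kmer_placements(genome, kl)
    places_r = _kmer_placements(genome, kr)
    for chrom_l, pos_l in places_l:
        for chrom_r, pos_r in places_r:
            if chrom_l == chrom_r and abs(pos_l - pos_r) <= config.repeat_max_distance:
                return False
    return True


def annotation_filter(candidate: FusionCandidate,
                      annotation: GeneAnnotation) -> bool:
    """Keep a candidate only when at least one breakpoint falls inside an
    annotated gene."""
    return bool(
        annotation.genes_at(candidate.left.chrom, candidate.left.pos)
        or annotation.genes_at(candidate.right.chrom, candidate.right.pos)
    )


def coverage_window_filter(profile, config: RunConfig) -> bool:
    """Reject candidates whose reads fail to cover the window around the
    fusion: each side's covered fraction must reach min_covered_fraction."""
    import numpy as np

    lfrac = float(np.count_nonzero(profile.ldepth)) / len(profile.ldepth)
    rfrac = float(np.count_nonzero(profile.rdepth)) / len(profile.rdepth)
    return (lfrac >= config.min_covered_fraction
            and rfrac >= config.min_covered_fraction)
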