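"""Stitch per-segment placements into full-read alignments admitting introns,
small indels and at most one fusion; score and select the best alignment per
read."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from splicefuse.io_model import RunConfig


@dataclass(frozen=True)
class Block:
    """One gap-free aligned stretch: 0-based half-open genome interval."""

    chrom: str
    start: int
    end: int
    strand: str  # + | -

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FullAlignment:
    """A stitched whole-read alignment.

    ``blocks`` are in read order; ``events[i]`` connects ``blocks[i]`` and
    ``blocks[i+1]`` and is one of ``("intron", length)``,
    ``("deletion", length)``, ``("insertion", length)`` or
    ``("fusion", FusionCandidate)``.
    """

    read_id: str
    sequence: str
    blocks: list[Block]
    events: list[tuple] = field(default_factory=list)
    mismatches: int = 0
    penalty: int = 0

    def __post_init__(self) -> None:
        if len(self.events) != len(self.blocks) - 1:
            raise ValueError("need exactly one event between consecutive blocks")
        if sum(1 for ev in self.events if ev[0] == "fusion") > 1:
            raise ValueError("at most one fusion event per alignment")

    @property
    def fusion(self):
        """The FusionCandidate spanned by this alignment, or None."""
        for ev in self.events:
            if ev[0] == "fusion":
                return ev[1]
        return None

    @property
    def is_gap_free(self) -> bool:
        return not self.events

    def aligned_read_length(self) -> int:
        """Block lengths plus insertions; equals len(sequence) when valid."""
        return sum(len(b) for b in self.blocks) + sum(
            ev[1] for ev in self.events if ev[0] == "insertion"
        )

    def side_read_lengths(self) -> tuple[int, int]:
        """Read bases on each side of the fusion event (0, 0 if none)."""
        for i, ev in enumerate(self.events):
            if ev[0] == "fusion":
                left = sum(len(b) for b in self.blocks[: i + 1]) + sum(
                    e[1] for e in self.events[:i] if e[0] == "insertion"
                )
                return left, len(self.sequence) - left
        return 0, 0

    def sort_key(self) -> tuple:
        b = self.blocks[0]
        return (b.chrom, b.start, b.strand)


def score_alignment(alignment: FullAlignment, config: Optional[RunConfig] = None) -> int:
    """Penalty of an alignment: introns -2, indels -4, fusions -4 (defaults)."""
    cfg = config or RunConfig()
    penalty = 0
    for ev in alignment.events:
        kind = ev[0]
        if kind == "intron":
            penalty += cfg.penalty_intron
        elif kind in ("insertion", "deletion"):
            penalty += cfg.penalty_indel
        elif kind == "fusion":
            penalty += cfg.penalty_fusion
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return penalty


def select_best(alignments: list[FullAlignment]) -> Optional[FullAlignment]:
    """Pick the best alignment: maximal penalty (least negative), then fewest
    mismatches, then (chrom, start, strand) of the first block."""
    if not alignments:
        return None
    return min(alignments, key=lambda a: (-a.penalty, a.mismatches, a.sort_key()))


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def _connect(prev: Block, nxt: Block, config: RunConfig):
    """All legal ways to join two consecutive read-order blocks.

    Yields (event_or_None, adjusted_next_block); empty if unjoinable.
    """
    if prev.chrom != nxt.chrom or prev.strand != nxt.strand:
        return
    if prev.strand == "+":
        gap = nxt.start - prev.end
    else:
        gap = prev.start - nxt.end
    if gap == 0:
        yield None, nxt
        return
    if 0 < gap <= config.max_intron_length:
        yield ("intron", gap), nxt
        if gap <= config.max_indel:
            yield ("deletion", gap), nxt
        return
    if -config.max_indel <= gap < 0:
        # read bases re-cover reference: trim the overlap off the next block
        # and book it as an insertion (consumes read, not reference)
        if prev.strand == "+":
            if nxt.end <= prev.end:
                return
            yield ("insertion", -gap), Block(nxt.chrom, prev.end, nxt.end, "+")
        else:
            if nxt.start >= prev.start:
                return
            yield ("insertion", -gap), Block(nxt.chrom, nxt.start, prev.start, "-")


def _extend_chain(chain_blocks, chain_events, event, block):
    blocks = list(chain_blocks)
    events = list(chain_events)
    if event is None and blocks:
        last = blocks[-1]
        if last.strand == "+":
            blocks[-1] = Block(last.chrom, last.start, block.end, "+")
        else:
            blocks[-1] = Block(last.chrom, block.start, last.end, "-")
    else:
        if blocks:
            events.append(event)
        blocks.append(block)
    return blocks, events


def stitch_segments(
    read_id: str,
    sequence: str,
    segments: list[str],
    seg_hits: list[list],
    contig_hits: list[list],
    config: RunConfig,
) -> list[FullAlignment]:
    """Chain per-segment genome hits and fusion-contig hits left-to-right into
    alignments covering the entire read.

    ``seg_hits[i]`` are SegmentAlignment placements of segment i (already
    capped by the multimap bound); ``contig_hits[i]`` are translated contig
    hits of segment i, each carrying a two-block genomic placement and a
    fusion candidate.  Chains needing two fusion points are never emitted.
    """
    n = len(segments)
    results: list[FullAlignment] = []

    def placements(i: int):
        for hit in seg_hits[i]:
            blk = Block(hit.chrom, hit.start, hit.start + hit.segment_length,
                        hit.strand)
            yield [(None, blk)], hit.mismatches, False
        for chit in contig_hits[i]:
            blk_a, blk_b = chit.blocks
            yield (
                [(None, blk_a), (("fusion", chit.candidate), blk_b)],
                chit.mismatches,
                True,
            )

    def dfs(i, blocks, events, mismatches, fused):
        if i == n:
            aln = FullAlignment(
                read_id, sequence, blocks, events, mismatches,
            )
            aln.penalty = score_alignment(aln, config)
            results.append(aln)
            return
        for steps, mm, has_fusion in placements(i):
            if has_fusion and fused:
                continue
            if not blocks:
                nb, ne = [], []
                for ev, blk in steps:
                    nb, ne = _extend_chain(nb, ne, ev, blk)
                dfs(i + 1, nb, ne, mismatches + mm, fused or has_fusion)
                continue
            first_blk = steps[0][1]  # steps[0] event is always None
            for conn_ev, adj_blk in _connect(blocks[-1], first_blk, config):
                nb, ne = _extend_chain(blocks, events, conn_ev, adj_blk)
                for ev, blk in steps[1:]:
                    nb, ne = _extend_chain(nb, ne, ev, blk)
                dfs(i + 1, nb, ne, mismatches + mm, fused or has_fusion)

    dfs(0, [], [], 0, False)
    # the read must be fully accounted for
    valid = [a for a in results if a.aligned_read_length() == len(sequence)]
    # deduplicate identical chains arising from different seed paths
    seen: set = set()
    unique: list[FullAlignment] = []
    for aln in sorted(valid, key=lambda a: (-a.penalty, a.mismatches, a.sort_key())):
        key = (tuple(aln.blocks), tuple(
            (ev[0], ev[1]) if ev[0] != "fusion" else ("fusion", ev[1].left, ev[1].right)
            for ev in aln.events
        ))
        if key not in seen:
            seen.add(key)
            unique.append(aln)
    return unique
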