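"""Two-phase pipeline: (1) find candidate fusions via segment-split alignment
and breakpoint refinement; (2) filter false fusions and rank what survives."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from splicefuse import filters as flt
from splicefuse.fusion_discovery import (
    BreakpointWindow,
    ContigIndex,
    FusionCandidate,
    build_fusion_contig,
    detect_fusion_pattern,
    narrow_by_mate,
    normalize_junction,
    refine_fusion_point,
)
from splicefuse.io_model import (
    GeneAnnotation,
    Genome,
    Read,
    ReadPair,
    RunConfig,
    read_bed,
    read_fasta,
    read_fastq,
    write_fusion_sam,
)
from splicefuse.ranking import (
    CoverageProfile,
    FusionReport,
    ScoreComponents,
    components_from_profile,
    fusion_score,
    rank_fusions,
)
from splicefuse.segment_aligner import (
    align_whole_read,
    align_exactish,
    build_index,
    default_index_k,
    split_read,
)
from splicefuse.stitching import FullAlignment, select_best, stitch_segments

log = logging.getLogger(__name__)

_STAGES = (
    "reads_total",
    "reads_gapfree_mapped",
    "reads_multimap_discarded",
    "reads_ium",
    "fusion_patterns",
    "candidates_refined",
    "contigs_built",
    "candidates_classified",
    "candidates_locally_maximal",
    "candidates_supported",
    "candidates_after_repeat",
    "candidates_after_annotation",
    "candidates_after_coverage",
    "fusions_reported",
)


@dataclass
class PipelineResult:
    reports: list[FusionReport]
    stage_counts: dict[str, int]
    selected_alignments: list[FullAlignment]
    candidates: list[FusionCandidate]
    paired: bool = True


def _fragments(reads) -> list[tuple[Read, Optional[Read], Optional[ReadPair]]]:
    frags = []
    for item in reads:
        if isinstance(item, ReadPair):
            frags.append((item.first, item.second, item))
        else:
            frags.append((item, None, None))
    return frags


def _pattern_consistent(pattern, window: BreakpointWindow, slack: int) -> bool:
    for anchor in (pattern.left, pattern.right):
        if anchor.chrom != window.chrom:
            continue
        if anchor.start <= window.high + slack and anchor.end >= window.low - slack:
            return True
    return False


def prune_patterns_by_window(patterns, window: Optional[BreakpointWindow],
                             slack: int):
    """Restrict the pattern search space using a mate-implied breakpoint
    window; falls back to the full set when nothing is consistent, so the
    narrowing can only remove ambiguity, never evidence."""
    if window is None or not patterns:
        return patterns
    consistent = [p for p in patterns if _pattern_consistent(p, window, slack)]
    return consistent or patterns


def _same_junction_axis(a: FusionCandidate, b: FusionCandidate, w: int) -> bool:
    for other in (b, b.mirrored()):
        if (a.left.chrom == other.left.chrom
                and a.left.strand == other.left.strand
                and a.right.chrom == other.right.chrom
                and a.right.strand == other.right.strand
                and abs(a.left.pos - other.left.pos) <= w
                and abs(a.right.pos - other.right.pos) <= w):
            return True
    return False


def _suppress_local_duplicates(candidates, supports, window: int):
    """Keep only the best-supported candidate among those whose junctions lie
    within `window` bases of each other on the same chromosome/strand axis.

    Reads refined through sequencing errors occasionally yield a junction a
    few bases off the true one; such a shifted candidate inherits nearly all
    of the true junction's pair support (pairs cannot resolve positions below
    fragment-length scale) but almost none of its spanning reads.  A single
    fused locus admits one junction, so competing explanations this close are
    mutually exclusive and only the locally best one is retained.
    """
    ranked = sorted(
        candidates,
        key=lambda c: (
            -supports[c].spanning_reads,
            -supports[c].supporting_pairs,
            c.left, c.right,
        ),
    )
    taken: list[FusionCandidate] = []
    for cand in ranked:
        if any(_same_junction_axis(cand, kept, window) for kept in taken):
            continue
        taken.append(cand)
    return sorted(taken)


def _depth_window(block_index, chrom: str, lo: int, hi: int) -> np.ndarray:
    """Per-base depth over [lo, hi) from the selected alignments' blocks."""
    depth = np.zeros(hi - lo, dtype=np.int64)
    entry = block_index.get(chrom)
    if entry is None:
        return depth
    starts, ends = entry
    mask = (starts < hi) & (ends > lo)
    for s, e in zip(starts[mask], ends[mask]):
        depth[max(s, lo) - lo : min(e, hi) - lo] += 1
    return depth


def coverage_profile(candidate: FusionCandidate, block_index, genome: Genome,
                     window_half: int) -> CoverageProfile:
    """Depth over the two windows flanking the junction (600 bp total with the
    default window_half of 300), clipped to chromosome bounds with zero
    padding outside."""
    cand = candidate
    wh = window_half

    def side_window(side, is_left: bool) -> np.ndarray:
        outward = (side.strand == "+") == is_left
        if outward:
            lo, hi = side.pos - wh + 1, side.pos + 1
        else:
            lo, hi = side.pos, side.pos + wh
        clip_lo = max(0, lo)
        clip_hi = min(genome.length(side.chrom), hi)
        depth = np.zeros(wh, dtype=np.int64)
        if clip_hi > clip_lo:
            depth[clip_lo - lo : clip_hi - lo] = _depth_window(
                block_index, side.chrom, clip_lo, clip_hi
            )
        return depth

    return CoverageProfile(side_window(cand.left, True),
                           side_window(cand.right, False))


def discover(
    genome: Genome,
    annotation: GeneAnnotation,
    reads,
    config: RunConfig,
) -> PipelineResult:
    """Run the full pipeline on loaded inputs; deterministic."""
    config.validate()
    counts = {name: 0 for name in _STAGES}
    frags = _fragments(reads)
    paired = any(f[2] is not None for f in frags)
    index = build_index(genome, default_index_k(config))

    # --- phase 1a: whole-read gap-free alignment; IUM determination --------
    selected: dict[tuple[str, str], FullAlignment] = {}
    ium: list[tuple[Read, Optional[ReadPair]]] = []
    for first, second, pair in frags:
        for read in (first, second):
            if read is None:
                continue
            counts["reads_total"] += 1
            if len(read.sequence) < index.k:
                continue
            hits = align_whole_read(index, genome, read,
                                    config.max_segment_mismatches,
                                    max_hits=config.multimap_bound)
            if not hits:
                ium.append((read, pair))
                counts["reads_ium"] += 1
            elif flt.multimap_filter(len(hits), config):
                best = min(hits, key=lambda a: (a.mismatches, a.sort_key()))
                selected[(read.id, read.mate_role)] = best
                counts["reads_gapfree_mapped"] += 1
            else:
                counts["reads_multimap_discarded"] += 1

    # --- phase 1b: segment alignment, pattern detection, refinement --------
    seg_cache: dict[tuple[str, str], tuple[list[str], list[list]]] = {}
    candidates: dict[FusionCandidate, int] = {}
    for read, pair in ium:
        segments = split_read(read.sequence, config.segment_length)
        seg_hits = [
            align_exactish(index, genome, seg, config.max_segment_mismatches,
                           max_hits=config.multimap_bound, segment_index=i)
            if len(seg) >= index.k else []
            for i, seg in enumerate(segments)
        ]
        seg_cache[(read.id, read.mate_role)] = (segments, seg_hits)
        patterns = detect_fusion_pattern(segments, seg_hits, config)
        if not patterns:
            continue
        window = None
        if pair is not None:
            partner_role = "second" if read.mate_role == "first" else "first"
            partner = selected.get((read.id, partner_role))
            if partner is not None and partner.is_gap_free:
                window = narrow_by_mate(
                    partner,
                    pair.expected_inner_distance or config.inner_distance,
                    pair.inner_distance_sd or config.inner_distance_sd,
                    genome.length(partner.blocks[0].chrom),
                )
        slack = 2 * len(read.sequence) + 2 * config.inner_distance_sd
        patterns = prune_patterns_by_window(patterns, window, slack)
        counts["fusion_patterns"] += len(patterns)
        for pattern in patterns:
            refined = refine_fusion_point(genome, pattern.left, pattern.right,
                                          pattern.middle)
            if refined is None:
                continue
            cand = normalize_junction(genome, refined[0])
            candidates[cand] = candidates.get(cand, 0) + 1
    counts["candidates_refined"] = len(candidates)

    # --- phase 1c: spliced fusion contigs and re-mapping --------------------
    ordered = sorted(candidates)
    contigs = []
    for cand in ordered:
        contig = build_fusion_contig(genome, cand, config.flank_length)
        if contig is not None:
            contigs.append(contig)
    counts["contigs_built"] = len(contigs)
    contig_index = ContigIndex(contigs, config)

    # --- phase 1d: stitching and per-read selection -------------------------
    for read, pair in ium:
        segments, seg_hits = seg_cache[(read.id, read.mate_role)]
        usable = [
            hits if 0 < len(hits) <= config.multimap_bound else []
            for hits in seg_hits
        ]
        contig_hits = [
            contig_index.map_segment(seg, i) for i, seg in enumerate(segments)
        ]
        if not any(usable) and not any(contig_hits):
            continue
        alignments = stitch_segments(read.id, read.sequence, segments,
                                     usable, contig_hits, config)
        best = select_best(alignments)
        if best is None:
            continue
        best_key = (best.penalty, best.mismatches)
        ties = sum(1 for a in alignments
                   if (a.penalty, a.mismatches) == best_key)
        if not flt.multimap_filter(ties, config):
            counts["reads_multimap_discarded"] += 1
            continue
        if best.fusion is not None and not flt.anchor_filter(best, config):
            continue
        selected[(read.id, read.mate_role)] = best

    selected_list = [
        selected[key] for key in sorted(selected, key=lambda k: (k[0], k[1]))
    ]
    pairs_list = []
    if paired:
        for first, second, pair in frags:
            if pair is None:
                continue
            pairs_list.append((
                selected.get((first.id, "first")),
                selected.get((second.id, "second")),
            ))

    # --- phase 2: filter cascade and ranking --------------------------------
    block_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for aln in selected_list:
        for block in aln.blocks:
            tmp.setdefault(block.chrom, []).append((block.start, block.end))
    for chrom, pairs_se in tmp.items():
        arr = np.array(pairs_se, dtype=np.int64)
        block_index[chrom] = (arr[:, 0], arr[:, 1])

    preset = flt.preset_from_config(config)
    reports: list[FusionReport] = []
    classified = [
        cand for cand in ordered
        if flt.classify_candidate(cand, config) != "rejected"
    ]
    n_classified = len(classified)
    supports = {
        cand: flt.count_support(cand, selected_list, pairs_list, config)
        for cand in classified
    }
    survivors = _suppress_local_duplicates(classified, supports,
                                           2 * config.segment_length)
    n_suppressed = len(survivors)
    n_supported = n_repeat = n_annot = n_cov = 0
    for cand in survivors:
        support = supports[cand]
        if not flt.support_filter(support, preset):
            continue
        n_supported += 1
        if not flt.repeat_filter(genome, cand, config):
            continue
        n_repeat += 1
        if not flt.annotation_filter(cand, annotation):
            continue
        n_annot += 1
        profile = coverage_profile(cand, block_index, genome, config.window_half)
        if not flt.coverage_window_filter(profile, config):
            continue
        n_cov += 1
        components = components_from_profile(profile, support,
                                             max_avg=config.max_avg,
                                             paired=paired)
        report = FusionReport(
            candidate=cand,
            kind=cand.kind(config.min_intra_distance),
            support=support,
            profile=profile,
            components=components,
            score=fusion_score(components),
            genes_left=tuple(annotation.genes_at(cand.left.chrom, cand.left.pos)),
            genes_right=tuple(annotation.genes_at(cand.right.chrom,
                                                  cand.right.pos)),
        )
        reports.append(report)
    counts["candidates_classified"] = n_classified
    counts["candidates_locally_maximal"] = n_suppressed
    counts["candidates_supported"] = n_supported
    counts["candidates_after_repeat"] = n_repeat
    counts["candidates_after_annotation"] = n_annot
    counts["candidates_after_coverage"] = n_cov
    ranked = rank_fusions(reports)
    counts["fusions_reported"] = len(ranked)
    return PipelineResult(ranked, counts, selected_list, ordered, paired)


# ---------------------------------------------------------------------------
# Report writers / readers
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "gene_left", "gene_right", "chrom_left", "pos_left", "strand_left",
    "chrom_right", "pos_right", "strand_right", "kind",
    "spanning_reads", "supporting_pairs", "contradicting_reads",
    "lcount", "rcount", "lavg", "ravg", "lgap", "rgap", "lder", "rder",
    "rate", "dist", "score",
)


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report_tsv(reports: list[FusionReport], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in reports:
            c, s, comp = r.candidate, r.support, r.components
            row = [
                ",".join(r.genes_left) or ".",
                ",".join(r.genes_right) or ".",
                c.left.chrom, c.left.pos, c.left.strand,
                c.right.chrom, c.right.pos, c.right.strand,
                r.kind,
                s.spanning_reads, s.supporting_pairs, s.contradicting_reads,
                comp.lcount, comp.rcount, comp.lavg, comp.ravg,
                comp.lgap, comp.rgap, comp.lder, comp.rder,
                comp.rate, comp.dist, r.score,
            ]
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_report_tsv(path: Union[str, Path]) -> list[FusionReport]:
    from splicefuse.fusion_discovery import Side
    from splicefuse.filters import FusionSupport

    reports = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_TSV_COLUMNS):
            raise ValueError(f"{path}: unexpected candidate TSV header")
        for line in fh:
            f = dict(zip(_TSV_COLUMNS, line.rstrip("\n").split("\t")))
            cand = FusionCandidate(
                Side(f["chrom_left"], int(f["pos_left"]), f["strand_left"]),
                Side(f["chrom_right"], int(f["pos_right"]), f["strand_right"]),
            )
            support = FusionSupport(int(f["spanning_reads"]),
                                    int(f["supporting_pairs"]),
                                    int(f["contradicting_reads"]))
            comp = ScoreComponents(
                int(f["lcount"]), int(f["rcount"]),
                float(f["lavg"]), float(f["ravg"]),
                int(f["lgap"]), int(f["rgap"]),
                float(f["lder"]), float(f["rder"]),
                rate=float(f["rate"]), dist=int(f["dist"]),
            )
            reports.append(FusionReport(
                candidate=cand, kind=f["kind"], support=support,
                components=comp, score=float(f["score"]),
                genes_left=tuple(g for g in f["gene_left"].split(",") if g != "."),
                genes_right=tuple(g for g in f["gene_right"].split(",") if g != "."),
            ))
    return reports


def write_stage_counts(counts: dict[str, int], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        for name in _STAGES:
            fh.write(f"{name}\t{counts[name]}\n")


def run_discover(
    genome_path: Union[str, Path],
    reads_paths: Union[str, Path, tuple],
    annotation_path: Union[str, Path],
    config: RunConfig,
    outdir: Union[str, Path],
) -> PipelineResult:
    """Load inputs, run discovery, and write the SAM dialect, candidate TSV,
    ranked TSV and stage-count log into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_path)
    annotation = read_bed(annotation_path)
    for chrom, _s, _e, name, _ in annotation.intervals:
        if chrom not in genome:
            raise ValueError(
                f"{annotation_path}: interval {name} references unknown "
                f"chromosome {chrom!r}"
            )
    if isinstance(reads_paths, (str, Path)):
        reads_paths = (reads_paths,)
    if len(reads_paths) == 2 and reads_paths[1] is not None:
        reads = list(read_fastq(reads_paths[0], reads_paths[1],
                                config.inner_distance,
                                config.inner_distance_sd))
    else:
        reads = list(read_fastq(reads_paths[0]))
    result = discover(genome, annotation, reads, config)
    unranked = sorted(
        result.reports,
        key=lambda r: (r.candidate.left, r.candidate.right),
    )
    write_report_tsv(unranked, outdir / "candidates.tsv")
    # ranked.tsv is derived from candidates.tsv through the same path the
    # `rank` subcommand uses, so re-ranking round-trips byte-identically
    rerank(outdir / "candidates.tsv", outdir / "ranked.tsv")
    write_fusion_sam(result.selected_alignments, outdir / "alignments.sam",
                     genome)
    write_stage_counts(result.stage_counts, outdir / "stage_counts.tsv")
    return result


def rerank(candidates_tsv: Union[str, Path], out_tsv: Union[str, Path]) -> None:
    """Re-rank an existing candidate TSV by recomputing scores from its
    stored components."""
    reports = read_report_tsv(candidates_tsv)
    for r in reports:
        r.score = fusion_score(r.components)
    write_report_tsv(rank_fusions(reports), out_tsv)
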