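"""Deterministic generator of toy genomes, annotations, planted fusion events
and reads with known truth.

Layout is a pure function of the SimulationSpec (no RNG), so genome
construction and transcript construction agree without sharing state; only
background sequence and read sampling are random, each driven by a child seed
of ``spec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from splicefuse.fusion_discovery import FusionCandidate, Side
from splicefuse.io_model import (
    GeneAnnotation,
    Genome,
    Read,
    ReadPair,
    revcomp,
    write_bed,
    write_fasta,
    write_fastq,
)

_EVENT_KINDS = ("inter", "intra", "inversion", "read_through", "repeat_artifact")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class LayoutError(ValueError):
    """Infeasible simulation layout (overlapping or out-of-bounds events)."""


@dataclass
class SimulationSpec:
    seed: int = 1
    n_chromosomes: int = 3
    chrom_length: int = 700_000
    planted_events: list[str] = field(default_factory=list)
    n_background_genes: int = 12
    n_multi_exon: int = 2
    gene_length: int = 800
    intron_length: int = 500
    repeat_blocks: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    # planted separations (must respect the 100 kb classification rule)
    min_intra_sep: int = 150_000
    read_through_sep: int = 60_000
    repeat_copy_len: int = 60
    read_length: int = 50
    fragment_length_mean: int = 300
    fragment_length_sd: int = 20
    coverage_depth: int = 30
    error_rate: float = 0.0
    paired: bool = True

    def validate(self) -> "SimulationSpec":
        for kind in self.planted_events:
            if kind not in _EVENT_KINDS:
                raise LayoutError(f"unknown planted event kind {kind!r}")
        if self.min_intra_sep < 100_000:
            raise LayoutError(
                "intra events must be planted with separation >= 100,000 bp"
            )
        if self.read_through_sep >= 100_000:
            raise LayoutError(
                "read-through events must be planted with separation < 100,000 bp"
            )
        if self.paired and self.fragment_length_mean < 2 * self.read_length:
            raise LayoutError(
                "fragment_length_mean must be >= 2 * read_length in paired mode"
            )
        if self.gene_length < 2 * self.read_length:
            raise LayoutError("gene_length must be >= 2 * read_length")
        if self.repeat_copy_len < 23:
            raise LayoutError("repeat_copy_len must cover at least one 23-mer")
        return self


@dataclass
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    def transcript(self, genome: Genome) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def transcript_to_genome(self, t: int) -> int:
        """Forward-strand coordinate of transcript position t (single exon)."""
        if len(self.exons) != 1:
            raise ValueError("event genes must be single-exon")
        s, e = self.exons[0]
        return s + t if self.strand == "+" else e - 1 - t


@dataclass
class TruthEvent:
    kind: str
    candidate: FusionCandidate
    left_gene: str
    right_gene: str
    reportable: bool
    transcript_name: str = ""


@dataclass
class TruthSet:
    events: list[TruthEvent] = field(default_factory=list)
    read_origins: dict[str, tuple] = field(default_factory=dict)

    def reportable_candidates(self) -> set[FusionCandidate]:
        return {ev.candidate.canonical() for ev in self.events if ev.reportable}


@dataclass
class Layout:
    genes: list[GeneModel]
    events: list[TruthEvent]
    repeat_copies: list[tuple[str, int, str, int, int]]
    # (src_chrom, src_start, dst_chrom, dst_start, length)


# ---------------------------------------------------------------------------
# Deterministic layout
# ---------------------------------------------------------------------------

_MARGIN = 5_000
_GENE_GAP = 2_000


def layout_from_spec(spec: SimulationSpec) -> Layout:
    spec.validate()
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    cursors = {c: _MARGIN for c in chrom_names}
    genes: list[GeneModel] = []
    events: list[TruthEvent] = []
    repeat_copies: list[tuple[str, int, str, int, int]] = []
    counter = 0

    def place(chrom: str, strand: str, start: Optional[int] = None,
              exons: int = 1) -> GeneModel:
        nonlocal counter
        if start is None:
            start = cursors[chrom]
        glen = spec.gene_length + (spec.intron_length if exons == 2 else 0)
        end = start + glen
        if end > spec.chrom_length - _MARGIN:
            raise LayoutError(
                f"gene does not fit on {chrom} at {start} (layout infeasible)"
            )
        for g in genes:
            if g.chrom == chrom and start < g.end and g.start < end:
                raise LayoutError(
                    f"gene at {chrom}:{start} overlaps {g.name} (layout infeasible)"
                )
        counter += 1
        if exons == 2:
            half = spec.gene_length // 2
            exon_list = [
                (start, start + half),
                (start + half + spec.intron_length, end),
            ]
        else:
            exon_list = [(start, end)]
        gene = GeneModel(f"GENE{counter:03d}", chrom, start, end, strand, exon_list)
        genes.append(gene)
        cursors[chrom] = max(cursors[chrom], end + _GENE_GAP)
        return gene

    def breakpoints(left: GeneModel, right: GeneModel) -> tuple[Side, Side]:
        cut = spec.gene_length // 2
        pos_l = left.transcript_to_genome(cut - 1)
        pos_r = right.transcript_to_genome(cut)
        return (Side(left.chrom, pos_l, left.strand),
                Side(right.chrom, pos_r, right.strand))

    chrom_cycle = 0

    def next_chrom(exclude: Optional[str] = None) -> str:
        nonlocal chrom_cycle
        for _ in range(len(chrom_names)):
            name = chrom_names[chrom_cycle % len(chrom_names)]
            chrom_cycle += 1
            if name != exclude:
                return name
        raise LayoutError("need at least two chromosomes for inter events")

    for i, kind in enumerate(spec.planted_events):
        if kind == "inter":
            c1 = next_chrom()
            c2 = next_chrom(exclude=c1)
            a = place(c1, "+")
            b = place(c2, "+")
            reportable = True
        elif kind == "intra":
            c1 = next_chrom()
            a = place(c1, "+")
            b = place(c1, "+", start=max(cursors[c1], a.start + spec.min_intra_sep))
            reportable = True
        elif kind == "inversion":
            c1 = next_chrom()
            a = place(c1, "+")
            b = place(c1, "-", start=max(cursors[c1], a.start + spec.min_intra_sep))
            reportable = True
        elif kind == "read_through":
            c1 = next_chrom()
            a = place(c1, "+")
            b = place(c1, "+", start=a.start + spec.read_through_sep)
            reportable = False
        elif kind == "repeat_artifact":
            c1 = next_chrom()
            c2 = next_chrom(exclude=c1)
            a = place(c1, "+")
            b = place(c2, "+")
            reportable = False
        else:  # pragma: no cover - validated earlier
            raise LayoutError(kind)
        left, right = breakpoints(a, b)
        cand = FusionCandidate(left, right)
        if kind == "intra" and abs(left.pos - right.pos) < 100_000:
            raise LayoutError(
                f"event {i} labelled intra but separation "
                f"{abs(left.pos - right.pos)} < 100,000"
            )
        if kind == "read_through" and abs(left.pos - right.pos) >= 100_000:
            raise LayoutError(f"event {i} labelled read_through but separation "
                              f"{abs(left.pos - right.pos)} >= 100,000")
        if kind == "repeat_artifact":
            # copy the right-side junction flank to within repeat range of the
            # left breakpoint, creating the repeat the filter must catch; pad
            # upstream so the copy still covers the junction k-mer after any
            # microhomology shift of the refined breakpoint
            pad = 25
            dst = a.end + 500
            length = spec.repeat_copy_len + pad
            if dst + length > spec.chrom_length - _MARGIN:
                raise LayoutError("repeat copy does not fit (layout infeasible)")
            repeat_copies.append(
                (right.chrom, right.pos - pad, a.chrom, dst, length)
            )
            cursors[a.chrom] = max(cursors[a.chrom], dst + length + _GENE_GAP)
        events.append(TruthEvent(kind, cand, a.name, b.name, reportable,
                                 transcript_name=f"fusion{i:03d}_{kind}"))

    for j in range(spec.n_background_genes):
        chrom = next_chrom()
        strand = "-" if j % 3 == 2 else "+"
        place(chrom, strand, exons=2 if j < spec.n_multi_exon else 1)

    return Layout(genes, events, repeat_copies)


# ---------------------------------------------------------------------------
# Genome / transcripts / reads
# ---------------------------------------------------------------------------

def make_genome(spec: SimulationSpec) -> tuple[Genome, GeneAnnotation]:
    """Seeded i.i.d. A/C/G/T background with planted repeat copies; identical
    output for identical specs."""
    layout = layout_from_spec(spec)
    rng = np.random.default_rng([spec.seed, 0])
    chroms: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for i in range(spec.n_chromosomes):
        arr = _BASES[rng.integers(0, 4, spec.chrom_length)]
        arrays[f"chr{i + 1}"] = arr
    for src_chrom, src_start, dst_chrom, dst_start, length in layout.repeat_copies:
        arrays[dst_chrom][dst_start : dst_start + length] = \
            arrays[src_chrom][src_start : src_start + length]
    for chrom, start, length, copies, spacing in spec.repeat_blocks:
        src = arrays[chrom][start : start + length].copy()
        for c in range(1, copies):
            dst = start + c * spacing
            if dst + length > spec.chrom_length:
                raise LayoutError(f"repeat block copy {c} exceeds {chrom}")
            arrays[chrom][dst : dst + length] = src
    for name, arr in arrays.items():
        chroms[name] = arr.tobytes().decode("ascii")
    genome = Genome(chroms)
    annotation = GeneAnnotation(
        [(g.chrom, g.start, g.end, g.name, g.strand) for g in layout.genes]
    )
    return genome, annotation


def make_fused_transcripts(
    spec: SimulationSpec, genome: Genome
) -> tuple[list[tuple[str, str]], TruthSet]:
    """One transcript per planted event: left-gene prefix through the
    breakpoint joined to the right-gene suffix (reverse-complemented sides for
    '-' strand genes); truth breakpoints recorded in genome coordinates."""
    layout = layout_from_spec(spec)
    by_name = {g.name: g for g in layout.genes}
    cut = spec.gene_length // 2
    transcripts: list[tuple[str, str]] = []
    truth = TruthSet(events=list(layout.events))
    for ev in layout.events:
        left_tx = by_name[ev.left_gene].transcript(genome)
        right_tx = by_name[ev.right_gene].transcript(genome)
        transcripts.append((ev.transcript_name, left_tx[:cut] + right_tx[cut:]))
    return transcripts, truth


def make_background_transcripts(
    spec: SimulationSpec, genome: Genome
) -> list[tuple[str, str]]:
    """The unfused transcript of every gene (both fusion partners and
    background genes), so contradicting reads and the annotation filter are
    exercised."""
    layout = layout_from_spec(spec)
    return [(g.name, g.transcript(genome)) for g in layout.genes]


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < error_rate)[0]
    if hits.size == 0:
        return seq
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    picks = rng.integers(0, 3, hits.size)
    for idx, pick in zip(hits, picks):
        arr[idx] = lut.get(int(arr[idx]), [ord("A"), ord("C"), ord("G")])[int(pick)]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    spec: SimulationSpec,
    transcripts: list[tuple[str, str]],
) -> tuple[list, TruthSet]:
    """Sample error-bearing fragments from transcripts at the configured
    coverage depth; paired mode emits both ends with inner distance equal to
    fragment length minus twice the read length.  Deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    rl = spec.read_length
    inner = spec.fragment_length_mean - 2 * rl
    out: list = []
    truth = TruthSet()
    counter = 0
    for name, seq in transcripts:
        tx_len = len(seq)
        if tx_len < rl:
            continue
        denom = 2 * rl if spec.paired else rl
        n_frags = max(1, round(spec.coverage_depth * tx_len / denom))
        lens = rng.normal(spec.fragment_length_mean, spec.fragment_length_sd,
                          n_frags)
        min_len = 2 * rl if spec.paired else rl
        lens = np.clip(np.rint(lens).astype(int), min_len, tx_len)
        starts = np.array([
            int(rng.integers(0, tx_len - ln + 1)) for ln in lens
        ])
        flips = rng.random(n_frags) < 0.5
        for ln, start, flip in zip(lens, starts, flips):
            frag = seq[start : start + ln]
            if flip:
                frag = revcomp(frag)
            counter += 1
            rid = f"sf{counter:07d}"
            if spec.paired:
                r1 = _apply_errors(frag[:rl], rng, spec.error_rate)
                r2 = _apply_errors(revcomp(frag[-rl:]), rng, spec.error_rate)
                out.append(ReadPair(
                    Read(rid, r1, "first"), Read(rid, r2, "second"),
                    max(0, inner), spec.fragment_length_sd,
                ))
            else:
                r1 = _apply_errors(frag[:rl], rng, spec.error_rate)
                out.append(Read(rid, r1, "none"))
            truth.read_origins[rid] = (name, int(start), int(ln), bool(flip))
    return out, truth


# ---------------------------------------------------------------------------
# File-set entry point
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tchrom_left\tpos_left\tstrand_left\t"
                 "chrom_right\tpos_right\tstrand_right\treportable\n")
        for ev in truth.events:
            c = ev.candidate
            fh.write(
                f"{ev.kind}\t{c.left.chrom}\t{c.left.pos}\t{c.left.strand}\t"
                f"{c.right.chrom}\t{c.right.pos}\t{c.right.strand}\t"
                f"{int(ev.reportable)}\n"
            )


def write_simulation(spec: SimulationSpec, outdir: Union[str, Path]) -> dict:
    """Generate and write genome.fa, annotation.bed, reads (FASTQ), and
    truth.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = make_genome(spec)
    fused, truth = make_fused_transcripts(spec, genome)
    background = make_background_transcripts(spec, genome)
    reads, read_truth = simulate_reads(spec, fused + background)
    truth.read_origins = read_truth.read_origins
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.bed",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_bed(annotation, paths["annotation"])
    write_truth(truth, paths["truth"])
    if spec.paired:
        paths["reads_1"] = outdir / "reads_1.fq"
        paths["reads_2"] = outdir / "reads_2.fq"
        write_fastq([p.first for p in reads], paths["reads_1"])
        write_fastq([p.second for p in reads], paths["reads_2"])
    else:
        paths["reads"] = outdir / "reads.fq"
        write_fastq(reads, paths["reads"])
    return {k: str(v) for k, v in paths.items()}
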