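"""Readers/writers for the standard formats the pipeline touches, the run
configuration, and the modified-SAM output dialect.

Coordinates are 0-based half-open everywhere inside the package; the single
conversion to 1-based happens when SAM records are emitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import yaml
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InputError(ValueError):
    """Malformed or inconsistent input file."""


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Named chromosome sequences, uppercase A/C/G/T/N, insertion-ordered."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise InputError(f"chromosome {name!r} has empty sequence")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def subseq(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]


@dataclass
class Read:
    id: str
    sequence: str
    mate_role: str = "none"  # none | first | second


@dataclass
class ReadPair:
    first: Read
    second: Read
    expected_inner_distance: int = 0
    inner_distance_sd: int = 0

    def __post_init__(self) -> None:
        if self.expected_inner_distance < 0:
            raise InputError("expected_inner_distance must be >= 0")


@dataclass
class GeneAnnotation:
    """Gene intervals: (chrom, start, end, name, strand), 0-based half-open."""

    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
        for chrom, start, end, name, strand in self.intervals:
            if start >= end:
                raise InputError(f"interval {name} has start >= end")
            self._by_chrom.setdefault(chrom, []).append((start, end, name, strand))

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        """Names of intervals containing 0-based position `pos`."""
        return [
            name
            for start, end, name, _strand in self._by_chrom.get(chrom, [])
            if start <= pos < end
        ]

    def __len__(self) -> int:
        return len(self.intervals)


_PRESETS = ("breast", "vcap", "uhr_paired", "uhr_single", "custom")


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with published defaults."""

    segment_length: int = 25
    max_segment_mismatches: int = 2
    multimap_bound: int = 2  # M
    min_anchor: int = 13
    max_anchor_mismatches: int = 2
    min_intra_distance: int = 100_000
    flank_length: int = 22
    min_contig_overlap: int = 3
    repeat_kmer: int = 23
    repeat_max_distance: int = 100_000
    window_half: int = 300
    max_intron_length: int = 50_000
    max_indel: int = 3
    min_covered_fraction: float = 0.5
    support_preset: str = "breast"
    # custom support preset knobs: (min_spanning AND min_pairs) OR min_sum
    min_spanning: int = 0
    min_pairs: int = 0
    min_sum: int = 0
    penalty_intron: int = -2
    penalty_indel: int = -4
    penalty_fusion: int = -4
    max_pair_distance: int = 1000
    inner_distance: int = 200
    inner_distance_sd: int = 30
    max_avg: int = 300

    @property
    def contig_length(self) -> int:
        return 2 * self.flank_length

    def validate(self) -> "RunConfig":
        if self.segment_length < 1:
            raise ConfigError("segment_length must be >= 1")
        if not (0 <= self.max_segment_mismatches <= 3):
            raise ConfigError("max_segment_mismatches must be in 0..3")
        if self.min_contig_overlap >= self.segment_length:
            raise ConfigError("min_contig_overlap must be < segment_length")
        if self.window_half <= 0:
            raise ConfigError("window_half must be > 0")
        if self.flank_length < self.min_contig_overlap:
            raise ConfigError("flank_length must be >= min_contig_overlap")
        if self.max_intron_length >= self.min_intra_distance:
            raise ConfigError(
                "max_intron_length must be < min_intra_distance, otherwise "
                "intra-chromosomal fusions are indistinguishable from introns"
            )
        if self.multimap_bound < 1:
            raise ConfigError("multimap_bound must be >= 1")
        if self.support_preset not in _PRESETS:
            raise ConfigError(
                f"unknown support preset {self.support_preset!r}; "
                f"expected one of {_PRESETS}"
            )
        if not (0.0 <= self.min_covered_fraction <= 1.0):
            raise ConfigError("min_covered_fraction must be in [0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None, **overrides) -> "RunConfig":
        """Load config from a flat-key YAML file; kwargs override file values."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: expected a mapping of config keys")
            values.update(loaded)
        values.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values).validate()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a FASTA file into a Genome (uppercased, U mapped to T)."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise InputError(f"{path}: duplicate record name {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise InputError(f"{path}: record {rec.id!r} has empty sequence")
        chroms[rec.id] = seq
    if not chroms:
        raise InputError(f"{path}: no FASTA records found")
    return Genome(chroms)


def _id_stem(read_id: str) -> str:
    stem = read_id.split()[0]
    if len(stem) > 2 and stem[-2] == "/" and stem[-1] in "12":
        stem = stem[:-2]
    return stem


def read_fastq(
    path: Union[str, Path],
    paired_path: Union[str, Path, None] = None,
    expected_inner_distance: int = 0,
    inner_distance_sd: int = 0,
) -> Iterator[Union[Read, ReadPair]]:
    """Stream reads from FASTQ; with `paired_path`, yield position-paired mates."""
    first = SeqIO.parse(str(path), "fastq")
    if paired_path is None:
        for rec in first:
            yield Read(rec.id, str(rec.seq).upper(), "none")
        return
    second = SeqIO.parse(str(paired_path), "fastq")
    sentinel = object()
    while True:
        r1 = next(first, sentinel)
        r2 = next(second, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise InputError(
                f"{path} and {paired_path} contain unequal numbers of records"
            )
        if _id_stem(r1.id) != _id_stem(r2.id):
            raise InputError(
                f"mate id mismatch: {r1.id!r} vs {r2.id!r}"
            )
        yield ReadPair(
            Read(r1.id, str(r1.seq).upper(), "first"),
            Read(r2.id, str(r2.seq).upper(), "second"),
            expected_inner_distance,
            inner_distance_sd,
        )


def read_bed(path: Union[str, Path]) -> GeneAnnotation:
    """Read a BED4+ file of gene intervals (0-based half-open, verbatim)."""
    intervals: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InputError(
                    f"{path}:{lineno}: BED line has {len(fields)} columns; "
                    "at least 4 required (gene name is mandatory)"
                )
            chrom, name = fields[0], fields[3]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise InputError(f"{path}:{lineno}: start >= end")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append((chrom, start, end, name, strand))
    return GeneAnnotation(intervals)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(genome: Genome, path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _cigar_for_side(blocks, events, lead_clip: int, tail_clip: int) -> str:
    """CIGAR for one fusion side (or a whole non-fusion alignment).

    `blocks`/`events` are already in genome (left-to-right) order.
    """
    ops: list[str] = []
    if lead_clip:
        ops.append(f"{lead_clip}S")
    ops.append(f"{blocks[0].end - blocks[0].start}M")
    for ev, blk in zip(events, blocks[1:]):
        kind, val = ev[0], ev[1]
        if kind == "intron":
            ops.append(f"{val}N")
        elif kind == "deletion":
            ops.append(f"{val}D")
        elif kind == "insertion":
            ops.append(f"{val}I")
        else:  # pragma: no cover - guarded by caller
            raise ValueError(f"unexpected event {kind!r} inside one side")
        ops.append(f"{blk.end - blk.start}M")
    if tail_clip:
        ops.append(f"{tail_clip}S")
    # merge adjacent M runs produced by insertion bookkeeping
    merged: list[str] = []
    for op in ops:
        if merged and op[-1] == "M" and merged[-1][-1] == "M":
            merged[-1] = f"{int(merged[-1][:-1]) + int(op[:-1])}M"
        else:
            merged.append(op)
    return "".join(merged)


def _emit_side(fh, qname, seq, blocks, events, read_u, read_v, mismatches, tags):
    """Write one SAM record covering read interval [read_u, read_v)."""
    strand = blocks[0].strand
    rlen = len(seq)
    if strand == "+":
        gblocks, gevents = blocks, events
        lead, tail = read_u, rlen - read_v
        out_seq = seq
        flag = 0
    else:
        gblocks, gevents = list(reversed(blocks)), list(reversed(events))
        lead, tail = rlen - read_v, read_u
        out_seq = revcomp(seq)
        flag = 16
    pos = min(b.start for b in gblocks) + 1  # 1-based SAM position
    cigar = _cigar_for_side(gblocks, gevents, lead, tail)
    cols = [
        qname, str(flag), gblocks[0].chrom, str(pos), "255", cigar,
        "*", "0", "0", out_seq, "*", f"NM:i:{mismatches}",
    ] + tags
    fh.write("\t".join(cols) + "\n")


def write_fusion_sam(alignments, path: Union[str, Path], genome: Genome) -> None:
    """Write selected full-read alignments in the modified-SAM dialect.

    Non-fusion alignments are single records.  A fusion-spanning read is
    emitted as two records sharing QNAME, one per side, each carrying
    ``XF:Z:<chromL>:<posL>:<strandL>|<chromR>:<posR>:<strandR>`` and
    ``XP:i:<read bases on this side>``; the other side's bases are soft
    clipped so each record's CIGAR consumes the whole read.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in genome.names:
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.length(name)}\n")
        fh.write("@PG\tID:splicefuse\tPN:splicefuse\n")
        for aln in alignments:
            fusion_idx = [
                i for i, ev in enumerate(aln.events) if ev[0] == "fusion"
            ]
            if len(fusion_idx) > 1:
                raise ValueError(
                    f"alignment for {aln.read_id} has {len(fusion_idx)} fusion "
                    "events; at most one is representable"
                )
            if not fusion_idx:
                _emit_side(
                    fh, aln.read_id, aln.sequence, aln.blocks, aln.events,
                    0, len(aln.sequence), aln.mismatches, [],
                )
                continue
            fi = fusion_idx[0]
            cand = aln.events[fi][1]
            xf = (
                f"XF:Z:{cand.left.chrom}:{cand.left.pos}:{cand.left.strand}|"
                f"{cand.right.chrom}:{cand.right.pos}:{cand.right.strand}"
            )
            left_blocks, right_blocks = aln.blocks[: fi + 1], aln.blocks[fi + 1 :]
            left_events, right_events = aln.events[:fi], aln.events[fi + 1 :]
            # read bases consumed by each side (insertions consume read bases)
            left_read = sum(b.end - b.start for b in left_blocks) + sum(
                ev[1] for ev in left_events if ev[0] == "insertion"
            )
            total_read = len(aln.sequence)
            _emit_side(
                fh, aln.read_id, aln.sequence, left_blocks, left_events,
                0, left_read, aln.mismatches, [xf, f"XP:i:{left_read}"],
            )
            _emit_side(
                fh, aln.read_id, aln.sequence, right_blocks, right_events,
                left_read, total_read, aln.mismatches,
                [xf, f"XP:i:{total_read - left_read}"],
            )


def write_fastq(reads, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_bed(annotation: GeneAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in annotation.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand or '.'}\n")
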