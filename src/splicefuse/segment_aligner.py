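"""Split reads into segments and align segments/whole reads to the genome with
bounded mismatches.

A forward-strand k-mer index with pigeonhole seed-and-extend replaces an
external short-read aligner: completeness with ``m`` mismatches is guaranteed
whenever ``(m + 1) * k <= len(query)``, because at least one of ``m + 1``
disjoint seeds must then be error-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from splicefuse.io_model import Genome, Read, revcomp
from splicefuse.stitching import Block, FullAlignment

_N = ord("N")
_POS_BITS = 40
_POS_MASK = (1 << _POS_BITS) - 1


@dataclass(frozen=True)
class SegmentAlignment:
    """Placement of one read segment on the genome forward coordinates.

    ``strand == "-"`` means the reverse complement of the segment matches the
    forward strand at ``[start, start + segment_length)``.
    """

    chrom: str
    start: int
    strand: str
    mismatches: int
    segment_index: int = 0
    segment_length: int = 0

    @property
    def end(self) -> int:
        return self.start + self.segment_length


def split_read(sequence: str, segment_length: int) -> list[str]:
    """Split a read into fixed-size pieces; the final piece absorbs the
    remainder, so it is ``segment_length <= L < 2 * segment_length`` long.

    Reads shorter than ``segment_length`` come back as a single piece.
    """
    if not sequence:
        raise ValueError("cannot split an empty sequence")
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    n = len(sequence) // segment_length
    if n <= 1:
        return [sequence]
    pieces = [
        sequence[i * segment_length : (i + 1) * segment_length]
        for i in range(n - 1)
    ]
    pieces.append(sequence[(n - 1) * segment_length :])
    return pieces


class KmerIndex:
    """Exhaustive forward-strand k-mer index over every chromosome.

    k-mers containing N are not indexed; positions are packed as
    ``chrom_ordinal << 40 | position``.
    """

    def __init__(self, genome: Genome, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        shortest = min(genome.length(name) for name in genome.names)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds the shortest chromosome length ({shortest})"
            )
        self.k = k
        self.genome = genome
        self.chrom_names = genome.names
        self.encoded: dict[str, np.ndarray] = {
            name: np.frombuffer(genome[name].encode("ascii"), dtype=np.uint8)
            for name in self.chrom_names
        }
        self._map: dict[str, list[int]] = {}
        for ci, name in enumerate(self.chrom_names):
            seq = genome[name]
            base = ci << _POS_BITS
            has_n = "N" in seq
            table = self._map
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if has_n and "N" in kmer:
                    continue
                table.setdefault(kmer, []).append(base | i)

    def lookup(self, kmer: str) -> list[int]:
        return self._map.get(kmer, ())

    def decode(self, packed: int) -> tuple[int, int]:
        return packed >> _POS_BITS, packed & _POS_MASK


def build_index(genome: Genome, k: int) -> KmerIndex:
    """Build the forward-strand k-mer index used by all alignment steps."""
    return KmerIndex(genome, k)


def default_index_k(config) -> int:
    """Largest seed size that keeps the pigeonhole completeness guarantee for
    segments at the configured mismatch bound."""
    return max(4, config.segment_length // (config.max_segment_mismatches + 1))


def _count_mismatches(garr: np.ndarray, qarr: np.ndarray, limit: int) -> int:
    """Hamming distance with genome N counting as a mismatch even against a
    read N (genome N never matches anything)."""
    mm = int(np.count_nonzero(garr != qarr))
    if mm <= limit:
        mm += int(np.count_nonzero((garr == qarr) & (garr == _N)))
    return mm


def _seed_offsets(length: int, k: int, max_mismatches: int) -> list[int]:
    wanted = max_mismatches + 1
    if wanted * k <= length:
        offsets = [i * k for i in range(wanted)]
    else:
        offsets = list(range(0, max(length - k, 0) + 1, k))
    tail = length - k
    if tail >= 0 and tail not in offsets:
        offsets.append(tail)
    return offsets


def align_exactish(
    index: KmerIndex,
    genome: Genome,
    query: str,
    max_mismatches: int,
    max_hits: Optional[int] = None,
    segment_index: int = 0,
) -> list[SegmentAlignment]:
    """Every placement of `query` on either strand with <= max_mismatches,
    found by seeding on error-free k-mers and extending without gaps.

    The result is deterministic (sorted by chrom, position, strand) and capped
    at ``max_hits + 1`` entries so callers can detect "more than max_hits".
    """
    L = len(query)
    k = index.k
    if L < k:
        raise ValueError(f"query length {L} is shorter than index k={k}")
    offsets = _seed_offsets(L, k, max_mismatches)
    hits: list[tuple[str, int, str, int]] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        qarr = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
        seen: set[int] = set()
        for off in offsets:
            for packed in index.lookup(q[off : off + k]):
                start_packed = packed - off
                if start_packed in seen:
                    continue
                seen.add(start_packed)
                ci, pos = index.decode(packed)
                start = pos - off
                garr = index.encoded[index.chrom_names[ci]]
                if start < 0 or start + L > garr.shape[0]:
                    continue
                mm = _count_mismatches(garr[start : start + L], qarr, max_mismatches)
                if mm <= max_mismatches:
                    hits.append((index.chrom_names[ci], start, strand, mm))
    hits.sort()
    if max_hits is not None:
        hits = hits[: max_hits + 1]
    return [
        SegmentAlignment(chrom, start, strand, mm, segment_index, L)
        for chrom, start, strand, mm in hits
    ]


def align_whole_read(
    index: KmerIndex,
    genome: Genome,
    read: Read,
    max_mismatches: int,
    max_hits: Optional[int] = None,
) -> list[FullAlignment]:
    """End-to-end gap-free placements of a whole read.

    Reads with at least one such placement are not initially-unmapped (IUM);
    reads with none enter fusion discovery.
    """
    hits = align_exactish(index, genome, read.sequence, max_mismatches, max_hits)
    out = []
    for hit in hits:
        aln = FullAlignment(
            read.id,
            read.sequence,
            [Block(hit.chrom, hit.start, hit.end, hit.strand)],
            [],
            hit.mismatches,
        )
        out.append(aln)
    return out
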