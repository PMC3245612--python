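"""Score how well reads are distributed around each surviving fusion and sort
the final report.

The score rewards covered bases and (capped) average depth in the two windows
flanking the junction and penalises left/right imbalance, coverage gaps and
coverage variance; a support-rate term rewards supporting evidence spread
away from the junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from splicefuse.filters import FusionSupport
from splicefuse.fusion_discovery import FusionCandidate


@dataclass
class CoverageProfile:
    """Per-base depths over the two windows flanking a junction, each
    window_half long, stored in transcript orientation."""

    ldepth: np.ndarray
    rdepth: np.ndarray

    def __post_init__(self) -> None:
        self.ldepth = np.asarray(self.ldepth, dtype=np.int64)
        self.rdepth = np.asarray(self.rdepth, dtype=np.int64)
        if self.ldepth.ndim != 1 or self.rdepth.ndim != 1:
            raise ValueError("depth profiles must be 1-D")
        if len(self.ldepth) != len(self.rdepth):
            raise ValueError("left and right windows must have equal size")
        if (self.ldepth < 0).any() or (self.rdepth < 0).any():
            raise ValueError("depths must be >= 0")


@dataclass
class ScoreComponents:
    lcount: int
    rcount: int
    lavg: float
    ravg: float
    lgap: int
    rgap: int
    lder: float
    rder: float
    max_avg: int = 300
    rate: float = 0.0
    dist: int = 0


@dataclass
class FusionReport:
    candidate: FusionCandidate
    kind: str
    support: FusionSupport
    profile: Optional[CoverageProfile] = None
    components: Optional[ScoreComponents] = None
    score: float = 0.0
    genes_left: tuple = ()
    genes_right: tuple = ()


def _longest_zero_run(depth: np.ndarray) -> int:
    best = run = 0
    for d in depth:
        if d == 0:
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


def coverage_stats(
    depth: Sequence[int],
    avg: Optional[float] = None,
) -> tuple[int, float, int, float]:
    """(count, avg, gap, der) for one window's depth array.

    count is the number of covered bases, avg the mean depth (computed from
    the array when not supplied), gap the length of the longest zero-depth
    run, and der the normalized coverage deviation::

        der = sqrt( (1/window) * sum_n ((avg - depth_n) / avg)^2 )

    When avg == 0 der is defined as 1.0 (the candidate should already have
    been rejected by the coverage filter).
    """
    arr = np.asarray(depth, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("depth must be a non-empty 1-D array")
    count = int(np.count_nonzero(arr))
    if avg is None:
        avg = float(arr.mean())
    gap = _longest_zero_run(arr)
    if avg > 0:
        der = math.sqrt(float(np.mean(((avg - arr) / avg) ** 2)))
    else:
        der = 1.0
    return count, float(avg), gap, der


def components_from_profile(
    profile: CoverageProfile,
    support: FusionSupport,
    max_avg: int = 300,
    paired: bool = True,
) -> ScoreComponents:
    """Assemble score components from a coverage profile and support counts.

    rate is supporting pairs (spanning reads for single-end data) over
    contradicting reads, with denominator 1 when there are no contradicting
    reads; dist sums each supporting end's distance to the junction (spanning
    read offsets for single-end data).
    """
    lcount, lavg, lgap, lder = coverage_stats(profile.ldepth)
    rcount, ravg, rgap, rder = coverage_stats(profile.rdepth)
    denom = max(1, support.contradicting_reads)
    if paired:
        rate = support.supporting_pairs / denom
        dist = support.pair_distance_sum
    else:
        rate = support.spanning_reads / denom
        dist = support.spanning_distance_sum
    return ScoreComponents(lcount, rcount, lavg, ravg, lgap, rgap, lder, rder,
                           max_avg, rate, dist)


def fusion_score(c: ScoreComponents) -> float:
    """Read-distribution score; higher is better."""
    return (
        c.lcount
        + c.rcount
        + min(c.max_avg, c.lavg)
        + min(c.max_avg, c.ravg)
        - abs(c.lcount - c.rcount)
        - min(c.max_avg, abs(c.lavg - c.ravg))
        - (c.lgap + c.rgap)
        - (c.lder + c.rder) * c.max_avg
        + c.rate * min(1000, c.dist)
    )


def rank_fusions(reports: list[FusionReport]) -> list[FusionReport]:
    """Sort descending by score; ties by support sum (descending) then by
    coordinates, so the order is deterministic."""
    def key(r: FusionReport):
        cand = r.candidate
        return (
            -r.score,
            -(r.support.spanning_reads + r.support.supporting_pairs),
            cand.left.chrom, cand.left.pos, cand.right.chrom, cand.right.pos,
            cand.left.strand, cand.right.strand,
        )

    return sorted(reports, key=key)
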