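"""Exact repeat-pair detection and clustering into putative array loci.

The scanner finds every pair of identical substrings whose length lies in the
repeat window and whose end-to-start gap lies in the spacer window -- the raw
signal a CRISPR array leaves in a genome.  A pair (pos1, pos2, length) is
reported iff it is containment-maximal on its diagonal: no admissible pair with
the same occurrence distance strictly contains it.  Matched pairs are then
single-linkage chained into clusters of co-located occurrences, one cluster per
putative array locus.

The implementation hashes nothing and builds no index: because the occurrence
distance d = length + gap is bounded by the two windows, only diagonals
d in [repeat_len_min + spacer_len_min, repeat_len_max + spacer_len_max] can
carry admissible pairs, and each diagonal is scanned with one vectorized
character comparison.  ``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_cli import GenomeRecord, PipelineConfig

__all__ = ["RepeatMatchPair", "RepeatCluster", "find_repeat_pairs", "cluster_pairs"]


@dataclass(frozen=True)
class RepeatMatchPair:
    """Two identical substrings at (pos1, pos2), 0-based, pos1 < pos2."""

    seq: str
    pos1: int
    pos2: int
    length: int

    @property
    def gap(self) -> int:
        """End-to-start gap between the two occurrences (the spacer length)."""
        return self.pos2 - (self.pos1 + self.length)


@dataclass
class RepeatCluster:
    """Co-located putative repeat occurrences forming one array locus.

    ``members`` are deduplicated occurrence intervals sorted by start (they may
    overlap for tandem-like loci); ``member_seqs`` are the parallel substrings.
    """

    members: list = field(default_factory=list)  # of (start, end)
    member_seqs: list = field(default_factory=list)

    @property
    def sequences(self) -> list[str]:
        """Deduplicated member substrings, first-seen order preserved."""
        seen: dict[str, None] = {}
        for s in self.member_seqs:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0][0], max(e for _, e in self.members))


def find_repeat_pairs(g: GenomeRecord, cfg: PipelineConfig) -> list[RepeatMatchPair]:
    """Return every containment-maximal exact repeat pair within the windows.

    Output is deduplicated and sorted by (pos1, pos2).  A genome too short to
    host two repeats and a spacer returns ``[]``.
    """
    n = g.length
    lmin, lmax = cfg.repeat_len_min, cfg.repeat_len_max
    smin, smax = cfg.spacer_len_min, cfg.spacer_len_max
    if n < 2 * lmin + smin:
        return []

    arr = np.frombuffer(g.seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    pairs: list[RepeatMatchPair] = []

    d_lo, d_hi = lmin + smin, lmax + smax
    for d in range(d_lo, min(d_hi, n - lmin) + 1):
        eq = (arr[:-d] == arr[d:]) & valid[:-d] & valid[d:]
        if not eq.any():
            continue
        # run-length encode the boolean match profile on this diagonal
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        lo = max(lmin, d - smax)
        for r, e in zip(starts, ends):
            m = int(e - r)
            hi = min(lmax, m, d - smin)
            if hi < lo:
                continue
            # containment-maximal admissible pairs all have length hi
            for s in range(int(r), int(r) + m - hi + 1):
                pairs.append(RepeatMatchPair(
                    seq=g.seq[s:s + hi], pos1=s, pos2=s + d, length=hi))

    uniq = {(p.pos1, p.pos2, p.length): p for p in pairs}
    return sorted(uniq.values(), key=lambda p: (p.pos1, p.pos2))


def cluster_pairs(
    pairs: Sequence[RepeatMatchPair], cfg: PipelineConfig
) -> list[RepeatCluster]:
    """Single-linkage chain pair occurrences into clusters.

    Two occurrence intervals join one cluster iff the gap between them is at
    most ``spacer_len_max + repeat_len_max`` (the largest possible array
    period).  Every occurrence lands in exactly one cluster; clusters are
    sorted by span start.
    """
    if not pairs:
        return []
    occ: dict[tuple[int, int], str] = {}
    for p in pairs:
        occ[(p.pos1, p.pos1 + p.length)] = p.seq
        occ[(p.pos2, p.pos2 + p.length)] = p.seq

    intervals = sorted(occ)
    clusters: list[RepeatCluster] = []
    current = RepeatCluster()
    reach = None  # rightmost end seen in the current chain
    for iv in intervals:
        if reach is not None and iv[0] - reach > cfg.chain_distance:
            clusters.append(current)
            current = RepeatCluster()
            reach = None
        current.members.append(iv)
        current.member_seqs.append(occ[iv])
        reach = iv[1] if reach is None else max(reach, iv[1])
    clusters.append(current)
    return clusters
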