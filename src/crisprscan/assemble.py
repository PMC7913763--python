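"""Edit-tolerant mapping of repeat variants back onto the genome.

Each candidate repeat variant is searched for approximately (substitutions,
insertions and deletions, unit cost) in the padded cluster region; the
non-overlapping occurrences are chained into an array candidate whenever
consecutive occurrences are separated by at most one spacer window.  Zero
gaps are allowed -- complete spacer deletion is a documented biological event.
Two further repairs mirror how real arrays decay: a substitution-only search
for a degenerate terminal repeat beyond each array end, and optional merging
of two arrays split by an insertion-sequence (IS) element.

Occurrence search contract
--------------------------
For every end position the semi-global edit distance of the variant against a
window ending there is computed (free start).  Ends within the edit budget are
visited in (edits, end) order; each is resolved to a window by a deterministic
traceback preferring substitution/match over deletion over insertion, and
accepted if it does not overlap a previously accepted window.  Tests pin this
contract against an independent quadratic dynamic-programming oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io_cli import GenomeRecord, PipelineConfig

__all__ = [
    "Occurrence",
    "ArrayCandidate",
    "fuzzy_occurrences",
    "build_array",
    "extend_degenerate",
    "merge_is_split",
    "edit_op_counts",
    "default_is_detector",
    "never_is_detector",
]

DAMAGED = "damaged"
SEVERELY_DAMAGED = "severely damaged"


@dataclass(frozen=True)
class Occurrence:
    """One (possibly inexact) repeat occurrence, 0-based half-open."""

    start: int
    end: int
    subs: int
    ins: int
    dels: int
    label: str | None = None

    @property
    def edits(self) -> int:
        return self.subs + self.ins + self.dels

    def shifted(self, offset: int) -> "Occurrence":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class ArrayCandidate:
    """An ordered alternation of repeat occurrences and spacers."""

    genome_id: str
    repeat_variant: str
    occurrences: tuple  # of Occurrence, sorted, non-overlapping
    strand: str = "+"
    is_gap_indices: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        occ = self.occurrences
        if len(occ) < 2:
            raise ValueError("an array candidate needs at least 2 repeats")
        for a, b in zip(occ, occ[1:]):
            if b.start < a.end:
                raise ValueError("occurrences overlap or are unsorted")

    @property
    def n_repeats(self) -> int:
        return len(self.occurrences)

    @property
    def start(self) -> int:
        return self.occurrences[0].start

    @property
    def end(self) -> int:
        return self.occurrences[-1].end

    @property
    def region(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def spacer_intervals(self) -> tuple:
        """Gaps between consecutive occurrences (zero-length allowed)."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.occurrences, self.occurrences[1:])
        )

    @property
    def total_edits(self) -> int:
        return sum(o.edits for o in self.occurrences)

    def spacer_seqs(self, g: GenomeRecord) -> tuple:
        return tuple(g.seq[s:e] for s, e in self.spacer_intervals)

    def occurrence_seqs(self, g: GenomeRecord) -> tuple:
        return tuple(g.seq[o.start:o.end] for o in self.occurrences)


# ---------------------------------------------------------------------------
# approximate occurrence search
# ---------------------------------------------------------------------------

def _encode(seq: str, mask_n: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    # N must match nothing: give query and target Ns distinct sentinels
    arr[arr == ord("N")] = mask_n
    return arr


def _semiglobal_matrix(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Full DP matrix D[(m+1), (n+1)]: edit distance of query vs windows of
    target with free start (D[0, j] = 0)."""
    m, n = len(query), len(target)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0] = 0
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cost = (target != query[i - 1]).astype(np.int32)
        prev = D[i - 1]
        base = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        row = np.empty(n + 1, dtype=np.int32)
        row[0] = i
        row[1:] = base
        # left-dependency via running minimum of (value - j) + j
        D[i] = np.minimum.accumulate(row - idx) + idx
    return D


def _traceback(D: np.ndarray, query: np.ndarray, target: np.ndarray,
               end: int) -> tuple[int, int, int, int]:
    """Resolve window start and edit-op counts for an occurrence ending at
    ``end``; prefers substitution/match > deletion > insertion."""
    i, j = D.shape[0] - 1, end
    subs = ins = dels = 0
    while i > 0:
        here = D[i, j]
        if j > 0:
            cost = int(target[j - 1] != query[i - 1])
            if D[i - 1, j - 1] + cost == here:
                subs += cost
                i, j = i - 1, j - 1
                continue
        if D[i - 1, j] + 1 == here:
            dels += 1
            i -= 1
            continue
        ins += 1
        j -= 1
    return j, subs, ins, dels


def fuzzy_occurrences(
    region_seq: str, repeat: str, edit_budget: int
) -> list[Occurrence]:
    """All non-overlapping occurrences of ``repeat`` within ``region_seq`` at
    edit distance <= ``edit_budget``; fewest-edits-first greedy selection."""
    if not repeat or not region_seq:
        return []
    q = _encode(repeat, ord("?"))
    t = _encode(region_seq, ord("!"))
    D = _semiglobal_matrix(q, t)
    final = D[-1]
    ends = np.flatnonzero(final <= edit_budget)
    if ends.size == 0:
        return []
    order = sorted(ends.tolist(), key=lambda e: (int(final[e]), e))
    accepted: list[Occurrence] = []
    for e in order:
        s, subs, ins, dels = _traceback(D, q, t, e)
        if s >= e:
            continue
        if any(not (e <= o.start or s >= o.end) for o in accepted):
            continue
        accepted.append(Occurrence(start=s, end=e, subs=subs, ins=ins, dels=dels))
    accepted.sort(key=lambda o: o.start)
    return accepted


def edit_op_counts(a: str, b: str) -> tuple[int, int, int]:
    """Global alignment op counts of ``a`` (reference) vs ``b`` (observed):
    (substitutions, insertions-in-b, deletions-from-a)."""
    q = _encode(a, ord("?"))
    t = _encode(b, ord("!"))
    m, n = len(q), len(t)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0] = np.arange(n + 1)
    for i in range(1, m + 1):
        D[i, 0] = i
        cost = (t != q[i - 1]).astype(np.int32)
        base = np.minimum(D[i - 1, 1:] + 1, D[i - 1, :-1] + cost)
        row = np.empty(n + 1, dtype=np.int32)
        row[0] = i
        row[1:] = base
        idx = np.arange(n + 1, dtype=np.int32)
        D[i] = np.minimum.accumulate(row - idx) + idx
    i, j = m, n
    subs = ins = dels = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = int(t[j - 1] != q[i - 1])
            if D[i - 1, j - 1] + cost == D[i, j]:
                subs += cost
                i, j = i - 1, j - 1
                continue
        if i > 0 and D[i - 1, j] + 1 == D[i, j]:
            dels += 1
            i -= 1
            continue
        ins += 1
        j -= 1
    return subs, ins, dels


# ---------------------------------------------------------------------------
# array construction
# ---------------------------------------------------------------------------

def build_array(
    g: GenomeRecord,
    cluster_span: tuple[int, int],
    variant: str,
    cfg: PipelineConfig,
) -> ArrayCandidate | None:
    """Chain fuzzy occurrences of ``variant`` around a cluster span into an
    array candidate, or ``None`` if fewer than two occurrences chain.

    The span is padded by one repeat+spacer period on both sides so boundary
    repeats are catchable.  Chains break where the gap between consecutive
    occurrences exceeds the spacer window; the longest chain wins (ties:
    leftmost).
    """
    pad = cfg.repeat_len_max + cfg.spacer_len_max
    lo = max(0, cluster_span[0] - pad)
    hi = min(g.length, cluster_span[1] + pad)
    occs = fuzzy_occurrences(g.seq[lo:hi], variant, cfg.edit_budget)
    if len(occs) < 2:
        return None
    occs = [o.shifted(lo) for o in occs]

    chains: list[list[Occurrence]] = [[occs[0]]]
    for o in occs[1:]:
        if o.start - chains[-1][-1].end > cfg.spacer_len_max:
            chains.append([o])
        else:
            chains[-1].append(o)
    best = max(chains, key=len)  # max() keeps the leftmost on ties
    if len(best) < 2:
        return None
    return ArrayCandidate(
        genome_id=g.id, repeat_variant=variant, occurrences=tuple(best))


def extend_degenerate(
    a: ArrayCandidate, g: GenomeRecord, cfg: PipelineConfig
) -> ArrayCandidate:
    """Search one period beyond each array end for a degenerate terminal
    repeat (substitution-only) and extend the array if one is found.

    An accepted copy is labeled "damaged" when its substitution count is at
    most ``degenerate_damaged_max`` (default 5), else "severely damaged".
    Acceptance requires subs <= min(degenerate_sub_cap, len(variant) // 3);
    the length-scaled guard keeps random flanking sequence out for short
    repeats.
    """
    variant = a.repeat_variant
    L = len(variant)
    limit = min(cfg.degenerate_sub_cap, L // 3)
    window = cfg.repeat_len_max + cfg.spacer_len_max
    q = _encode(variant, ord("?"))

    def _best_hamming(lo: int, hi: int) -> tuple[int, int] | None:
        """(start, subs) of the best full-length substitution-only match with
        start in [lo, hi]; ties to the smallest gap handled by caller order."""
        if hi < lo:
            return None
        t = _encode(g.seq[lo:hi + L], ord("!"))
        if len(t) < L:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(t, L)
        mism = (windows != q).sum(axis=1)
        k = int(mism.argmin())
        return lo + k, int(mism[k])

    occs = list(a.occurrences)

    # rightward: gap = start - array end must fit the spacer window
    right_lo = a.end
    right_hi = min(a.end + cfg.spacer_len_max, a.end + window - L, g.length - L)
    hit = _best_hamming(right_lo, right_hi)
    if hit is not None and hit[1] <= limit:
        s, subs = hit
        label = DAMAGED if subs <= cfg.degenerate_damaged_max else SEVERELY_DAMAGED
        occs.append(Occurrence(start=s, end=s + L, subs=subs, ins=0, dels=0,
                               label=label))

    # leftward: mirror of the above
    left_hi = a.start - L
    left_lo = max(0, a.start - cfg.spacer_len_max - L, a.start - window)
    hit = _best_hamming(left_lo, left_hi)
    if hit is not None and hit[1] <= limit and hit[0] + L <= a.start:
        s, subs = hit
        label = DAMAGED if subs <= cfg.degenerate_damaged_max else SEVERELY_DAMAGED
        occs.insert(0, Occurrence(start=s, end=s + L, subs=subs, ins=0, dels=0,
                                  label=label))

    if len(occs) == len(a.occurrences):
        return a
    occs.sort(key=lambda o: o.start)
    return replace(a, occurrences=tuple(occs))


# ---------------------------------------------------------------------------
# IS-element mediated split repair
# ---------------------------------------------------------------------------

def never_is_detector(gap_seq: str) -> bool:
    """Trivial detector: nothing is an IS element (the test default)."""
    return False


def default_is_detector(gap_seq: str) -> bool:
    """Length + ORF heuristic: an IS element is a mobile gene, so a long gap
    carrying a substantial open reading frame in any of the six frames."""
    from .features import find_orfs  # local import avoids a cycle

    if len(gap_seq) < 400:
        return False
    return any(e - s >= 300 for s, e in find_orfs(gap_seq))


def merge_is_split(
    arrays: Sequence[ArrayCandidate],
    g: GenomeRecord,
    is_detector: Callable[[str], bool],
    cfg: PipelineConfig,
) -> list[ArrayCandidate]:
    """Merge neighboring arrays with identical repeat variants whose gap is an
    IS element; the gap interval is annotated and excluded from spacer stats."""
    arrays = sorted(arrays, key=lambda a: a.start)
    out: list[ArrayCandidate] = []
    for a in arrays:
        if out:
            prev = out[-1]
            if (prev.genome_id == a.genome_id
                    and prev.repeat_variant == a.repeat_variant
                    and a.start >= prev.end
                    and is_detector(g.seq[prev.end:a.start])):
                gap_index = len(prev.occurrences) - 1
                merged = ArrayCandidate(
                    genome_id=prev.genome_id,
                    repeat_variant=prev.repeat_variant,
                    occurrences=prev.occurrences + a.occurrences,
                    strand=prev.strand,
                    is_gap_indices=frozenset(
                        set(prev.is_gap_indices)
                        | {gap_index}
                        | {i + len(prev.occurrences) for i in a.is_gap_indices}
                    ),
                )
                out[-1] = merged
                continue
        out.append(a)
    return out
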