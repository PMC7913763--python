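"""Cluster enhancement: the candidate repeat set between a minimal core and a
maximal consensus.

Exact pair matching alone cannot decide whether nucleotides shared by chance at
spacer boundaries belong to the repeat or to the spacers.  The remedy is to
expand each cluster into a set of repeat variants: a maximal element (the
column-majority consensus of the aligned members), a minimal element (the
longest run of unanimously agreeing columns), every contiguous variant in
between, and end-trimmed versions of each.  Downstream, each variant is mapped
back to the genome and the classifier arbitrates between the resulting arrays.

"Between" is read as contiguous end extension/contraction only: variants share
the anchored core and differ at the flanks, which is the only ambiguity exact
pair matching can create at a fixed locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_cli import PipelineConfig
from .repeat_scan import RepeatCluster

__all__ = [
    "UnderSupportedClusterError",
    "InconsistentConsensusError",
    "CandidateRepeatSet",
    "build_consensus_elements",
    "enumerate_filter_set",
    "trim_variants",
    "assemble_candidate_set",
]

_ALPHA_ORDER = "ACGT"


class UnderSupportedClusterError(ValueError):
    """Cluster has fewer than two members; no consensus can be formed."""


class InconsistentConsensusError(ValueError):
    """The minimal element does not occur within the maximal element."""


@dataclass(frozen=True)
class CandidateRepeatSet:
    """The enhanced variant set for one cluster.

    ``provenance`` maps each variant to how it arose: ``filter_set`` (between
    min and max element), ``original`` (a raw cluster member) or ``trim``.
    """

    cluster_ref: RepeatCluster
    max_elem: str
    min_elem: str
    variants: tuple
    provenance: dict


def _slide_offset(anchor: str, member: str) -> int:
    """Best gap-free offset of ``member`` against ``anchor``; ties leftmost."""
    best_off, best_score = 0, -1
    for off in range(-len(member) + 1, len(anchor)):
        lo = max(0, off)
        hi = min(len(anchor), off + len(member))
        if hi <= lo:
            continue
        score = sum(
            1 for j in range(lo, hi) if anchor[j] == member[j - off]
        )
        if score > best_score:
            best_off, best_score = off, score
    return best_off


def build_consensus_elements(
    cluster: RepeatCluster, max_members: int | None = None
) -> tuple[str, str]:
    """Compute the (max_elem, min_elem) consensus pair for a cluster.

    Members are end-gap aligned by sliding each against the longest member
    (ties: leftmost offset).  The maximal element takes each column's most
    frequent non-gap nucleotide (ties broken A<C<G<T); the minimal element is
    the leftmost longest run of columns on which all members agree and are
    non-gap.  If no column is covered unanimously (possible for heterogeneous
    tandem-like clusters) the rule relaxes to columns on which all *covering*
    members agree.
    """
    seqs = list(cluster.member_seqs)
    if len(seqs) < 2:
        raise UnderSupportedClusterError(
            f"cluster with {len(seqs)} member(s) cannot support a consensus")
    if max_members is not None and len(seqs) > max_members:
        # keep the most frequent member sequences; deterministic tie order
        counts = Counter(seqs)
        ranked = sorted(counts, key=lambda s: (-counts[s], s))
        keep = []
        for s in ranked:
            keep.extend([s] * counts[s])
            if len(keep) >= max_members:
                break
        seqs = keep[:max_members]

    anchor = max(seqs, key=len)  # first of the longest members
    offsets = [_slide_offset(anchor, s) if s is not anchor else 0 for s in seqs]
    lo = min(offsets)
    hi = max(off + len(s) for off, s in zip(offsets, seqs))

    columns: list[list[str]] = [[] for _ in range(hi - lo)]
    for off, s in zip(offsets, seqs):
        for j, c in enumerate(s):
            columns[off + j - lo].append(c)

    max_elem = "".join(
        min(col and Counter(col).items(),
            key=lambda kv: (-kv[1], _ALPHA_ORDER.index(kv[0])))[0]
        for col in columns
    )

    n = len(seqs)
    full = [len(col) == n and len(set(col)) == 1 for col in columns]
    if not any(full):
        full = [len(set(col)) == 1 for col in columns]
    best = (0, 0)  # (length, start); leftmost longest run
    run_start = None
    for j, ok in enumerate(full + [False]):
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            if j - run_start > best[0]:
                best = (j - run_start, run_start)
            run_start = None
    if best[0] == 0:
        return max_elem, max_elem
    min_elem = max_elem[best[1]:best[1] + best[0]]
    return max_elem, min_elem


def enumerate_filter_set(max_elem: str, min_elem: str) -> list[str]:
    """All contiguous substrings of ``max_elem`` containing the anchored core.

    The leftmost occurrence of ``min_elem`` anchors the core; with L left and R
    right flanking positions there are exactly (L+1)*(R+1) such substrings
    before deduplication.
    """
    idx = max_elem.find(min_elem)
    if idx < 0:
        raise InconsistentConsensusError(
            f"minimal element {min_elem!r} not found in maximal {max_elem!r}")
    L = idx
    R = len(max_elem) - idx - len(min_elem)
    out: dict[str, None] = {}
    for i in range(L + 1):
        for j in range(R + 1):
            out.setdefault(max_elem[i:len(max_elem) - j], None)
    return list(out)


def trim_variants(repeat: str, max_trim: int = 3) -> list[str]:
    """End-trimmed variants: up to ``max_trim`` nt omitted from both ends.

    Before deduplication there are (max_trim+1)**2 - 1 variants (15 for the
    default); a repeat no longer than 2*max_trim returns ``[]``.
    """
    if len(repeat) <= 2 * max_trim:
        return []
    out: dict[str, None] = {}
    for i in range(max_trim + 1):
        for j in range(max_trim + 1):
            if i == 0 and j == 0:
                continue
            out.setdefault(repeat[i:len(repeat) - j], None)
    return list(out)


def assemble_candidate_set(
    cluster: RepeatCluster, cfg: PipelineConfig | None = None
) -> CandidateRepeatSet:
    """Unify the filter set, the original cluster members and their trims.

    Variants shorter than ``repeat_len_min - max_trim`` or longer than
    ``repeat_len_max`` (not admissible repeats) are dropped; the list is
    deduplicated with provenance priority filter_set > original > trim and
    capped at ``max_variants_per_cluster`` (filter set and originals first).
    """
    cfg = cfg or PipelineConfig()
    max_elem, min_elem = build_consensus_elements(
        cluster, max_members=cfg.max_consensus_members)
    floor = cfg.repeat_len_min - cfg.max_trim
    ceiling = cfg.repeat_len_max

    provenance: dict[str, str] = {}
    for v in enumerate_filter_set(max_elem, min_elem):
        provenance.setdefault(v, "filter_set")
    for v in cluster.sequences:
        provenance.setdefault(v, "original")
    for v in list(provenance):
        for t in trim_variants(v, cfg.max_trim):
            provenance.setdefault(t, "trim")

    variants = [v for v in provenance if floor <= len(v) <= ceiling]
    variants = variants[:cfg.max_variants_per_cluster]
    provenance = {v: provenance[v] for v in variants}
    return CandidateRepeatSet(
        cluster_ref=cluster, max_elem=max_elem, min_elem=min_elem,
        variants=tuple(variants), provenance=provenance)
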