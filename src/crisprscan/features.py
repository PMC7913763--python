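"""The 13 array-derived features used to classify candidates.

Repeat-level evidence (count, length, internal similarity, mismatches,
AT-content, hairpin stability, similarity to known repeats), spacer-level
evidence (mutual similarity, mean length, length uniformity) and whole-region
evidence (overlap with protein-coding ORFs, tandem-repeat-protein likeness)
together describe what separates a functional CRISPR array from look-alike
repetitive elements.  The vector order is fixed and documented in
``FEATURE_NAMES``; trained models depend on it.

Pluggable engines
-----------------
The hairpin score, ORF caller, tandem scorer and reference aligner all accept
a replacement callable.  The bundled defaults are self-contained: a Nussinov
base-pair-maximization fold (pseudo-energy -1 per pair, minimum loop 3, with
G-U wobble), a six-frame ATG..stop ORF scanner, a protein half-identity
periodicity scorer, and a Smith-Waterman local aligner (match +1, mismatch -1,
gap -2) normalized by the shorter sequence.  Each is a deliberately simple
stand-in with the same sign of correlation as the heavier tools practitioners
may plug in; a model must be scored with the engines it was trained with,
which is recorded in the model metadata.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .assemble import ArrayCandidate
from .io_cli import GenomeRecord, PipelineConfig, normalize_sequence, read_fasta

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FOLDING_ENGINE_ID",
    "repeat_stats",
    "at_content",
    "mfe_score",
    "reference_similarity",
    "spacer_stats",
    "orf_score",
    "tandem_score",
    "featurize",
    "find_orfs",
    "identity",
    "load_reference_repeats",
]

FEATURE_NAMES = (
    "n_repeats",
    "repeat_length",
    "repeat_similarity",
    "n_mismatches",
    "at_content",
    "mfe_score",
    "blast_exact",
    "blast_relaxed",
    "spacer_similarity",
    "avg_spacer_len",
    "spacer_uniformity",
    "orf_score",
    "tandem_score",
)

FOLDING_ENGINE_ID = "nussinov-v1"


@dataclass(frozen=True)
class FeatureVector:
    n_repeats: int
    repeat_length: int
    repeat_similarity: float
    n_mismatches: int
    at_content: float
    mfe_score: float
    blast_exact: float
    blast_relaxed: float
    spacer_similarity: float
    avg_spacer_len: float
    spacer_uniformity: float
    orf_score: float
    tandem_score: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES],
                        dtype=float)


def identity(a: str, b: str) -> float:
    """1 - edit_distance/max(len); two empty strings are identical."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


# ---------------------------------------------------------------------------
# repeat-level features
# ---------------------------------------------------------------------------

def repeat_stats(
    a: ArrayCandidate, g: GenomeRecord
) -> tuple[int, int, float, int]:
    """(n_repeats, repeat_length, repeat_similarity, n_mismatches).

    Similarity is the mean over occurrences of 1 - edits/max(len), measured
    against the repeat variant; mismatches are total edit operations.
    """
    variant = a.repeat_variant
    sims = []
    total = 0
    for occ, seq in zip(a.occurrences, a.occurrence_seqs(g)):
        edits = occ.edits
        sims.append(1.0 - edits / max(len(seq), len(variant)))
        total += edits
    return a.n_repeats, len(variant), float(np.mean(sims)), total


def at_content(repeat: str) -> float:
    """(#A + #T) / length with N excluded from numerator and denominator."""
    if not repeat:
        raise ValueError("AT-content of an empty sequence is undefined")
    denom = sum(1 for c in repeat if c != "N")
    if denom == 0:
        return 0.0
    return sum(1 for c in repeat if c in "AT") / denom


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@functools.lru_cache(maxsize=65536)
def _nussinov_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs with a minimum loop length."""
    n = len(seq)
    if n <= min_loop:
        return 0
    can_pair = np.zeros((n, n), dtype=np.int32)
    for (x, y) in _PAIRS:
        xi = np.array([c == x for c in seq])
        yj = np.array([c == y for c in seq])
        can_pair |= xi[:, None] & yj[None, :]
    M = np.zeros((n + 1, n + 1), dtype=np.int32)  # padded: M[i, j] on [i, j)
    for span in range(min_loop + 2, n + 1):
        i = np.arange(0, n - span + 1)
        j = i + span  # exclusive end; last char index j-1
        best = M[i, j - 1].copy()
        for k_off in range(0, span - min_loop - 1):
            k = i + k_off
            cand = M[i, k] + M[k + 1, j - 1] + 1
            hit = can_pair[k, j - 1].astype(bool)
            np.maximum(best, np.where(hit, cand, 0), out=best)
        M[i, j] = best
    return int(M[0, n])


def mfe_score(repeat: str, folding: Callable[[str], float] | None = None) -> float:
    """Hairpin stability score: max(0, -MFE) of the transcribed repeat.

    The default engine scores -1 pseudo-energy per nested base pair (Nussinov
    maximization, minimum loop 3), so the score equals the maximal number of
    base pairs.  A thermodynamic folder returning an MFE in kcal/mol may be
    plugged in instead.
    """
    rna_as_dna = normalize_sequence(repeat)
    if folding is not None:
        return max(0.0, -float(folding(rna_as_dna)))
    return float(_nussinov_pairs(rna_as_dna))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()
_BASES = "ACGT"


@functools.lru_cache(maxsize=16)
def _relaxed_db(ref_db: tuple, seed: int) -> tuple:
    """Deterministically mutated copy of the reference set: every
    single-substitution variant at 3 seeded positions per entry plus one
    seeded 2-substitution variant."""
    out = []
    for k, entry in enumerate(ref_db):
        rng = np.random.default_rng((seed * 1_000_003 + k) % (2 ** 31))
        if len(entry) < 2:
            out.append(entry)
            continue
        positions = rng.choice(len(entry), size=min(3, len(entry)), replace=False)
        for p in sorted(int(x) for x in positions):
            for b in _BASES:
                if b != entry[p]:
                    out.append(entry[:p] + b + entry[p + 1:])
        p1, p2 = sorted(int(x) for x in
                        rng.choice(len(entry), size=2, replace=False))
        b1 = _BASES[int(rng.integers(4))]
        b2 = _BASES[int(rng.integers(4))]
        mutated = list(entry)
        mutated[p1] = b1 if b1 != entry[p1] else _BASES[(_BASES.index(entry[p1]) + 1) % 4]
        mutated[p2] = b2 if b2 != entry[p2] else _BASES[(_BASES.index(entry[p2]) + 1) % 4]
        out.append("".join(mutated))
    return tuple(out)


def _best_local_score(repeat: str, db: tuple) -> float:
    best = 0.0
    for entry in db:
        if not entry:
            continue
        score = _ALIGNER.score(entry, repeat) / min(len(entry), len(repeat))
        if score > best:
            best = score
    return min(1.0, max(0.0, best))


@functools.lru_cache(maxsize=65536)
def _reference_similarity_cached(
    repeat: str, ref_db: tuple, seed: int
) -> tuple[float, float]:
    exact = _best_local_score(repeat, ref_db)
    relaxed = _best_local_score(repeat, _relaxed_db(ref_db, seed))
    return exact, relaxed


def reference_similarity(
    repeat: str, ref_db: Sequence[str], seed: int = 0
) -> tuple[float, float]:
    """(blast_exact, blast_relaxed): normalized local-alignment similarity of
    the repeat to the reference set and to its mutated copy, both in [0, 1]."""
    if not ref_db:
        raise ValueError("reference repeat database is empty")
    return _reference_similarity_cached(repeat, tuple(ref_db), seed)


def load_reference_repeats(path=None) -> list[str]:
    """Load the user-supplied reference repeat FASTA, or the small synthetic
    fixture shipped with the package."""
    if path is None:
        source = resources.files("crisprscan.data") / "reference_repeats.synthetic.fasta"
        with resources.as_file(source) as p:
            return [r.seq for r in read_fasta(p)]
    return [r.seq for r in read_fasta(path)]


# ---------------------------------------------------------------------------
# spacer-level features
# ---------------------------------------------------------------------------

def spacer_stats(
    a: ArrayCandidate, g: GenomeRecord
) -> tuple[float, float, float]:
    """(spacer_similarity, avg_spacer_len, spacer_uniformity).

    Similarity is the maximum pairwise identity; uniformity is the
    coefficient of variation of spacer lengths (population std / mean, 0 for
    a single spacer or zero mean).  IS-annotated gaps are excluded.  An array
    with no true spacers returns (0, 0, 0).
    """
    seqs = [s for k, s in enumerate(a.spacer_seqs(g))
            if k not in a.is_gap_indices]
    if not seqs:
        return 0.0, 0.0, 0.0
    sim = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            sim = max(sim, identity(seqs[i], seqs[j]))
    lengths = np.array([len(s) for s in seqs], dtype=float)
    mean = float(lengths.mean())
    cv = float(lengths.std() / mean) if mean > 0 else 0.0
    return sim, mean, cv


# ---------------------------------------------------------------------------
# whole-region features
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: str, min_len: int = 150) -> list[tuple[int, int]]:
    """ATG..stop ORFs of at least ``min_len`` nt in all six frames, returned
    as intervals on the forward coordinate system."""
    n = len(seq)
    out = []
    for strand_seq, forward in ((seq, True),
                                (seq.translate(_RC_TABLE)[::-1], False)):
        for frame in range(3):
            start = None
            for p in range(frame, n - 2, 3):
                codon = strand_seq[p:p + 3]
                if start is None:
                    if codon == "ATG":
                        start = p
                elif codon in _STOPS:
                    end = p + 3
                    if end - start >= min_len:
                        if forward:
                            out.append((start, end))
                        else:
                            out.append((n - end, n - start))
                    start = None
    return sorted(out)


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


@functools.lru_cache(maxsize=8192)
def _orfs_cached(seq: str) -> tuple:
    return tuple(find_orfs(seq))


def orf_score(
    region_seq: str,
    array_interval: tuple[int, int] | None = None,
    caller: Callable[[str], Sequence[tuple[int, int]]] | None = None,
) -> float:
    """Protein-coding evidence overlapping the array.

    score = max over ORFs of (fraction of the array interval covered by the
    ORF) * min(1, ORF length / 300), clamped to [0, 1]; 0 without ORFs.
    """
    orfs = caller(region_seq) if caller is not None else _orfs_cached(region_seq)
    if array_interval is None:
        array_interval = (0, len(region_seq))
    a0, a1 = array_interval
    span = max(1, a1 - a0)
    best = 0.0
    for s, e in orfs:
        overlap = max(0, min(e, a1) - max(s, a0))
        if overlap == 0:
            continue
        best = max(best, (overlap / span) * min(1.0, (e - s) / 300.0))
    return min(1.0, best)


@functools.lru_cache(maxsize=8192)
def _tandem_cached(region_seq: str) -> float:
    orfs = _orfs_cached(region_seq)
    if not orfs:
        return 0.0
    s, e = max(orfs, key=lambda iv: iv[1] - iv[0])
    sub = region_seq[s:e]
    # orientation does not matter for half-identity periodicity; translate
    # the forward frame of whichever strand yields a clean frame
    prot = str(Seq(sub).translate(to_stop=False))
    arr = np.frombuffer(prot.encode("ascii", errors="replace"), dtype=np.uint8)
    best = 0.0
    for h in range(20, min(len(arr) // 2, 90) + 1):
        win = np.lib.stride_tricks.sliding_window_view(arr, h)
        if len(win) <= h:
            continue
        frac = (win[:-h] == win[h:]).mean(axis=1)
        m = float(frac.max())
        if m > best:
            best = m
    return best


def tandem_score(
    region_seq: str, scorer: Callable[[str], float] | None = None
) -> float:
    """Tandem-repeat-protein likeness of the best ORF in the region.

    The default scorer translates the longest ORF and slides even-length
    windows of at least 40 residues over the protein, scoring the maximum
    fraction of identical residues between the two window halves -- a
    periodicity surrogate for profile-HMM tandem-repeat detection.  Returns 0
    when the region has no ORF.
    """
    if scorer is not None:
        return float(scorer(region_seq))
    return _tandem_cached(region_seq)


# ---------------------------------------------------------------------------
# assembly of the full vector
# ---------------------------------------------------------------------------

_ORF_PAD = 300  # nt of context around the array when scanning for ORFs


def featurize(
    a: ArrayCandidate,
    g: GenomeRecord,
    cfg: PipelineConfig,
    ref_db: Sequence[str] | None = None,
    folding: Callable[[str], float] | None = None,
    orf_caller=None,
    tandem_scorer=None,
) -> FeatureVector:
    """Assemble the 13 features for an array candidate, in canonical order.

    A pure function of (array, genome, config, reference set, engines); model
    feature subsets are selected downstream, never here.
    """
    if ref_db is None:
        ref_db = load_reference_repeats(cfg.reference_repeats_path)
    n_rep, rep_len, rep_sim, n_mm = repeat_stats(a, g)
    atc = at_content(a.repeat_variant)
    mfe = mfe_score(a.repeat_variant, folding)
    b_exact, b_relaxed = reference_similarity(a.repeat_variant, ref_db, cfg.seed)
    sp_sim, sp_len, sp_cv = spacer_stats(a, g)

    lo = max(0, a.start - _ORF_PAD)
    hi = min(g.length, a.end + _ORF_PAD)
    region = g.seq[lo:hi]
    interval = (a.start - lo, a.end - lo)
    orf = orf_score(region, interval, orf_caller)
    tandem = tandem_score(region, tandem_scorer)

    return FeatureVector(
        n_repeats=n_rep,
        repeat_length=rep_len,
        repeat_similarity=rep_sim,
        n_mismatches=n_mm,
        at_content=atc,
        mfe_score=mfe,
        blast_exact=b_exact,
        blast_relaxed=b_relaxed,
        spacer_similarity=sp_sim,
        avg_spacer_len=sp_len,
        spacer_uniformity=sp_cv,
        orf_score=orf,
        tandem_score=tandem,
    )
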