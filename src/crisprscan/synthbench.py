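"""Synthetic benchmark generation and caller scoring.

The generators emit arrays with the statistical structure of curated CRISPR
benchmark sets: positives with at least three near-identical repeats and
unique spacers of near-uniform length, and three families of negatives that
mimic the classic false-positive modes -- shuffled arrays (each repeat and
each spacer independently letter-permuted), tandem repeats (a unit copied
back-to-back with light substitution noise, i.e. zero-length "spacers"), and
arrays whose "spacers" are all identical (a non-CRISPR repetitive element).
Every generator is a pure function of its spec and seed.

Spacers in positives are rejected while they share any 15-mer with the
repeat, so planted boundaries are unambiguous and boundary-recovery tests are
crisp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assemble import ArrayCandidate, Occurrence, edit_op_counts
from .io_cli import GenomeRecord, PipelineConfig

__all__ = [
    "PlantedArraySpec",
    "BenchmarkResult",
    "random_seq",
    "generate_positive",
    "shuffle_negative",
    "tandem_negative",
    "identical_spacer_negative",
    "candidate_from_truth",
    "sample_positive_spec",
    "make_benchmark",
    "score_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SHARED_K = 15  # spacers must not share a k-mer this long with the repeat


@dataclass(frozen=True)
class PlantedArraySpec:
    """Ground-truth description of one planted array."""

    repeat: str
    n_repeats: int
    spacer_lengths: tuple
    per_repeat_substitutions: tuple
    flank_lengths: tuple = (300, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("a planted array needs at least 2 repeats")
        if len(self.spacer_lengths) != self.n_repeats - 1:
            raise ValueError("need n_repeats - 1 spacer lengths")
        if len(self.per_repeat_substitutions) != self.n_repeats:
            raise ValueError("need one substitution count per repeat")


@dataclass(frozen=True)
class BenchmarkResult:
    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    tnr: float
    acc: float
    bacc: float
    mcc: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("tp", "tn", "fp", "fn", "tpr", "tnr", "acc", "bacc",
                          "mcc")}


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _shares_kmer(a: str, b: str, k: int = _SHARED_K) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    positions = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in positions:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def generate_positive(
    spec: PlantedArraySpec,
) -> tuple[GenomeRecord, list[tuple[int, int]]]:
    """Plant a clean array in random flanks; returns (genome, repeat intervals).

    Spacers are uniform random DNA re-drawn until they share no 15-mer with
    the repeat.  Repeat copies carry the specified substitution counts at
    seeded random positions.  Fully deterministic given the spec.

    Planted boundaries are kept unambiguous: if every spacer (plus the
    adjacent flank) happened to start -- or end -- with the same nucleotide,
    the repeat boundary itself would be ill-defined (the shared character
    would be an equally valid repeat extension), so the first spacer is
    re-drawn until at least two boundary characters differ.
    """
    rng = np.random.default_rng(spec.seed)
    left = random_seq(rng, spec.flank_lengths[0])
    right = random_seq(rng, spec.flank_lengths[1])

    def draw_spacer(n: int) -> str:
        while True:
            s = random_seq(rng, n)
            if not _shares_kmer(spec.repeat, s):
                return s

    spacers = [draw_spacer(n) for n in spec.spacer_lengths]
    if spacers and left and right:
        while len({s[0] for s in spacers} | {right[0]}) == 1 or \
                len({s[-1] for s in spacers} | {left[-1]}) == 1:
            spacers[0] = draw_spacer(spec.spacer_lengths[0])
    parts = [left]
    truth: list[tuple[int, int]] = []
    pos = len(left)
    for i in range(spec.n_repeats):
        rep = _mutate(rng, spec.repeat, spec.per_repeat_substitutions[i])
        parts.append(rep)
        truth.append((pos, pos + len(rep)))
        pos += len(rep)
        if i < spec.n_repeats - 1:
            parts.append(spacers[i])
            pos += len(spacers[i])
    parts.append(right)
    genome = GenomeRecord(id=f"planted_{spec.seed}", seq="".join(parts))
    return genome, truth


def _intervals_between(truth: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(a[1], b[0]) for a, b in zip(truth, truth[1:])]


def shuffle_negative(
    g: GenomeRecord, truth: Sequence[tuple[int, int]], seed: int
) -> GenomeRecord:
    """Letter-permute each repeat and each spacer interval independently;
    flanks untouched.  Mononucleotide composition is preserved per interval."""
    rng = np.random.default_rng(seed)
    seq = list(g.seq)
    for s, e in list(truth) + _intervals_between(truth):
        chunk = seq[s:e]
        rng.shuffle(chunk)
        seq[s:e] = chunk
    return GenomeRecord(id=f"{g.id}_shuffled_{seed}", seq="".join(seq))


def tandem_negative(
    unit: str, n_copies: int, seed: int, flank: int = 300,
) -> tuple[GenomeRecord, list[tuple[int, int]]]:
    """A tandem repeat: the unit copied back-to-back with 1-2% per-copy
    substitutions -- the classic CRISPR mimic with zero-length "spacers"."""
    rng = np.random.default_rng(seed)
    left = random_seq(rng, flank)
    right = random_seq(rng, flank)
    parts = [left]
    truth = []
    pos = flank
    rate = rng.uniform(0.01, 0.02)
    for _ in range(n_copies):
        n_subs = int(rng.binomial(len(unit), rate))
        copy = _mutate(rng, unit, n_subs)
        parts.append(copy)
        truth.append((pos, pos + len(copy)))
        pos += len(copy)
    parts.append(right)
    genome = GenomeRecord(id=f"tandem_{seed}", seq="".join(parts))
    return genome, truth


def identical_spacer_negative(
    repeat: str, spacer: str, n: int, seed: int, flank: int = 300,
) -> tuple[GenomeRecord, list[tuple[int, int]]]:
    """An array whose spacers are all the same sequence: a repetitive element
    masquerading as CRISPR."""
    if n < 4:
        raise ValueError("identical-spacer negatives use at least 4 repeats")
    rng = np.random.default_rng(seed)
    left = random_seq(rng, flank)
    right = random_seq(rng, flank)
    parts = [left]
    truth = []
    pos = flank
    for i in range(n):
        parts.append(repeat)
        truth.append((pos, pos + len(repeat)))
        pos += len(repeat)
        if i < n - 1:
            parts.append(spacer)
            pos += len(spacer)
    parts.append(right)
    genome = GenomeRecord(id=f"idspacer_{seed}", seq="".join(parts))
    return genome, truth


def candidate_from_truth(
    g: GenomeRecord, truth: Sequence[tuple[int, int]]
) -> ArrayCandidate:
    """Build an array candidate directly from ground-truth repeat intervals.

    The repeat variant is the column-majority consensus of the interval
    substrings; per-occurrence edit-operation counts are measured against it.
    Used to extract training features from generated arrays without running
    detection (the benchmark harness never peeks at features).
    """
    seqs = [g.seq[s:e] for s, e in truth]
    width = max(len(s) for s in seqs)
    cols = []
    for j in range(width):
        letters = [s[j] for s in seqs if j < len(s)]
        counts: dict[str, int] = {}
        for c in letters:
            counts[c] = counts.get(c, 0) + 1
        cols.append(min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    variant = "".join(cols)
    occs = []
    for (s, e), seq in zip(truth, seqs):
        subs, ins, dels = edit_op_counts(variant, seq)
        occs.append(Occurrence(start=s, end=e, subs=subs, ins=ins, dels=dels))
    return ArrayCandidate(genome_id=g.id, repeat_variant=variant,
                          occurrences=tuple(occs))


# ---------------------------------------------------------------------------
# sampling at the benchmark's study conditions
# ---------------------------------------------------------------------------

def sample_positive_spec(
    rng: np.random.Generator,
    cfg: PipelineConfig | None = None,
    clean: bool = False,
) -> PlantedArraySpec:
    """Draw one realistic positive array spec.

    3-10 repeats of 21-55 nt; spacer lengths near-uniform within an array
    (base 20-60 nt, +-2 jitter), matching the narrow within-array spacer
    length distribution of real arrays; repeats are exact with probability
    0.7, else carry 1-2 substitutions (``clean=True`` forces exact repeats).
    """
    cfg = cfg or PipelineConfig()
    n_rep = int(rng.integers(3, 11))
    rep_len = int(rng.integers(cfg.repeat_len_min, cfg.repeat_len_max + 1))
    base = int(rng.integers(20, 61))
    spacer_lengths = tuple(
        int(np.clip(base + rng.integers(-2, 3), cfg.spacer_len_min,
                    cfg.spacer_len_max))
        for _ in range(n_rep - 1)
    )
    if clean:
        subs = tuple(0 for _ in range(n_rep))
    else:
        subs = tuple(
            int(rng.integers(1, 3)) if rng.random() > 0.7 else 0
            for _ in range(n_rep)
        )
    return PlantedArraySpec(
        repeat=random_seq(rng, rep_len),
        n_repeats=n_rep,
        spacer_lengths=spacer_lengths,
        per_repeat_substitutions=subs,
        seed=int(rng.integers(0, 2 ** 31)),
    )


def make_benchmark(
    seed: int,
    n_pos: int,
    n_neg: int,
    cfg: PipelineConfig | None = None,
    clean_positives: bool = False,
) -> list[tuple[GenomeRecord, bool, list[tuple[int, int]]]]:
    """Seeded benchmark samples: (genome, label, truth intervals).

    Negatives mix 50% shuffled arrays, 25% tandem repeats and 25%
    identical-spacer arrays.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_pos):
        g, truth = generate_positive(sample_positive_spec(rng, cfg,
                                                          clean=clean_positives))
        samples.append((g, True, truth))
    for i in range(n_neg):
        kind = i % 4
        if kind in (0, 1):  # 50% shuffled
            g, truth = generate_positive(sample_positive_spec(rng, cfg))
            shuffled = shuffle_negative(g, truth, seed=int(rng.integers(2 ** 31)))
            samples.append((shuffled, False, truth))
        elif kind == 2:  # 25% tandem
            unit = random_seq(rng, int(rng.integers(24, 81)))
            g, truth = tandem_negative(unit, int(rng.integers(4, 9)),
                                       seed=int(rng.integers(2 ** 31)))
            samples.append((g, False, truth))
        else:  # 25% identical spacers
            repeat = random_seq(rng, int(rng.integers(cfg.repeat_len_min,
                                                      cfg.repeat_len_max + 1)))
            spacer = random_seq(rng, int(rng.integers(cfg.spacer_len_min, 51)))
            g, truth = identical_spacer_negative(
                repeat, spacer, int(rng.integers(4, 9)),
                seed=int(rng.integers(2 ** 31)))
            samples.append((g, False, truth))
    return samples


def score_benchmark(
    calls: Sequence[bool], labels: Sequence[bool]
) -> BenchmarkResult:
    """Confusion counts and TPR/TNR/ACC/BACC/MCC for binary calls.

    Convention: a rate with a zero denominator is 0, and MCC is 0 whenever
    any confusion-matrix marginal is 0.
    """
    if len(calls) != len(labels):
        raise ValueError("calls and labels differ in length")
    tp = sum(1 for c, l in zip(calls, labels) if c and l)
    tn = sum(1 for c, l in zip(calls, labels) if not c and not l)
    fp = sum(1 for c, l in zip(calls, labels) if c and not l)
    fn = sum(1 for c, l in zip(calls, labels) if not c and l)
    total = tp + tn + fp + fn
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total if total else 0.0
    bacc = (tpr + tnr) / 2
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return BenchmarkResult(tp=tp, tn=tn, fp=fp, fn=fn, tpr=tpr, tnr=tnr,
                           acc=acc, bacc=bacc, mcc=float(mcc))
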