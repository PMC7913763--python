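# Methods

This note documents the models, algorithms and numerical choices behind
`crisprscan`, what the synthetic benchmark does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Candidate generation

### Repeat-pair scanning

A CRISPR array leaves exact (or near-exact) repeated substrings at a spacing
bounded by biology. The scanner reports every pair of identical substrings
(pos1, pos2, length) with length in the repeat window (default 21–55 nt) and
end-to-start gap in the spacer window (default 18–78 nt) — the gap rather
than the center distance, because the gap *is* the spacer. `N` matches
nothing, including another `N`.

Since the occurrence distance `d = length + gap` is confined to
`[repeat_min + spacer_min, repeat_max + spacer_max]` (39–133 nt by default),
only ~95 diagonals of the self-comparison matrix can carry admissible pairs;
each is scanned with one vectorized character comparison and run-length
encoding. A pair is reported iff it is **containment-maximal** on its
diagonal: no admissible pair with the same occurrence distance strictly
contains it. Within a maximal matching run of length `M` on diagonal `d` the
containment-maximal pairs are exactly the windows of length
`min(repeat_max, M, d − spacer_min)`, provided that is at least
`max(repeat_min, d − spacer_max)`. The contract is pinned by a property test
against brute-force enumeration of *all* substring pairs on sequences up to
500 nt.

Occurrence intervals are then single-linkage chained into clusters: two
occurrences join one cluster iff their gap is at most
`spacer_max + repeat_max` (the largest possible array period — the method's
own choice; no threshold is inherited). Clustering partitions the
occurrences; clusters are the pipeline's loci.

### Cluster enhancement: the candidate set F

Exact pair matching cannot decide whether nucleotides shared by chance at
spacer boundaries belong to the repeat or the spacers. Each cluster is
therefore expanded into a set of repeat variants between two consensus
elements:

- members are end-gap aligned by sliding each against the longest member
  (best match count; ties → leftmost offset). The alignment is deliberately
  gap-free internally: members are same-locus occurrences differing mainly at
  their ends, and internal indels are handled later by the fuzzy search;
- the **maximal element** takes each column's most frequent non-gap
  nucleotide (ties broken in fixed order A<C<G<T, for determinism);
- the **minimal element** is the leftmost longest run of columns on which all
  members agree with full coverage. If no column is covered by every member
  (possible for heterogeneous tandem-like clusters) the rule relaxes to
  columns on which all covering members agree; if even that fails, the
  maximal element itself is used;
- the filter set contains every contiguous substring of the maximal element
  that includes the anchored core — with `L` left and `R` right flanking
  positions, `(L+1)·(R+1)` strings. "Between" is read as contiguous end
  extension/contraction only: non-contiguous subsequences cannot map back to
  a fixed genomic locus and would explode combinatorially;
- the variant set is the union of the filter set, the raw cluster members,
  and end-trimmed versions of each (up to 3 nt off each end; 15 variants per
  repeat before deduplication). Variants shorter than `repeat_min − 3` or
  longer than `repeat_max` are dropped — the latter because slid consensus
  of tandem-like clusters can otherwise produce multi-period pseudo-repeats.

Two desk-scale caps keep pathological loci (long tandem runs generate
hundreds of overlapping members) bounded: at most 32 member sequences enter
the consensus (most frequent first) and at most 64 variants per cluster are
evaluated (filter set and originals before trims). Clean array loci stay far
below both caps.

### Edit-tolerant array assembly

Each variant is searched for in the cluster region (padded by one period on
both sides, so boundary repeats are catchable) under a unit-cost edit budget
(default 3 per occurrence). For every end position the semi-global edit
distance of the variant against a window ending there is computed with a
vectorized DP (the left-dependency of the recurrence is resolved with a
running-minimum transform, so each row is a handful of array operations).
Candidate ends within budget are visited in (edits, end) order; each is
resolved to a window by a traceback that prefers substitution/match over
deletion over insertion, and accepted greedily if it does not overlap an
accepted window. The identical contract is implemented independently as a
plain-Python quadratic DP and the two are required to agree on every tested
region.

Occurrences chain into an array while consecutive gaps are at most
`spacer_max`; zero-length gaps are allowed (complete spacer deletion), the
longest chain wins (ties → leftmost), and arrays need at least two
occurrences to be emitted (three to be eligible for the bona-fide call).

**Degenerate terminal repeats.** One window of length
`repeat_max + spacer_max` beyond each array end is scanned substitution-only
(full-length Hamming profiles, vectorized); the best position with gap at
most `spacer_max` is accepted if its substitution count is at most
`min(10, L//3)` for repeat length `L`. The cap of 10 bounds the severely
damaged class (damaged: ≤5 substitutions; severely damaged: 6–10); the
`L//3` guard is a false-positive control: for a 21-nt repeat the background
mismatch count against random flanks is Binomial(21, 0.75) and reaches 10
often enough that, uncapped, random sequence would regularly be absorbed as
a "severely damaged" terminal repeat.

**IS-split merging.** Two neighboring arrays with identical repeat variants
whose gap passes an injectable detector are merged; the gap is annotated and
excluded from all spacer statistics (otherwise merging would poison spacer
uniformity). The bundled default detector is a length + ORF heuristic (gap
≥ 400 nt carrying an ORF ≥ 300 nt — an insertion sequence is a mobile gene);
profile-HMM-based detectors can be plugged in. Merging is off by default and
exposed as a CLI flag.

## The 13 features

Order is fixed (`features.FEATURE_NAMES`); models record their subset and are
refused if the feature-engine identifier does not match.

| feature | definition | default/units |
|---|---|---|
| n_repeats | occurrence count | count |
| repeat_length | variant length | nt |
| repeat_similarity | mean over occurrences of 1 − edits/max(len), vs the variant | [0,1] |
| n_mismatches | total edit operations across occurrences | count |
| at_content | (#A + #T)/length, N excluded from both sides | [0,1] |
| mfe_score | max(0, −MFE) of the transcribed repeat | pairs (bundled engine) |
| blast_exact | best normalized local-alignment score vs the reference repeat set | [0,1] |
| blast_relaxed | same, vs a deterministically mutated copy of the set | [0,1] |
| spacer_similarity | max pairwise spacer identity (1 − edit/max(len)) | [0,1] |
| avg_spacer_len | mean spacer length | nt |
| spacer_uniformity | coefficient of variation of spacer lengths | ≥0 |
| orf_score | max over ORFs of overlap-fraction × min(1, len/300) | [0,1] |
| tandem_score | max half-identity of even windows ≥40 aa over the best ORF's protein | [0,1] |

Notes on the bundled engines, each pluggable and each chosen to carry the
same sign of correlation as the heavier tool a practitioner might swap in:

- **Folding** is Nussinov base-pair maximization (pairs A-T, G-C and the
  G-T wobble; minimum loop 3; −1 pseudo-energy per pair), so `mfe_score`
  equals the maximal number of nested pairs. A thermodynamic folder can be
  plugged in, but a model must then be retrained: the engine id is stored in
  model metadata and checked at scoring time.
- **Reference similarity** is Smith–Waterman (match +1, mismatch −1, gap −2,
  via Biopython's PairwiseAligner) normalized by the shorter sequence and
  clamped to [0,1]. Unrelated random sequences score ~0.25 under this scheme.
  The relaxed copy of the reference set adds, per entry, every
  single-substitution variant at three seeded positions plus one seeded
  two-substitution variant. The packaged reference set is a synthetic
  stand-in (12 hairpin-bearing repeat-like sequences, generated, labelled
  synthetic); users supply their own curated set via
  `--reference-repeats`.
- **ORF calling** scans all six frames for ATG→stop frames ≥150 nt in the
  array region padded by 300 nt. Reverse-strand ORFs count: coding sequence
  under an "array" is evidence against it regardless of strand.
- **Tandem-protein likeness** translates the longest ORF and slides
  even-length windows (40–180 residues) over the protein, scoring the best
  fraction of identical residues between the two window halves — a
  periodicity surrogate for profile-HMM tandem-repeat search. Nucleotide
  periodicity survives any reading frame, so the forward-frame translation
  suffices even for reverse-strand ORFs.
- **Spacer statistics** exclude IS-annotated gaps; an array with no true
  spacers (two repeats, spacer deleted) reports (0, 0, 0). Two zero-length
  spacers are defined identical (similarity 1) — back-to-back repeats are
  maximal evidence of tandem structure.

## Classification and grouping

The classifier family is extremely randomized trees (100 estimators, default
depth, fixed seed; scikit-learn). The certainty score is the positive-class
pseudo-probability, averaged when several models are used. Three default
models ship as *feature subsets* (8, 9 and 10 features) chosen by our own
wrapper subset search over the synthetic training distribution; the models
themselves are trained at run time from the seed, so no binary model files
are distributed. Trained bundles can be saved/loaded (joblib) and are checked
for feature-engine compatibility.

**Training set.** 400 positives + 400 negatives by default (negatives mixed
50% shuffled / 25% tandem / 25% identical-spacer; configurable). Arrays are
featurized from their ground-truth repeat/spacer partition, mirroring how
curated arrays enter training as given loci. A **hard-negative mining** pass
then runs the detector on every negative genome, scores its candidates with a
stage-one model trained on the truth-based set, and adds the top three per
genome (above score 0.1) as extra negatives. This closes a blind spot:
detection of tandem-like regions emits sub-sampled periodicities — e.g.
two-occurrence candidates whose single "spacer" looks ordinary — that a
truth-only training set never contains.

**Grouping.** Scores ≥ 0.75 → candidate group; [0.4, 0.75) → possible;
< 0.4 → low score (both thresholds configurable, ≥/< semantics exact). Per
locus, the bona-fide candidate is chosen among eligible candidates (score
≥ 0.75, ≥ 3 repeats) whose scores lie within `score_tie_margin` (default
0.1) of the eligible maximum: pseudo-probabilities that close are ties at
the ensemble's resolution — measured spread between boundary variants of one
clean array is below 0.09 — and are resolved structurally: more repeats,
fewer total edit operations, longer repeat, leftmost. This prefers the
maximal exactly-matching variant (correct boundaries) over trims (shorter)
and over extensions into spacer territory (which carry edits).

**Suspicious-array rules.** Independently of the learned score, an array is
flagged when any of: max pairwise spacer identity > 0.6; mean repeat identity
< 0.8; repeat-vs-spacer similarity > 0.5; any spacer shorter than 30% of the
mean (i.e. 70% shorter than average; strict <). The repeat-vs-spacer rule
uses the normalized local-alignment score rather than whole-sequence edit
identity: random DNA pairs sit at ~0.5 edit identity, which would make the
0.5 threshold fire on noise, whereas local-alignment similarity of unrelated
sequences is ~0.25 and a spacer containing a repeat fragment scores near 1.

**Feature subset search.** The wrapper enumerates feature subsets (all
non-empty subsets up to a budget, or restricted sizes), scores each by
stratified k-fold cross-validated accuracy (k = 10 by default) and sorts by
accuracy, then size. For 13 features the full enumeration is 2^13 − 1 = 8191
subsets.

## The synthetic benchmark

Every generator is a pure function of its spec and seed (byte-identical
reruns). Defaults define the study conditions:

- **positives**: 3–10 repeats of 21–55 nt; per-array base spacer length
  uniform in 20–60 nt with ±2 nt jitter (real arrays have near-uniform
  spacer lengths within an array); repeats exact with probability 0.7, else
  1–2 substitutions; 300-nt random flanks. Spacers are re-drawn until they
  share no 15-mer with the repeat, and until at least two spacer boundary
  characters (including the adjacent flank) differ — otherwise the planted
  boundary itself would be formally ambiguous, defeating the generator's
  purpose of unambiguous ground truth;
- **shuffled negatives**: each repeat and each spacer interval independently
  letter-permuted (composition preserved, similarity destroyed);
- **tandem negatives**: a 24–80 nt unit copied 4–8 times back-to-back with
  1–2% per-copy substitutions — the classic CRISPR mimic with zero-length
  "spacers";
- **identical-spacer negatives**: ≥4 repeats all separated by one identical
  spacer — a non-CRISPR repetitive element.

What the generator does **not** emulate: genomic base composition bias and
repeat families (flanks are uniform random), leader sequences and cas-gene
context, repeat/spacer length distributions of particular taxa, arrays
overlapping real coding sequence, and degraded arrays beyond the single
planted damaged terminal. Passing tests therefore demonstrate the machinery
— boundary resolution, edit-tolerant assembly, separability of the four
structural array families — not classifier performance on real genomes, for
which models should be retrained on curated arrays via the same interfaces.

Benchmark metrics (TPR, TNR, ACC, BACC, MCC) follow the standard formulas;
rates with zero denominators are 0, and MCC is defined as 0 when any
confusion-matrix marginal is zero.

## Numerical and scale choices

- Internal coordinates 0-based half-open; reports 1-based inclusive.
- All tie-breaks are deterministic and documented (leftmost / fixed alphabet
  order / lexicographic), so every stage is reproducible bit-for-bit from
  its seed.
- The reverse strand is scanned on request (`--scan-reverse`) by running the
  forward pipeline on the reverse complement and re-expressing coordinates;
  orientation *prediction* is out of scope.
- Problem sizes in the test suite and acceptance script — 200 seeded trials
  for recovery rates, 400 + 400 training with 200 + 200 held-out, sequences
  ≤ 500 nt for brute-force oracle comparisons — are the package's chosen
  study conditions: large enough that the 0.90/0.95 property bounds have
  narrow binomial uncertainty, small enough to run on a single CPU in
  minutes.

## Known limitations

- The scanner seeds only exact repeat pairs; arrays whose every repeat copy
  differs from every other would be missed at seeding (mismatches enter only
  via fuzzy assembly around exact seeds).
- Reverse-complement (palindromic) repeat pairing is not seeded.
- The bundled ORF/tandem/folding/alignment engines are deliberately simple
  surrogates; their absolute values are not comparable to Prodigal, HMMER,
  RNAfold or BLAST outputs, and models are only valid with the engines they
  were trained with.
- The certainty score is calibrated on the synthetic training distribution;
  on real genomes it should be read as a ranking, not a probability, until
  retrained on curated data.
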