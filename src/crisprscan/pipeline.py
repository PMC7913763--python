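"""End-to-end orchestration: scan -> enhance -> assemble -> featurize ->
score -> group -> flag.

Each repeat-pair cluster is one locus.  Every repeat variant of the cluster's
enhanced candidate set is mapped back to the genome, featurized and scored;
the per-locus grouping then promotes the top scorer (certainty >= 0.75, at
least 3 repeats) to the bona-fide candidate, with the remaining variants kept
as alternatives, possibles or low-score candidates.
"""

from __future__ import annotations

from typing import Callable, Sequence

from . import assemble as asm
from . import enhance, evaluate, features, repeat_scan, synthbench
from .io_cli import GenomeRecord, PipelineConfig

__all__ = ["detect_candidates", "run", "train_default_models"]


def detect_candidates(
    g: GenomeRecord, cfg: PipelineConfig
) -> list[tuple]:
    """Detection half of the pipeline.

    Returns one (cluster, candidate_set, arrays) triple per locus, where
    ``arrays`` holds the assembled, degenerate-extended array candidate for
    each repeat variant that mapped back with at least two occurrences.
    """
    pairs = repeat_scan.find_repeat_pairs(g, cfg)
    out = []
    for cluster in repeat_scan.cluster_pairs(pairs, cfg):
        if len(cluster.member_seqs) < 2:
            continue
        cand_set = enhance.assemble_candidate_set(cluster, cfg)
        arrays = []
        for variant in cand_set.variants:
            a = asm.build_array(g, cluster.span, variant, cfg)
            if a is None:
                continue
            arrays.append(asm.extend_degenerate(a, g, cfg))
        if arrays:
            out.append((cluster, cand_set, arrays))
    return out


def run(
    g: GenomeRecord,
    cfg: PipelineConfig,
    models: Sequence[evaluate.ClassifierModel],
    ref_db: Sequence[str] | None = None,
    merge_is: bool = False,
    is_detector: Callable[[str], bool] | None = None,
) -> list[evaluate.ScoredArray]:
    """Detect, score, group and flag every array candidate in one genome."""
    if ref_db is None:
        ref_db = features.load_reference_repeats(cfg.reference_repeats_path)
    detected = detect_candidates(g, cfg)
    scored: list[evaluate.ScoredArray] = []
    for _, _, arrays in detected:
        if merge_is:
            detector = is_detector or asm.default_is_detector
            arrays = asm.merge_is_split(arrays, g, detector, cfg)
        fvs = [features.featurize(a, g, cfg, ref_db=ref_db) for a in arrays]
        scores = evaluate.score_matrix(fvs, models)
        grouped = evaluate.assign_groups(
            list(zip(arrays, scores.tolist())), cfg, features=fvs)
        for sa in grouped:
            flags = evaluate.flag_suspicious(sa.array, g)
            scored.append(evaluate.ScoredArray(
                array=sa.array, features=sa.features, score=sa.score,
                group=sa.group, flags=flags,
                spacer_seqs=sa.array.spacer_seqs(g)))
    scored.sort(key=lambda s: (s.array.genome_id, s.array.start, -s.score))
    return scored


def train_default_models(
    seed: int,
    n_pos: int = 400,
    n_neg: int = 400,
    cfg: PipelineConfig | None = None,
    ref_db: Sequence[str] | None = None,
) -> list[evaluate.ClassifierModel]:
    """Train the three default models (8/9/10-feature subsets) on the seeded
    synthetic training distribution."""
    cfg = cfg or PipelineConfig(seed=seed)
    if ref_db is None:
        ref_db = features.load_reference_repeats(cfg.reference_repeats_path)
    pos, neg = training_features(seed, n_pos, n_neg, cfg, ref_db)
    return [
        evaluate.train_model(pos, neg, subset, seed=seed + k)
        for k, subset in enumerate(evaluate.DEFAULT_SUBSETS)
    ]


def training_features(
    seed: int,
    n_pos: int,
    n_neg: int,
    cfg: PipelineConfig,
    ref_db: Sequence[str],
    hard_negatives: bool = True,
    hard_neg_per_genome: int = 3,
    hard_neg_floor: float = 0.1,
) -> tuple[list, list]:
    """Feature vectors for a seeded training set.

    Arrays are first featurized from their ground-truth structure (the
    generated repeat/spacer partition), mirroring how curated arrays enter
    training as given loci.  Because the detector emits many variants per
    locus -- including sub-sampled periodicities of tandem-like regions that
    a truth-only training set never shows -- a hard-negative mining pass then
    runs detection on every negative genome, scores the resulting candidates
    with a stage-one model trained on the truth-based set, and adds the
    highest-scoring candidates per genome (above ``hard_neg_floor``) as
    additional negatives.
    """
    samples = synthbench.make_benchmark(seed, n_pos, n_neg, cfg)
    pos, neg = [], []
    for g, label, truth in samples:
        cand = synthbench.candidate_from_truth(g, truth)
        fv = features.featurize(cand, g, cfg, ref_db=ref_db)
        (pos if label else neg).append(fv)

    if hard_negatives and pos and neg:
        stage1 = evaluate.train_model(pos, neg, features.FEATURE_NAMES,
                                      seed=seed)
        mined = []
        for g, label, _ in samples:
            if label:
                continue
            for _, _, arrays in detect_candidates(g, cfg):
                fvs = [features.featurize(a, g, cfg, ref_db=ref_db)
                       for a in arrays]
                scores = stage1.predict_scores(fvs)
                order = sorted(range(len(fvs)), key=lambda i: -scores[i])
                picked = [fvs[i] for i in order[:hard_neg_per_genome]
                          if scores[i] >= hard_neg_floor]
                mined.extend(picked)
        neg = neg + mined
    return pos, neg
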