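"""Candidate evaluation: ensemble training, certainty scores, grouping,
wrapper feature-subset selection and rule-based spurious-array flags.

The classifier is an extremely randomized trees ensemble whose positive-class
pseudo-probability serves as the certainty score; with several models the
score is the mean of per-model scores.  Scores split candidates at 0.75 and
0.4 into candidate / potential / low-score groups, and within each locus the
top scorer at or above 0.75 becomes the bona-fide candidate.

Independently of the learned score, four defect rules flag arrays that are
suspicious by construction: over-similar spacers (identity > 0.6),
under-similar repeats (identity < 0.8), repeat-spacer similarity (> 0.5), and
an uneven spacer length distribution (some spacer 70% shorter than average).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .assemble import ArrayCandidate
from .features import FEATURE_NAMES, FOLDING_ENGINE_ID, FeatureVector, identity
from .io_cli import GenomeRecord, PipelineConfig

__all__ = [
    "ClassifierModel",
    "ScoredArray",
    "SuspicionReport",
    "DEFAULT_SUBSETS",
    "train_model",
    "score_array",
    "score_matrix",
    "assign_groups",
    "feature_subset_search",
    "flag_suspicious",
    "save_models",
    "load_models",
]

N_ESTIMATORS = 100

# the four spurious-array defect rules (see flag_suspicious)
SPACER_IDENTITY_MAX = 0.6        # spacer-vs-spacer identity above -> suspicious
REPEAT_IDENTITY_MIN = 0.8        # mean repeat identity below -> suspicious
REPEAT_SPACER_IDENTITY_MAX = 0.5  # repeat-vs-spacer identity above -> suspicious
SHORT_SPACER_FRACTION = 0.3      # a spacer under this fraction of the mean
#                                  (70% shorter than average) -> suspicious

# Feature subsets of the three default models (8, 9 and 10 features), the
# winners of a wrapper subset search over the synthetic training distribution.
DEFAULT_SUBSETS: tuple = (
    ("n_mismatches", "at_content", "blast_exact", "spacer_similarity",
     "avg_spacer_len", "spacer_uniformity", "orf_score", "tandem_score"),
    ("n_mismatches", "at_content", "mfe_score", "blast_exact",
     "blast_relaxed", "spacer_similarity", "avg_spacer_len",
     "spacer_uniformity", "orf_score"),
    ("n_repeats", "n_mismatches", "at_content", "mfe_score", "blast_exact",
     "blast_relaxed", "spacer_similarity", "avg_spacer_len",
     "spacer_uniformity", "tandem_score"),
)


@dataclass
class ClassifierModel:
    """A trained ensemble plus everything needed to re-score identically."""

    feature_subset: tuple
    estimator: ExtraTreesClassifier
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.feature_subset) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names {sorted(unknown)!r}")

    def _columns(self, fvs: Sequence[FeatureVector]) -> np.ndarray:
        return np.array(
            [[getattr(fv, name) for name in self.feature_subset] for fv in fvs],
            dtype=float,
        )

    def predict_scores(self, fvs: Sequence[FeatureVector]) -> np.ndarray:
        proba = self.estimator.predict_proba(self._columns(fvs))
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


@dataclass(frozen=True)
class SuspicionReport:
    similar_spacers: bool
    damaged_repeats: bool
    repeat_spacer_similarity: bool
    uneven_spacer_lengths: bool

    @property
    def any(self) -> bool:
        return (self.similar_spacers or self.damaged_repeats
                or self.repeat_spacer_similarity or self.uneven_spacer_lengths)


@dataclass(frozen=True)
class ScoredArray:
    """An array candidate with its features, certainty score, group and flags."""

    array: ArrayCandidate
    features: FeatureVector | None
    score: float
    group: str
    flags: SuspicionReport | None = None
    spacer_seqs: tuple = ()

    def on_reverse_strand(self, genome_length: int) -> "ScoredArray":
        """Re-express a candidate found on the reverse complement in forward
        coordinates with strand '-'."""
        a = self.array
        occs = tuple(sorted(
            (replace(o, start=genome_length - o.end, end=genome_length - o.start)
             for o in a.occurrences),
            key=lambda o: o.start))
        flipped = replace(a, occurrences=occs, strand="-")
        return replace(self, array=flipped)


def _matrix(fvs: Sequence[FeatureVector], subset: Sequence[str]) -> np.ndarray:
    return np.array([[getattr(fv, n) for n in subset] for fv in fvs], dtype=float)


def train_model(
    pos: Sequence[FeatureVector],
    neg: Sequence[FeatureVector],
    subset: Sequence[str],
    seed: int,
    n_estimators: int = N_ESTIMATORS,
) -> ClassifierModel:
    """Train one extremely-randomized-trees model on a feature subset.

    Deterministic given (data, subset, seed); the returned model scores the
    positive-class pseudo-probability.
    """
    if not pos or not neg:
        raise ValueError("training requires non-empty positive and negative sets")
    subset = tuple(subset)
    unknown = set(subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names {sorted(unknown)!r}")
    X = np.vstack([_matrix(pos, subset), _matrix(neg, subset)])
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    est = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    est.fit(X, y)
    return ClassifierModel(
        feature_subset=subset,
        estimator=est,
        metadata={
            "seed": seed,
            "n_pos": len(pos),
            "n_neg": len(neg),
            "n_estimators": n_estimators,
            "folding_engine": FOLDING_ENGINE_ID,
            "version": 1,
        },
    )


def _check_engines(models: Sequence[ClassifierModel]) -> None:
    for m in models:
        engine = m.metadata.get("folding_engine", FOLDING_ENGINE_ID)
        if engine != FOLDING_ENGINE_ID:
            raise ValueError(
                f"model trained with folding engine {engine!r}; "
                f"this build scores with {FOLDING_ENGINE_ID!r}")


def score_array(fv: FeatureVector, models: Sequence[ClassifierModel]) -> float:
    """Certainty score: mean positive-class pseudo-probability over models."""
    return float(score_matrix([fv], models)[0])


def score_matrix(
    fvs: Sequence[FeatureVector], models: Sequence[ClassifierModel]
) -> np.ndarray:
    if not models:
        raise ValueError("at least one classifier model is required")
    _check_engines(models)
    per_model = np.stack([m.predict_scores(fvs) for m in models])
    per_model.sort(axis=0)  # order-independent summation
    return per_model.mean(axis=0)


def assign_groups(
    cands: Sequence[tuple],
    cfg: PipelineConfig,
    features: Sequence[FeatureVector] | None = None,
) -> list[ScoredArray]:
    """Group candidates of one locus by certainty score.

    score >= score_high: bona_fide or alternative; score_low <= score <
    score_high: possible; below: low_score.

    The bona-fide candidate is chosen among eligible candidates (score >=
    score_high, >= 3 repeats) whose scores lie within ``score_tie_margin`` of
    the eligible maximum: pseudo-probabilities that close are ties at the
    ensemble's resolution and are broken structurally -- more repeats, fewer
    total edit operations, longer repeat, leftmost.
    """
    if features is None:
        features = [None] * len(cands)
    eligible = [i for i, (arr, score) in enumerate(cands)
                if score >= cfg.score_high and arr.n_repeats >= 3]
    bona_idx = None
    if eligible:
        top = max(cands[i][1] for i in eligible)
        tied = [i for i in eligible
                if cands[i][1] >= top - cfg.score_tie_margin]
        bona_idx = min(tied, key=lambda i: (
            -cands[i][0].n_repeats,
            cands[i][0].total_edits,
            -len(cands[i][0].repeat_variant),
            cands[i][0].start,
        ))
    out = []
    for i, (arr, score) in enumerate(cands):
        if score >= cfg.score_high:
            group = "bona_fide" if i == bona_idx else "alternative"
        elif score >= cfg.score_low:
            group = "possible"
        else:
            group = "low_score"
        out.append(ScoredArray(array=arr, features=features[i], score=score,
                               group=group))
    return out


def feature_subset_search(
    pos: Sequence[FeatureVector],
    neg: Sequence[FeatureVector],
    feature_names: Sequence[str],
    seed: int,
    max_features: int | None = None,
    k: int = 10,
    budget: int = 8191,
    n_estimators: int = N_ESTIMATORS,
    sizes: Sequence[int] | None = None,
) -> list[tuple[tuple, float]]:
    """Wrapper subset search: evaluate feature subsets by k-fold CV accuracy.

    By default every non-empty subset up to ``max_features`` is enumerated
    (guarded by ``budget``); ``sizes`` restricts enumeration to specific
    subset sizes.  Results sorted by accuracy (desc), then subset size.
    """
    feature_names = tuple(feature_names)
    max_features = max_features or len(feature_names)
    wanted = tuple(sizes) if sizes else tuple(range(1, max_features + 1))
    total = sum(
        1 for r in wanted for _ in itertools.combinations(feature_names, r)
    )
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the search budget of {budget}; "
            "restrict the feature list or subset sizes")
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    for r in wanted:
        for subset in itertools.combinations(feature_names, r):
            X = np.vstack([_matrix(pos, subset), _matrix(neg, subset)])
            est = ExtraTreesClassifier(n_estimators=n_estimators,
                                       random_state=seed)
            acc = float(cross_val_score(est, X, y, cv=cv).mean())
            results.append((subset, acc))
    results.sort(key=lambda t: (-t[1], len(t[0]), t[0]))
    return results


def flag_suspicious(a: ArrayCandidate, g: GenomeRecord) -> SuspicionReport:
    """Apply the four defect rules to an assembled array candidate.

    Spacer-vs-spacer identity is whole-sequence (edit-based), matching the
    spacer_similarity feature.  Repeat-vs-spacer similarity is the normalized
    local-alignment score (as used for reference-repeat matching): unrelated
    random sequences score ~0.25 there, so the 0.5 threshold flags genuine
    repeat fragments inside spacers rather than alignment noise.
    """
    from .features import _best_local_score, repeat_stats, spacer_stats

    spacers = [s for i, s in enumerate(a.spacer_seqs(g))
               if i not in a.is_gap_indices]
    sp_sim, _, _ = spacer_stats(a, g)
    _, _, rep_sim, _ = repeat_stats(a, g)
    rs_sim = _best_local_score(
        a.repeat_variant, tuple(s for s in spacers if s))
    lengths = [len(s) for s in spacers]
    uneven = False
    if lengths:
        mean = sum(lengths) / len(lengths)
        uneven = any(l < SHORT_SPACER_FRACTION * mean for l in lengths)
    return SuspicionReport(
        similar_spacers=sp_sim > SPACER_IDENTITY_MAX,
        damaged_repeats=rep_sim < REPEAT_IDENTITY_MIN,
        repeat_spacer_similarity=rs_sim > REPEAT_SPACER_IDENTITY_MAX,
        uneven_spacer_lengths=uneven,
    )


def save_models(models: Sequence[ClassifierModel], path) -> None:
    """Persist trained models as a versioned bundle."""
    joblib.dump(
        [{"feature_subset": m.feature_subset, "estimator": m.estimator,
          "metadata": m.metadata} for m in models],
        path,
    )


def load_models(path) -> list[ClassifierModel]:
    bundles = joblib.load(path)
    models = [ClassifierModel(feature_subset=tuple(b["feature_subset"]),
                              estimator=b["estimator"],
                              metadata=dict(b["metadata"]))
              for b in bundles]
    _check_engines(models)
    return models
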