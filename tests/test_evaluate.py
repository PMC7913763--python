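"""Classifier training, certainty scoring, grouping and suspicion rules."""

import dataclasses

import numpy as np
import pytest

from crisprscan.assemble import ArrayCandidate, Occurrence, build_array
from crisprscan.evaluate import (
    ClassifierModel,
    assign_groups,
    feature_subset_search,
    flag_suspicious,
    load_models,
    save_models,
    score_array,
    score_matrix,
    train_model,
)
from crisprscan.features import FEATURE_NAMES, FeatureVector
from crisprscan.io_cli import PipelineConfig
from crisprscan.synthbench import PlantedArraySpec, generate_positive

from conftest import make_genome, random_dna


def toy_fv(**overrides) -> FeatureVector:
    base = dict(
        n_repeats=4, repeat_length=30, repeat_similarity=1.0, n_mismatches=0,
        at_content=0.5, mfe_score=5.0, blast_exact=0.2, blast_relaxed=0.3,
        spacer_similarity=0.3, avg_spacer_len=35.0, spacer_uniformity=0.05,
        orf_score=0.0, tandem_score=0.1,
    )
    base.update(overrides)
    return FeatureVector(**base)


def separable_sets(rng, n=60):
    pos = [toy_fv(repeat_similarity=1.0 - 0.02 * rng.random(),
                  n_mismatches=int(rng.integers(0, 2)))
           for _ in range(n)]
    neg = [toy_fv(repeat_similarity=0.4 + 0.1 * rng.random(),
                  n_mismatches=int(rng.integers(20, 40)),
                  spacer_similarity=0.9)
           for _ in range(n)]
    return pos, neg


class TestTrainModel:
    def test_separable_toy_is_learned_perfectly(self, rng):
        pos, neg = separable_sets(rng)
        m = train_model(pos[:40], neg[:40], FEATURE_NAMES, seed=0)
        sp = m.predict_scores(pos[40:])
        sn = m.predict_scores(neg[40:])
        assert (sp >= 0.5).all() and (sn < 0.5).all()

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            pos, neg = separable_sets(rng, n=40)
            both = pos + neg
            labels = np.array([1] * 40 + [0] * 40)
            r.shuffle(labels)
            p = [fv for fv, l in zip(both, labels) if l == 1]
            q = [fv for fv, l in zip(both, labels) if l == 0]
            m = train_model(p[: len(p) // 2], q[: len(q) // 2],
                            FEATURE_NAMES, seed=seed, n_estimators=30)
            held_p = p[len(p) // 2:]
            held_q = q[len(q) // 2:]
            correct = (m.predict_scores(held_p) >= 0.5).sum() + (
                m.predict_scores(held_q) < 0.5).sum()
            accs.append(correct / (len(held_p) + len(held_q)))
        assert abs(np.mean(accs) - 0.5) <= 0.12

    def test_training_is_deterministic(self, rng):
        pos, neg = separable_sets(rng)
        probe = pos[:10] + neg[:10]
        m1 = train_model(pos, neg, FEATURE_NAMES, seed=3)
        m2 = train_model(pos, neg, FEATURE_NAMES, seed=3)
        assert np.array_equal(m1.predict_scores(probe), m2.predict_scores(probe))

    def test_empty_class_rejected(self, rng):
        pos, _ = separable_sets(rng, n=5)
        with pytest.raises(ValueError):
            train_model(pos, [], FEATURE_NAMES, seed=0)

    def test_unknown_feature_rejected(self, rng):
        pos, neg = separable_sets(rng, n=5)
        with pytest.raises(ValueError):
            train_model(pos, neg, ("not_a_feature",), seed=0)

    def test_save_load_round_trip(self, rng, tmp_path):
        pos, neg = separable_sets(rng)
        m = train_model(pos, neg, FEATURE_NAMES[:5], seed=1)
        save_models([m], tmp_path / "bundle.joblib")
        (loaded,) = load_models(tmp_path / "bundle.joblib")
        assert loaded.feature_subset == m.feature_subset
        probe = pos[:8]
        assert np.array_equal(loaded.predict_scores(probe),
                              m.predict_scores(probe))


class _FixedModel:
    """Stub with a constant certainty score, for aggregation tests."""

    def __init__(self, value):
        self.value = value
        self.metadata = {}

    def predict_scores(self, fvs):
        return np.full(len(fvs), self.value)


class TestScoreAggregation:
    def test_mean_of_models(self):
        models = [_FixedModel(v) for v in (0.9, 0.6, 0.6)]
        assert score_array(toy_fv(), models) == pytest.approx(0.7)

    def test_single_model_identity(self):
        assert score_array(toy_fv(), [_FixedModel(0.42)]) == pytest.approx(0.42)

    def test_permutation_invariance_and_bounds(self, rng):
        vals = [0.1, 0.5, 0.95]
        models = [_FixedModel(v) for v in vals]
        a = score_matrix([toy_fv()], models)[0]
        b = score_matrix([toy_fv()], models[::-1])[0]
        assert a == b and 0.0 <= a <= 1.0

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            score_array(toy_fv(), [])


def _cand(start, n_repeats=4, rep_len=30, edits=0, gid="g"):
    occs = []
    pos = start
    for i in range(n_repeats):
        occs.append(Occurrence(pos, pos + rep_len, edits if i == 0 else 0, 0, 0))
        pos += rep_len + 35
    return ArrayCandidate(genome_id=gid, repeat_variant="A" * rep_len,
                          occurrences=tuple(occs))


class TestAssignGroups:
    def test_threshold_grouping(self, cfg):
        cands = [(_cand(0), s) for s in (0.9, 0.8, 0.5, 0.2)]
        groups = [sa.group for sa in assign_groups(cands, cfg)]
        assert groups == ["bona_fide", "alternative", "possible", "low_score"]

    def test_exact_threshold_values(self, cfg):
        """score == 0.75 is high (>= rule); score == 0.4 is possible, not low."""
        cands = [(_cand(0), 0.75), (_cand(1000), 0.4),
                 (_cand(2000), 0.39999), (_cand(3000), 0.749)]
        groups = [sa.group for sa in assign_groups(cands, cfg)]
        assert groups == ["bona_fide", "possible", "low_score", "possible"]

    def test_no_bona_fide_below_high(self, cfg):
        cands = [(_cand(0), 0.7), (_cand(500), 0.2)]
        groups = [sa.group for sa in assign_groups(cands, cfg)]
        assert "bona_fide" not in groups
        assert groups == ["possible", "low_score"]

    def test_all_low(self, cfg):
        cands = [(_cand(0), 0.1), (_cand(100), 0.3)]
        assert all(sa.group == "low_score" for sa in assign_groups(cands, cfg))

    def test_two_repeat_candidate_cannot_be_bona_fide(self, cfg):
        cands = [(_cand(0, n_repeats=2), 0.99), (_cand(1000, n_repeats=4), 0.8)]
        groups = [sa.group for sa in assign_groups(cands, cfg)]
        assert groups == ["alternative", "bona_fide"]

    def test_score_tie_prefers_fewer_edits_then_longer_repeat(self, cfg):
        exact = _cand(0, rep_len=30, edits=0)
        noisy = _cand(0, rep_len=32, edits=2)
        trimmed = _cand(0, rep_len=28, edits=0)
        groups = {id(sa.array): sa.group for sa in assign_groups(
            [(noisy, 0.9), (exact, 0.9), (trimmed, 0.9)], cfg)}
        assert groups[id(exact)] == "bona_fide"

    def test_grouping_is_monotone_in_score(self, cfg):
        order = {"low_score": 0, "possible": 1, "alternative": 2, "bona_fide": 2}
        rng = np.random.default_rng(8)
        scores = sorted(rng.random(10).tolist())
        cands = [(_cand(1000 * i), s) for i, s in enumerate(scores)]
        ranks = [order[sa.group] for sa in assign_groups(cands, cfg)]
        assert ranks == sorted(ranks)


class TestFeatureSubsetSearch:
    def test_three_features_give_seven_subsets(self, rng):
        pos, neg = separable_sets(rng, n=30)
        res = feature_subset_search(pos, neg, FEATURE_NAMES[:3], seed=0,
                                    k=3, n_estimators=10)
        assert len(res) == 7

    def test_full_enumeration_count_matches_formula(self):
        # sum_{i=1..13} C(13, i) = 2^13 - 1 non-empty subsets
        assert sum(1 for _ in range(1)) == 1
        from itertools import combinations
        total = sum(len(list(combinations(range(13), r))) for r in range(1, 14))
        assert total == 8191

    def test_budget_guard(self, rng):
        pos, neg = separable_sets(rng, n=10)
        with pytest.raises(ValueError):
            feature_subset_search(pos, neg, FEATURE_NAMES, seed=0, budget=100)

    def test_perfect_feature_beats_noise(self):
        winners_with_noise = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            pos = [toy_fv(repeat_similarity=1.0, at_content=r.random())
                   for _ in range(30)]
            neg = [toy_fv(repeat_similarity=0.3, at_content=r.random())
                   for _ in range(30)]
            res = feature_subset_search(
                pos, neg, ("repeat_similarity", "at_content"), seed=seed,
                k=3, n_estimators=10)
            best_subset, best_acc = res[0]
            if "at_content" in best_subset:
                winners_with_noise += 1
        assert winners_with_noise <= 2  # the noise feature (almost) never wins


class TestFlagSuspicious:
    def _planted_candidate(self, seed, cfg, **kwargs):
        rng = np.random.default_rng(seed)
        spec = PlantedArraySpec(
            repeat=random_dna(rng, 30), n_repeats=5,
            spacer_lengths=kwargs.get("spacer_lengths", (35, 35, 35, 35)),
            per_repeat_substitutions=kwargs.get("subs", (0, 0, 0, 0, 0)),
            seed=seed)
        g, truth = generate_positive(spec)
        a = build_array(g, (truth[0][0], truth[-1][1]), spec.repeat, cfg)
        return a, g

    def test_clean_array_has_no_flags(self, cfg):
        a, g = self._planted_candidate(41, cfg)
        rep = flag_suspicious(a, g)
        assert not rep.any

    def test_identical_spacers_flagged(self, rng, cfg):
        R, S = random_dna(rng, 30), random_dna(rng, 35)
        g = make_genome(random_dna(rng, 100) + R + S + R + S + R
                        + random_dna(rng, 100))
        a = build_array(g, (100, 100 + 3 * 30 + 2 * 35), R, cfg)
        assert flag_suspicious(a, g).similar_spacers

    def test_damaged_repeats_flagged_below_080(self, cfg):
        from crisprscan.synthbench import candidate_from_truth
        rng = np.random.default_rng(43)
        spec = PlantedArraySpec(
            repeat=random_dna(rng, 30), n_repeats=5,
            spacer_lengths=(35, 35, 35, 35),
            per_repeat_substitutions=(7, 7, 7, 7, 7), seed=43)
        g, truth = generate_positive(spec)
        a = candidate_from_truth(g, truth)
        assert flag_suspicious(a, g).damaged_repeats

    def test_uneven_spacer_boundary_arithmetic(self, rng):
        # {30,30,30,8}: 8 >= 0.3*24.5 -> not flagged; {30,30,30,6}: flagged
        def build(last):
            R = random_dna(rng, 30)
            parts, occs, pos = [], [], 0
            for i, L in enumerate([30, 30, 30, last]):
                parts.append(R)
                occs.append(Occurrence(pos, pos + 30, 0, 0, 0))
                pos += 30
                parts.append(random_dna(rng, L))
                pos += L
            parts.append(R)
            occs.append(Occurrence(pos, pos + 30, 0, 0, 0))
            pos += 30
            g = make_genome("".join(parts))
            return ArrayCandidate(genome_id="g", repeat_variant=R,
                                  occurrences=tuple(occs)), g
        a8, g8 = build(8)
        assert not flag_suspicious(a8, g8).uneven_spacer_lengths
        a6, g6 = build(6)
        assert flag_suspicious(a6, g6).uneven_spacer_lengths

    def test_any_is_or_of_flags(self, cfg):
        a, g = self._planted_candidate(47, cfg)
        rep = flag_suspicious(a, g)
        assert rep.any == (rep.similar_spacers or rep.damaged_repeats
                           or rep.repeat_spacer_similarity
                           or rep.uneven_spacer_lengths)
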