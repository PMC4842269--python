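import numpy as np
import pytest

from tssmapper.categorizer import CategoryAssignment
from tssmapper.io_formats import CoverageTrack, LibraryMeta
from tssmapper.peakcalling import Peak, TSSCandidate
from tssmapper.tss_svm import (ConditionScored, ScoredTSS, SvmConfig,
                               TrainingSet, assign_confidence, extract_features,
                               filter_internal_tss, merge_conditions,
                               score_candidates, train_classifier)


def _candidate(pos=1000, strand="+", minus_pos=None, plus_h=50.0, minus_h=5.0):
    minus_pos = pos if minus_pos is None else minus_pos
    plus = Peak("chr", strand, "Free", "TEXplus", pos, plus_h, 5.0)
    minus = Peak("chr", strand, "Free", "TEXminus", minus_pos, minus_h, 1.0)
    return TSSCandidate("chr", strand, "Free", pos, plus, minus)


def _tracks(L=2100, plus_starts=None, minus_starts=None):
    ps = np.zeros(L) if plus_starts is None else plus_starts
    ms = np.zeros(L) if minus_starts is None else minus_starts
    return (CoverageTrack("chr", LibraryMeta("Free", "TEXplus", "+"), ps),
            CoverageTrack("chr", LibraryMeta("Free", "TEXminus", "+"), ms))


class TestFeatures:
    def test_ratio_uses_pseudocount_when_minus_empty(self):
        plus, minus = _tracks()
        f = extract_features(_candidate(plus_h=50.0, minus_h=0.0), plus, minus)
        assert f[2] == pytest.approx(51.0)  # (50+1)/(0+1)

    def test_pair_distance_feature(self):
        plus, minus = _tracks()
        f = extract_features(_candidate(pos=1000, minus_pos=1002), plus, minus)
        assert f[9] == 2

    def test_read_start_radius_sum_matches_loop_oracle(self):
        ps = np.zeros(2100)
        ps[998:1001] = 10  # 1-based positions 999..1001
        plus, minus = _tracks(plus_starts=ps)
        f = extract_features(_candidate(pos=1000), plus, minus)
        oracle = sum(ps[i] for i in range(len(ps)) if abs((i + 1) - 1000) <= 4)
        assert f[7] == oracle == 30

    def test_coverage_window_mean(self):
        cov = np.zeros(2100)
        cov[984:1014] = 60  # the centred [-15,+14] window around position 1000
        plus, minus = _tracks()
        plus.coverage = cov
        f = extract_features(_candidate(pos=1000), plus, minus)
        assert f[3] == pytest.approx(60.0)


def _separable_training(n=40, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.normal(100, 10, n), rng.normal(20, 2, n),
                           rng.normal(20, 2, n)] + [rng.normal(5, 1, n)] * 7)
    neg = np.column_stack([rng.normal(3, 1, n), rng.normal(3, 1, n),
                           rng.normal(1, 0.2, n)] + [rng.normal(5, 1, n)] * 7)
    X = np.vstack([pos, neg])
    y = np.array([1] * n + [0] * n)
    return TrainingSet(X, y, "Free")


class TestTraining:
    def test_separable_set_reaches_perfect_training_accuracy(self):
        train = _separable_training()
        model = train_classifier(train, SvmConfig(seed=0))
        scores = score_candidates(model, train.X)
        assert np.all((scores > 0) == (train.y == 1))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 10))
        with pytest.raises(ValueError, match="positive and negative"):
            train_classifier(TrainingSet(X, np.ones(20, dtype=int), "Free"))

    def test_training_is_deterministic_given_seed(self):
        train = _separable_training()
        m1 = train_classifier(train, SvmConfig(seed=7))
        m2 = train_classifier(train, SvmConfig(seed=7))
        probe = np.random.default_rng(1).normal(5, 3, size=(30, 10))
        assert np.array_equal(score_candidates(m1, probe), score_candidates(m2, probe))

    def test_scores_are_finite_everywhere(self):
        model = train_classifier(_separable_training(), SvmConfig(seed=0))
        probe = np.zeros((1, 10))
        assert np.isfinite(score_candidates(model, probe)).all()

    def test_feature_length_mismatch_rejected(self):
        model = train_classifier(_separable_training(), SvmConfig(seed=0))
        with pytest.raises(ValueError, match="expected"):
            score_candidates(model, np.zeros((3, 7)))


def _cs(cond, pos, score=1.0, strand="+", ratio=5.0, height=50.0):
    return ConditionScored("chr", strand, cond, pos, score, height, ratio)


class TestMerging:
    def test_close_pair_merges_at_rounded_mean(self):
        out = merge_conditions([_cs("Free", 1000)], [_cs("Nod", 1002)])
        assert len(out) == 1
        assert out[0].position == 1001
        assert out[0].detected_in == {"Free", "Nod"}

    def test_half_tie_goes_to_three_prime_coordinate(self):
        out = merge_conditions([_cs("Free", 1000)], [_cs("Nod", 1001)])
        assert out[0].position == 1001  # 3' on the plus strand
        out = merge_conditions([_cs("Free", 1000, strand="-")],
                               [_cs("Nod", 1001, strand="-")])
        assert out[0].position == 1000  # 3' on the minus strand

    def test_separation_three_stays_separate(self):
        out = merge_conditions([_cs("Free", 1000)], [_cs("Nod", 1003)])
        assert sorted(t.position for t in out) == [1000, 1003]
        assert all(len(t.detected_in) == 1 for t in out)

    def test_symmetric_in_condition_arguments(self):
        for strand in "+-":
            for off in range(6):
                a = merge_conditions([_cs("Free", 1000, strand=strand)],
                                     [_cs("Nod", 1000 + off, strand=strand)])
                b = merge_conditions([_cs("Free", 1000 + off, strand=strand)],
                                     [_cs("Nod", 1000, strand=strand)])
                assert sorted(t.position for t in a) == sorted(t.position for t in b)

    def test_retention_requires_a_positive_score(self):
        out = merge_conditions([_cs("Free", 1000, score=-0.5)],
                               [_cs("Nod", 1001, score=-0.1)])
        assert out == []
        out = merge_conditions([_cs("Free", 1000, score=-0.5)],
                               [_cs("Nod", 1001, score=0.1)])
        assert len(out) == 1
        assert all(any(s is not None and s > 0 for s in (t.score_free, t.score_nod))
                   for t in out)

    def test_wrong_condition_lists_rejected(self):
        with pytest.raises(ValueError, match="non-Free"):
            merge_conditions([_cs("Nod", 10)], [])


def _scored_tss(pos, cats, ratio_free=None, ratio_nod=None, strand="+"):
    return ScoredTSS(id=f"t{pos}", replicon_id="chr", strand=strand, position=pos,
                     score_free=1.0 if ratio_free is not None else None,
                     score_nod=1.0 if ratio_nod is not None else None,
                     ratio_free=ratio_free, ratio_nod=ratio_nod,
                     detected_in={"Free"} if ratio_free is not None else {"Nod"},
                     categories=cats)


class TestInternalFilter:
    def test_itss_with_higher_ratio_retained(self):
        g = _scored_tss(100, [CategoryAssignment("gTSS", "geneA", 30)], ratio_free=5.0)
        i = _scored_tss(500, [CategoryAssignment("iTSS", "geneA", 370)], ratio_free=6.0)
        assert len(filter_internal_tss([g, i])) == 2

    def test_itss_with_lower_ratio_dropped(self):
        g = _scored_tss(100, [CategoryAssignment("gTSS", "geneA", 30)], ratio_free=5.0)
        i = _scored_tss(500, [CategoryAssignment("iTSS", "geneA", 370)], ratio_free=4.0)
        kept = filter_internal_tss([g, i])
        assert [t.position for t in kept] == [100]

    def test_itss_in_gene_without_gtss_passes(self):
        i = _scored_tss(500, [CategoryAssignment("iTSS", "geneB", 370)], ratio_free=0.2)
        assert len(filter_internal_tss([i])) == 1

    def test_cross_condition_fallback(self):
        # gene's gTSS scored only in Nod, iTSS only in Free: best ratios compared
        g = _scored_tss(100, [CategoryAssignment("gTSS", "geneA", 30)], ratio_nod=5.0)
        weak = _scored_tss(500, [CategoryAssignment("iTSS", "geneA", 370)], ratio_free=4.0)
        strong = _scored_tss(600, [CategoryAssignment("iTSS", "geneA", 470)], ratio_free=9.0)
        kept = filter_internal_tss([g, weak, strong])
        assert sorted(t.position for t in kept) == [100, 600]

    def test_never_removes_non_itss_records(self):
        g = _scored_tss(100, [CategoryAssignment("gTSS", "geneA", 30)], ratio_free=9.0)
        records = [
            g,
            _scored_tss(200, [CategoryAssignment("aTSS_i", "geneA", 100)],
                        ratio_free=0.1, strand="-"),
            _scored_tss(900, [CategoryAssignment("oTSS", None, None)], ratio_free=0.1),
            _scored_tss(300, [CategoryAssignment("iTSS", "geneA", 200),
                              CategoryAssignment("gTSS", "geneB", 50)], ratio_free=0.1),
        ]
        kept = filter_internal_tss(records)
        assert sorted(t.position for t in kept) == [100, 200, 300, 900]
        # the failing iTSS assignment itself is removed, the record survives
        t300 = next(t for t in kept if t.position == 300)
        assert {a.category for a in t300.categories} == {"gTSS"}


class TestConfidence:
    def test_below_cutoff_is_low(self):
        t = _scored_tss(10, [], ratio_free=1.0)
        t.score_free = 0.39
        assert assign_confidence(t).confidence == "low"

    def test_at_cutoff_is_high(self):
        t = _scored_tss(10, [], ratio_free=1.0)
        t.score_free = 0.40
        assert assign_confidence(t).confidence == "high"

    def test_max_rule_over_conditions(self):
        t = _scored_tss(10, [], ratio_free=1.0, ratio_nod=1.0)
        t.score_free, t.score_nod = 0.1, 3.1
        assert assign_confidence(t).confidence == "high"

    def test_all_na_scores_rejected(self):
        t = ScoredTSS(id="x", replicon_id="chr", strand="+", position=5)
        with pytest.raises(ValueError, match="NA"):
            assign_confidence(t)
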