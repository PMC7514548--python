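"""Metric formulas, confidence intervals and the leave-one-subject-out harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from capscore.errors import ProtocolViolationError
from capscore.evaluation import (
    ConfusionCounts, SubjectData, auc, basic_metrics, ci95, confusion, dor,
    dor_from_counts, loo_evaluate,
)
from capscore.networks.estimators import LSTMPhaseClassifier


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.FP, c.FN) == (0, 0) and c.total == 3

    def test_inverted_prediction(self):
        c = confusion([1, 0], [0, 1])
        assert (c.TP, c.TN) == (0, 0)

    def test_hand_count(self):
        c = confusion([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 1, 1)

    def test_excluded_epochs_removed(self):
        c = confusion([1, 1, 0], [1, 0, 0], exclude=[False, True, False])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1, 0, 1])


class TestBasicMetrics:
    def test_hand_worked_table(self):
        m = basic_metrics(ConfusionCounts(TP=3, FN=1, FP=2, TN=4))
        assert m.Sen == pytest.approx(0.75)
        assert m.Spe == pytest.approx(2 / 3)
        assert m.Acc == pytest.approx(0.7)
        assert m.PPV == pytest.approx(0.6)
        assert m.NPV == pytest.approx(0.8)

    def test_perfect_counts(self):
        m = basic_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert all(getattr(m, k) == 1.0 for k in
                   ("Acc", "Sen", "Spe", "PPV", "NPV"))

    def test_empty_positive_class_marker(self):
        m = basic_metrics(ConfusionCounts(TP=0, FN=0, FP=1, TN=3))
        assert np.isnan(m.Sen)

    def test_accuracy_prevalence_identity(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 40, 4)
            c = ConfusionCounts(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn))
            m = basic_metrics(c)
            p = (c.TP + c.FN) / c.total
            assert m.Acc == pytest.approx(p * m.Sen + (1 - p) * m.Spe)


class TestDOR:
    def test_chance_level_is_one(self):
        assert dor(0.5, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("sen,spe,expected", [
        (0.746, 0.766, 9.61),   # phase detector, LSTM
        (0.714, 0.842, 13.30),  # cycle detector, LSTM + rule engine
    ])
    def test_reported_operating_points(self, sen, spe, expected):
        assert round(dor(sen, spe), 2) == expected

    def test_count_form_equals_prevalence_free_form(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, 4))
            c = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
            m = basic_metrics(c)
            assert dor(m.Sen, m.Spe) == pytest.approx(dor_from_counts(c),
                                                      rel=1e-12)

    def test_boundary_marker(self):
        assert np.isinf(dor(0.5, 1.0))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 1)  # force ties
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                continue
            pos, neg = scores[truth == 1], scores[truth == 0]
            brute = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ])
            assert abs(auc(scores, truth) - brute) < 1e-12

    @given(st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, power):
        rng = np.random.default_rng(power)
        scores = rng.random(60)
        truth = rng.integers(0, 2, 60)
        transformed = np.exp(power * scores)
        assert auc(scores, truth) == pytest.approx(auc(transformed, truth),
                                                   abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestCI:
    def test_constant_values_zero_width(self):
        e = ci95([2.0, 2.0, 2.0])
        assert e.mean == e.lower95 == e.upper95 == 2.0

    def test_closed_form_t_interval(self):
        e = ci95([1.0, 2.0, 3.0])
        half = stats.t.ppf(0.975, 2) * 1.0 / np.sqrt(3)
        assert e.mean == pytest.approx(2.0)
        assert e.upper95 - e.mean == pytest.approx(half)

    def test_interval_contains_mean(self, rng):
        vals = rng.normal(size=10)
        e = ci95(vals)
        assert e.lower95 <= e.mean <= e.upper95

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            ci95([1.0])


class TestLeaveOneSubjectOut:
    def _factory(self, seed):
        return LSTMPhaseClassifier(cells=16, dense_units=8, context_length=20,
                                   n_passes=30, learning_rate=3e-3, seed=seed)

    def test_separable_subjects_high_auc(self, small_corpus):
        result = loo_evaluate(small_corpus, self._factory, n_repeats=2,
                              base_seed=0)
        for m in result.per_subject_phase.values():
            assert m.AUC > 0.9

    def test_metrics_averaged_over_repeats(self, small_corpus):
        # per-subject value equals the mean of per-repeat metrics, not a
        # pooled-count recomputation
        from capscore.evaluation import evaluate_subject

        held = small_corpus[0]
        train = small_corpus[1:]
        x = np.concatenate([d.epochs for d in train])
        y = np.concatenate([d.phase_labels for d in train])
        accs = []
        for rep in range(2):
            est = self._factory(seed=0 + rep).fit(x, y)
            pm, _ = evaluate_subject(est, held)
            accs.append(pm.Acc)
        result = loo_evaluate(small_corpus, self._factory, n_repeats=2,
                              base_seed=0)
        assert result.per_subject_phase[held.subject_id].Acc == pytest.approx(
            np.mean(accs))

    def test_duplicate_subject_rejected(self, small_corpus):
        bad = [small_corpus[0], small_corpus[0]]
        with pytest.raises(ProtocolViolationError):
            loo_evaluate(bad, self._factory, n_repeats=1)

    def test_fewer_than_two_subjects_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            loo_evaluate(small_corpus[:1], self._factory, n_repeats=1)

    def test_summary_frame_shape(self, small_corpus):
        result = loo_evaluate(small_corpus, self._factory, n_repeats=1,
                              base_seed=3)
        frame = result.summary_frame()
        assert set(frame.columns) == {"stage", "metric", "mean", "lower95",
                                      "upper95"}
        assert set(frame["stage"]) == {"phase", "cycle"}
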