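"""Tests of the ROC/geometric-mean threshold classifier and voting rules."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from cdktrace import (PROLIFERATIVE, QUIESCENT, CoverageError,
                      DegenerateLabelsError, InputError, StratificationError,
                      TimepointRoc, TraceClassifier, TraceSet, TrainingError,
                      accuracy_vs_time, classify_trace, evaluate,
                      fit_classifier, roc_at_timepoint, train_test_split)
from conftest import make_trace


def pair_count_auc(pos, neg):
    """Brute-force oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def labels_for(pos, neg):
    return (np.concatenate([pos, neg]),
            np.array([PROLIFERATIVE] * len(pos) + [QUIESCENT] * len(neg)))


class TestRocAtTimepoint:
    def test_perfectly_separable(self):
        ratios, labels = labels_for([0.80, 0.90], [0.10, 0.12])
        roc = roc_at_timepoint(ratios, labels)
        assert roc.auc == 1.0
        assert roc.chosen_gmean == 1.0
        assert 0.12 <= roc.chosen_threshold < 0.80

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(2, 11))
        n_neg = int(rng.integers(2, 21 - n_pos))
        # quantize to force ties
        pos = np.round(rng.random(n_pos), 1)
        neg = np.round(rng.random(n_neg), 1)
        ratios, labels = labels_for(pos, neg)
        roc = roc_at_timepoint(ratios, labels)
        assert roc.auc == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)
        # independent library cross-check
        assert roc.auc == pytest.approx(
            roc_auc_score(labels == PROLIFERATIVE, ratios), abs=1e-12)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(3)
        ratios = rng.random(500)
        labels = np.array([PROLIFERATIVE, QUIESCENT] * 250)
        rng.shuffle(labels)
        roc = roc_at_timepoint(ratios, labels)
        assert 0.45 <= roc.auc <= 0.55

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            roc_at_timepoint([0.1, 0.2], [QUIESCENT, QUIESCENT])

    def test_chosen_threshold_rank_invariant(self):
        # a strictly monotone transform maps the chosen cutoff along with it
        rng = np.random.default_rng(5)
        ratios, labels = labels_for(rng.random(8) + 0.3, rng.random(8))
        base = roc_at_timepoint(ratios, labels)
        trans = roc_at_timepoint(np.exp(ratios), labels)
        assert trans.auc == pytest.approx(base.auc, abs=1e-12)
        assert trans.chosen_gmean == pytest.approx(base.chosen_gmean, abs=1e-12)
        assert trans.chosen_threshold == pytest.approx(
            np.exp(base.chosen_threshold), rel=1e-12)

    def test_gmean_is_max_over_thresholds(self):
        rng = np.random.default_rng(8)
        ratios, labels = labels_for(rng.random(10) + 0.2, rng.random(10))
        roc = roc_at_timepoint(ratios, labels)
        gmeans = np.sqrt(roc.sensitivity * roc.specificity)
        assert roc.chosen_gmean == pytest.approx(gmeans.max())


class TestFitClassifier:
    def test_auc_grows_with_time(self, default_traces):
        clf = fit_classifier(default_traces)
        grid = clf.timepoints
        early = grid[(grid >= 5) & (grid <= 60)]
        aucs = [clf.per_timepoint[t].auc for t in early]
        rho = sps.spearmanr(early, aucs).statistic
        assert rho >= 0

    def test_single_class_training_raises(self, default_traces):
        with pytest.raises(TrainingError):
            fit_classifier(default_traces.subset(QUIESCENT))

    def test_fitting_is_deterministic(self, default_traces):
        a = fit_classifier(default_traces)
        b = fit_classifier(default_traces)
        assert a.to_json() == b.to_json()

    def test_json_round_trip(self, default_traces):
        clf = fit_classifier(default_traces)
        clone = TraceClassifier.from_json(clf.to_json())
        assert clone.timepoints.tolist() == clf.timepoints.tolist()
        for t in clf.timepoints:
            assert (clone.per_timepoint[t].chosen_threshold
                    == clf.per_timepoint[t].chosen_threshold)
            assert clone.per_timepoint[t].auc == clf.per_timepoint[t].auc


def toy_classifier(threshold=0.3, times=np.arange(0, 125, 5.0)):
    per = {float(t): TimepointRoc(
        time_min=float(t), thresholds=np.array([]), sensitivity=np.array([]),
        specificity=np.array([]), auc=1.0, chosen_threshold=threshold,
        chosen_gmean=1.0, n_pos=5, n_neg=5) for t in times}
    return TraceClassifier(per_timepoint=per, sample_interval_min=5.0)


class TestClassifyTrace:
    def test_long_trace_unanimous_low_votes(self):
        times = np.arange(0, 95, 5.0)
        trace = make_trace(times, np.full(times.size, 0.1), fate=QUIESCENT)
        fate, votes = classify_trace(trace, toy_classifier())
        assert fate == QUIESCENT
        assert all(v.fate == QUIESCENT for v in votes)

    def test_long_trace_uses_only_post_60_samples(self):
        times = np.arange(0, 95, 5.0)
        # poison everything at or before 60 min: high ratios would vote
        # proliferative, but the post-60 samples are all low
        ratios = np.where(times <= 60, 0.9, 0.1)
        trace = make_trace(times, ratios)
        fate, votes = classify_trace(trace, toy_classifier())
        assert fate == QUIESCENT
        assert all(v.time_min > 60 for v in votes)

    def test_short_trace_majority_of_last_three(self):
        times = np.arange(0, 50, 5.0)  # ends at 45 min
        ratios = np.full(times.size, 0.1)
        ratios[-3:] = [0.9, 0.9, 0.1]  # votes P, P, Q
        fate, votes = classify_trace(make_trace(times, ratios), toy_classifier())
        assert len(votes) == 3
        assert fate == PROLIFERATIVE

    def test_even_split_broken_by_latest_vote(self):
        times = np.arange(0, 85, 5.0)  # post-60 samples: 65,70,75,80
        ratios = np.full(times.size, 0.1)
        ratios[times == 65] = 0.9
        ratios[times == 80] = 0.9  # 2-2 split, latest vote proliferative
        fate, _ = classify_trace(make_trace(times, ratios), toy_classifier())
        assert fate == PROLIFERATIVE

    def test_boundary_vote_goes_quiescent(self):
        times = np.arange(0, 50, 5.0)
        ratios = np.full(times.size, 0.3)  # exactly at threshold
        fate, votes = classify_trace(make_trace(times, ratios), toy_classifier())
        assert fate == QUIESCENT

    def test_short_trace_below_20_min_raises(self):
        t = make_trace(np.arange(0, 20, 5.0), np.full(4, 0.1))  # ends at 15
        with pytest.raises(CoverageError):
            classify_trace(t, toy_classifier())

    def test_missing_trained_timepoint_raises(self):
        clf = toy_classifier(times=np.arange(0, 35, 5.0))  # trained to 30 min
        t = make_trace(np.arange(0, 95, 5.0), np.full(19, 0.1))
        with pytest.raises(CoverageError):
            classify_trace(t, clf)


class TestSplitAndEvaluate:
    def test_stratified_75_25(self, default_traces):
        train, test = train_test_split(default_traces, 0.75, seed=0)
        assert len(train) == 150 and len(test) == 50
        for part in (train, test):
            assert set(part.fates) == {PROLIFERATIVE, QUIESCENT}

    def test_split_seeded(self, default_traces):
        a1, b1 = train_test_split(default_traces, 0.75, seed=7)
        a2, b2 = train_test_split(default_traces, 0.75, seed=7)
        assert [t.cell_id for t in a1] == [t.cell_id for t in a2]
        assert [t.cell_id for t in b1] == [t.cell_id for t in b2]

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_bad_fraction_raises(self, default_traces, frac):
        with pytest.raises(InputError):
            train_test_split(default_traces, frac, seed=0)

    def test_tiny_class_raises(self):
        ts = TraceSet([make_trace([0, 5, 10], [0.1] * 3, cell_id=f"q{i}",
                                  fate=QUIESCENT) for i in range(5)]
                      + [make_trace([0, 5, 10], [0.9] * 3, cell_id="p0",
                                    fate=PROLIFERATIVE)])
        with pytest.raises(StratificationError):
            train_test_split(ts, 0.75, seed=0)

    def test_separable_train_equals_test_accuracy_one(self, separable_pair):
        high, low = separable_pair
        ts = TraceSet(list(high) + list(low))
        clf = fit_classifier(ts)
        report = evaluate(clf, ts)
        assert report.accuracy == 1.0
        assert sum(report.confusion.values()) == report.n_traces

    def test_single_trace_report(self, separable_pair):
        high, low = separable_pair
        clf = fit_classifier(TraceSet(list(high) + list(low)))
        report = evaluate(clf, TraceSet([high[0]]))
        assert report.n_traces == 1
        assert report.confusion == {(PROLIFERATIVE, PROLIFERATIVE): 1}

    def test_too_short_traces_skipped_not_counted(self, separable_pair):
        high, low = separable_pair
        clf = fit_classifier(TraceSet(list(high) + list(low)))
        short = make_trace([0, 5, 10], [0.9, 0.9, 0.9], cell_id="s",
                           fate=PROLIFERATIVE)
        report = evaluate(clf, TraceSet([high[0], short]))
        assert report.n_traces == 1
        assert [c for c, _ in report.skipped] == ["s"]

    def test_empty_test_raises(self, separable_pair):
        clf = fit_classifier(TraceSet(list(separable_pair[0])
                                      + list(separable_pair[1])))
        with pytest.raises(InputError):
            evaluate(clf, TraceSet([]))


class TestAccuracyVsTime:
    def test_separable_accuracy_one_everywhere(self, separable_pair):
        high, low = separable_pair
        ts = TraceSet(list(high) + list(low))
        clf = fit_classifier(ts)
        table = accuracy_vs_time(clf, ts)
        assert (table["accuracy"] == 1.0).all()
        assert (table["auc"] == 1.0).all()

    def test_accuracy_non_decreasing_with_time(self, default_traces):
        train, test = train_test_split(default_traces, 0.75, seed=1)
        clf = fit_classifier(train)
        table = accuracy_vs_time(clf, test)
        sub = table[table["time_min"] <= 60]
        rho = sps.spearmanr(sub["time_min"], sub["accuracy"]).statistic
        assert rho >= 0

    def test_untested_timepoint_omitted(self, separable_pair):
        high, low = separable_pair
        clf = fit_classifier(TraceSet(list(high) + list(low)))
        short = TraceSet([make_trace([0, 5, 10, 15, 20, 25], [0.9] * 6,
                                     fate=PROLIFERATIVE)])
        table = accuracy_vs_time(clf, short)
        assert table["time_min"].max() == 25.0
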