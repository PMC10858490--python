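import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phenorare.evaluation import (
    RankedList,
    aggregate,
    auroc_auprc,
    evaluate_scores,
    recall_precision_at_k,
    sensitivity_at_threshold,
    specificity_at_threshold,
    threshold_at_specificity,
)


def pairwise_auroc(scores, labels):
    """Mann-Whitney oracle: P(case > control) + 0.5 P(tie)."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    ctrls = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return wins / (len(cases) * len(ctrls))


def stepwise_auprc(scores, labels):
    """Average precision oracle: sum of (delta recall) x precision over the
    distinct score thresholds, descending; tied scores enter together."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    total_cases = y.sum()
    tp = seen = 0
    ap = prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        group = scores == t
        tp += y[group].sum()
        seen += group.sum()
        recall = tp / total_cases
        ap += (recall - prev_recall) * (tp / seen)
        prev_recall = recall
    return ap


class TestThreshold:
    def test_ten_order_statistics(self):
        controls = [i / 10 for i in range(10)]
        t = threshold_at_specificity(controls, 0.90)
        assert t == 0.8
        assert specificity_at_threshold(controls, t) == 0.9

    def test_tied_controls_give_specificity_one(self):
        t = threshold_at_specificity([0.3] * 8, 0.90)
        assert t == 0.3
        assert specificity_at_threshold([0.3] * 8, t) == 1.0

    def test_half_specificity(self):
        assert threshold_at_specificity([1, 2, 3, 4], 0.5) == 2

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            threshold_at_specificity([], 0.9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200),
           st.floats(0.05, 0.95))
    def test_achieved_specificity_never_below_target(self, controls, target):
        t = threshold_at_specificity(controls, target)
        assert specificity_at_threshold(controls, t) >= target - 1e-6

    def test_calibration_tight_on_large_control_sets(self):
        """On 1,000+ controls the overshoot is at most one order statistic."""
        rng = np.random.default_rng(0)
        for n in (1000, 5000):
            controls = rng.random(n)
            t = threshold_at_specificity(controls, 0.90)
            achieved = specificity_at_threshold(controls, t)
            assert 0.90 <= achieved <= 0.90 + 1.0 / n + 1e-12


class TestSensitivity:
    @pytest.mark.parametrize(
        "cases,t,expected",
        [([0.9, 0.8], 0.5, 1.0), ([0.1, 0.2], 0.5, 0.0)],
    )
    def test_boundaries(self, cases, t, expected):
        assert sensitivity_at_threshold(cases, t) == expected

    def test_18_of_30_cases_above(self):
        cases = [0.9] * 18 + [0.1] * 12
        assert sensitivity_at_threshold(cases, 0.5) == pytest.approx(0.6)


class TestTopK:
    def make_perfect(self, n_cases, n_controls):
        scores = {f"case{i}": 1000.0 - i for i in range(n_cases)}
        scores.update({f"ctrl{i}": -float(i) for i in range(n_controls)})
        labels = {pid: 1 if pid.startswith("case") else 0 for pid in scores}
        return RankedList.from_scores(scores), labels

    def test_perfect_ranking_study_scale(self):
        ranked, labels = self.make_perfect(30, 7231)
        recall, precision = recall_precision_at_k(ranked, labels, 1.0)
        assert recall == 1.0
        assert precision == pytest.approx(30 / 73)  # m = round(0.01 * 7261) = 73

    def test_k_100_percent_gives_prevalence(self):
        ranked, labels = self.make_perfect(30, 7231)
        recall, precision = recall_precision_at_k(ranked, labels, 100.0)
        assert recall == 1.0
        assert precision == pytest.approx(30 / 7261)

    def test_precision_recall_identity(self):
        """precision@k = recall@k * n_cases / m for any ranking."""
        rng = np.random.default_rng(2)
        scores = {f"p{i}": float(rng.random()) for i in range(500)}
        labels = {pid: int(rng.random() < 0.1) for pid in scores}
        ranked = RankedList.from_scores(scores)
        n_cases = sum(labels.values())
        for k in (1.0, 5.0, 10.0, 50.0):
            m = max(1, round(k / 100 * len(ranked)))
            recall, precision = recall_precision_at_k(ranked, labels, k)
            assert precision == pytest.approx(recall * n_cases / m)

    def test_ties_broken_by_patient_id(self):
        ranked = RankedList.from_scores({"b": 1.0, "a": 1.0, "c": 0.5})
        assert ranked.patient_ids == ("a", "b", "c")

    def test_missing_labels_are_a_contract_error(self):
        ranked = RankedList.from_scores({"a": 1.0})
        with pytest.raises(ValueError, match="missing"):
            recall_precision_at_k(ranked, {}, 10.0)


class TestAurocAuprc:
    def test_perfect_separation(self):
        assert auroc_auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == (1.0, 1.0)

    def test_case_between_two_controls(self):
        auroc, _ = auroc_auprc([3, 2, 1], [0, 1, 0])
        assert auroc == 0.5

    def test_against_pairwise_and_stepwise_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            scores = rng.integers(0, 10, size=60).astype(float)  # ties likely
            labels = rng.integers(0, 2, size=60)
            if len(set(labels)) < 2:
                continue
            auroc, auprc = auroc_auprc(scores, labels)
            assert auroc == pytest.approx(pairwise_auroc(scores, labels))
            assert auprc == pytest.approx(stepwise_auprc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_auprc([0.1, 0.2], [1, 1])


class TestAggregate:
    def test_identical_values_give_degenerate_ci(self):
        agg = aggregate([{"auroc": 0.7}] * 10)
        assert agg["auroc"]["mean"] == pytest.approx(0.7)
        assert agg["auroc"]["ci95"] == pytest.approx([0.7, 0.7])

    def test_symmetric_ci_for_balanced_values(self):
        agg = aggregate([{"auroc": 0.0}] * 5 + [{"auroc": 1.0}] * 5)
        mean = agg["auroc"]["mean"]
        lo, hi = agg["auroc"]["ci95"]
        assert mean == pytest.approx(0.5)
        assert hi - mean == pytest.approx(mean - lo)

    def test_closed_form_t_interval(self):
        vals = [{"auroc": 0.8}] * 5 + [{"auroc": 0.9}] * 5
        agg = aggregate(vals)
        sd = np.std([0.8] * 5 + [0.9] * 5, ddof=1)
        half = sps.t.ppf(0.975, 9) * sd / np.sqrt(10)
        assert half == pytest.approx(0.0377, abs=1e-4)
        lo, hi = agg["auroc"]["ci95"]
        assert hi - agg["auroc"]["mean"] == pytest.approx(half)

    def test_rate_cis_truncated_to_unit_interval(self):
        agg = aggregate([{"auprc": 0.01}, {"auprc": 0.9}, {"auprc": 0.95}])
        lo, hi = agg["auprc"]["ci95"]
        assert 0.0 <= lo <= hi <= 1.0


class TestMonotoneInvariance:
    def test_all_metrics_invariant_to_monotone_score_transforms(self):
        rng = np.random.default_rng(4)
        scores = {f"p{i}": float(rng.random()) for i in range(300)}
        labels = {pid: int(rng.random() < 0.05) for pid in scores}
        labels[max(scores)] = 1  # ensure both classes
        base = evaluate_scores(scores, labels)
        for transform in (lambda s: 2 * s + 1, np.exp, lambda s: s**3):
            warped = {pid: float(transform(s)) for pid, s in scores.items()}
            got = evaluate_scores(warped, labels)
            for key, value in base.items():
                if key == "threshold":
                    continue
                assert got[key] == pytest.approx(value), key
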