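import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murmurbench.metrics import (
    CostParameters,
    MurmurConfusion,
    OutcomeConfusion,
    UndefinedMetricError,
    cross_task_metrics,
    expert_mean_cost,
    expert_total_cost,
    metric_concordance,
    murmur_confusion,
    optimal_screening_fraction,
    outcome_confusion,
    outcome_cost,
    rank_entries,
    traditional_metrics,
    weighted_accuracy,
)
from murmurbench.types import ValidationError

from conftest import make_output, random_scored_cohort
from oracles import (
    naive_outcome_cost,
    naive_traditional,
    naive_weighted_accuracy,
)


class TestConfusions:
    def test_perfect_agreement_fills_diagonal(self):
        labels = {"a": "Present", "b": "Unknown", "c": "Absent", "d": "Absent"}
        outputs = [make_output(pid, murmur_class=lab) for pid, lab in labels.items()]
        m = murmur_confusion(labels, outputs).m
        assert np.array_equal(np.diag(m), [1, 1, 2]) and m.sum() == 4

    def test_hand_counted_five_patient_matrix(self):
        labels = dict(zip("abcde", ["Present", "Present", "Absent", "Absent", "Absent"]))
        preds = ["Present", "Absent", "Present", "Absent", "Absent"]
        outputs = [make_output(pid, murmur_class=p) for pid, p in zip("abcde", preds)]
        m = murmur_confusion(labels, outputs).m
        # rows = output, columns = label, order (Present, Unknown, Absent)
        expected = np.array([[1, 0, 1], [0, 0, 0], [1, 0, 2]])
        assert np.array_equal(m, expected)

    def test_empty_input_gives_zero_matrix(self):
        assert murmur_confusion({}, []).m.sum() == 0
        n = outcome_confusion({}, [])
        assert n.n_patients == 0

    def test_id_mismatch_lists_offenders(self):
        labels = {"a": "Absent", "b": "Absent"}
        with pytest.raises(ValidationError, match="'b'"):
            murmur_confusion(labels, [make_output("a"), make_output("c")])

    def test_outcome_counts(self):
        labels = {"a": "Abnormal", "b": "Abnormal", "c": "Normal", "d": "Normal"}
        preds = ["Abnormal", "Normal", "Abnormal", "Normal"]
        outputs = [make_output(p, outcome_class=c) for p, c in zip("abcd", preds)]
        n = outcome_confusion(labels, outputs)
        assert (n.n_TP, n.n_FN, n.n_FP, n.n_TN) == (1, 1, 1, 1)


class TestWeightedAccuracy:
    def test_perfect_classifier_scores_one(self):
        m = np.diag([10, 5, 85])
        assert weighted_accuracy(MurmurConfusion(m)) == 1.0

    def test_hand_evaluated_mixed_matrix(self):
        m = np.zeros((3, 3), dtype=int)
        m[0, 0] = 10  # m_PP
        m[2, 0] = 5   # m_AP
        m[2, 2] = 85  # m_AA
        assert weighted_accuracy(MurmurConfusion(m)) == pytest.approx(135 / 160, abs=1e-15)

    def test_always_absent_on_imbalanced_labels(self):
        m = np.zeros((3, 3), dtype=int)
        m[2, 0], m[2, 1], m[2, 2] = 15, 5, 80
        expected = 80 / (5 * 15 + 3 * 5 + 80)
        assert weighted_accuracy(MurmurConfusion(m)) == pytest.approx(expected, abs=1e-15)

    def test_empty_matrix_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            weighted_accuracy(MurmurConfusion(np.zeros((3, 3), dtype=int)))

    @given(st.lists(st.integers(0, 20), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_equal_weights_reduce_to_plain_accuracy(self, entries):
        m = np.asarray(entries).reshape(3, 3)
        if m.sum() == 0:
            return
        wa = weighted_accuracy(MurmurConfusion(m), weights=(1.0, 1.0, 1.0))
        assert wa == pytest.approx(np.trace(m) / m.sum(), abs=1e-12)


class TestCostModel:
    def test_expert_mean_cost_at_printed_points(self):
        assert expert_mean_cost(0.0) == 25.0
        assert expert_mean_cost(1.0) == pytest.approx(10_000.0, abs=1e-9)
        assert expert_mean_cost(0.25) == pytest.approx(61.0, abs=1e-9)

    def test_expert_mean_cost_domain(self):
        with pytest.raises(ValidationError):
            expert_mean_cost(-0.1)
        with pytest.raises(ValidationError):
            expert_mean_cost(1.1)

    def test_expert_total_cost(self):
        assert expert_total_cost(0, 100) == 2500.0
        assert expert_total_cost(30, 100) == pytest.approx(8097.76, abs=1e-9)
        for t in (1, 7, 100):
            assert expert_total_cost(t, t) / t == pytest.approx(10_000.0, abs=1e-9)
        with pytest.raises(ValidationError):
            expert_total_cost(5, 4)
        with pytest.raises(ValidationError):
            expert_total_cost(0, 0)

    def test_outcome_cost_hand_values(self):
        total, mean = outcome_cost(OutcomeConfusion(0, 0, 0, 100))
        assert (total, mean) == (pytest.approx(3500.0), pytest.approx(35.0))
        total, mean = outcome_cost(OutcomeConfusion(20, 10, 5, 65))
        assert total == pytest.approx(459_097.76, abs=1e-6)
        assert mean == pytest.approx(4590.9776, abs=1e-8)
        total, mean = outcome_cost(OutcomeConfusion(10, 0, 0, 0))
        assert mean == pytest.approx(20_010.0, abs=1e-9)

    def test_cost_monotone_in_errors_and_treatments(self):
        base = OutcomeConfusion(5, 5, 5, 50)
        more_fn = OutcomeConfusion(5, 5, 6, 50)
        more_tp = OutcomeConfusion(6, 5, 5, 50)
        assert outcome_cost(more_fn)[0] > outcome_cost(base)[0]
        assert outcome_cost(more_tp)[0] > outcome_cost(base)[0]

    def test_total_and_mean_differ_by_cohort_size(self):
        n = OutcomeConfusion(3, 7, 2, 13)
        total, mean = outcome_cost(n)
        assert total == pytest.approx(mean * n.n_patients, rel=1e-15)

    def test_empty_cohort_undefined(self):
        with pytest.raises(UndefinedMetricError):
            outcome_cost(OutcomeConfusion(0, 0, 0, 0))


class TestOptimalScreeningFraction:
    def test_default_parameters_give_one_quarter(self):
        res = optimal_screening_fraction()
        assert not res.boundary
        assert res.fraction == pytest.approx(0.25, abs=1e-4)

    def test_agrees_with_dense_grid_oracle(self):
        xs = np.arange(1e-5, 1.0 + 1e-5, 1e-5)
        c0, c1, c2, c4 = CostParameters().expert_poly
        values = c0 / xs + c1 + c2 * xs + c4 * xs**3
        oracle = xs[int(np.argmin(values))]
        assert optimal_screening_fraction().fraction == pytest.approx(oracle, abs=1e-4)

    def test_monotone_objective_hits_boundary_with_flag(self):
        res = optimal_screening_fraction(CostParameters(expert_poly=(25.0, 397.0, 0.0, 0.0)))
        assert res.boundary and res.fraction == pytest.approx(1.0, abs=1e-6)


class TestTraditionalMetrics:
    def test_perfect_separation_auroc_one(self):
        labels = {"a": "Abnormal", "b": "Normal"}
        outputs = [
            make_output("a", outcome_class="Abnormal", outcome_probs=(0.9, 0.1)),
            make_output("b", outcome_class="Normal", outcome_probs=(0.1, 0.9)),
        ]
        tm = traditional_metrics(labels, outputs, "outcome")
        assert tm.auroc == 1.0 and tm.accuracy == 1.0

    def test_constant_scores_give_half_auroc(self):
        labels = {"a": "Abnormal", "b": "Normal", "c": "Abnormal"}
        outputs = [make_output(p, outcome_class="Normal", outcome_probs=(0.4, 0.6))
                   for p in "abc"]
        assert traditional_metrics(labels, outputs, "outcome").auroc == 0.5

    def test_four_patient_pair_enumeration(self):
        labels = {"a": "Abnormal", "b": "Abnormal", "c": "Normal", "d": "Normal"}
        p_abn = {"a": 0.9, "b": 0.4, "c": 0.6, "d": 0.2}
        outputs = [
            make_output(pid, outcome_class="Abnormal" if p_abn[pid] > 0.5 else "Normal",
                        outcome_probs=(p_abn[pid], 1 - p_abn[pid]))
            for pid in "abcd"
        ]
        tm = traditional_metrics(labels, outputs, "outcome")
        assert tm.auroc == pytest.approx(3 / 4)
        # thresholding at 0.5 classifies a and d correctly, b and c wrongly
        assert tm.accuracy == pytest.approx(2 / 4)

    def test_absent_class_excluded_with_warning(self):
        labels = {"a": "Present", "b": "Absent"}  # no Unknown labels
        outputs = [make_output("a", murmur_class="Present"),
                   make_output("b", murmur_class="Absent")]
        with pytest.warns(UserWarning, match="Unknown"):
            tm = traditional_metrics(labels, outputs, "murmur")
        assert 0.0 <= tm.auroc <= 1.0

    def test_binary_auroc_matches_sklearn(self):
        from sklearn.metrics import average_precision_score, roc_auc_score
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.integers(0, 2, size=20)
            if y.sum() in (0, len(y)):
                continue
            s = np.round(rng.random(20), 1)
            labels = {f"P{i}": ("Abnormal" if v else "Normal") for i, v in enumerate(y)}
            outputs = [make_output(f"P{i}", outcome_probs=(float(s[i]), float(1 - s[i])))
                       for i in range(20)]
            tm = traditional_metrics(labels, outputs, "outcome")
            assert tm.auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            assert tm.auprc == pytest.approx(average_precision_score(y, s), abs=1e-12)


class TestOracleEquivalence:
    def test_random_small_cohorts_match_naive_reimplementation(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            murmur_labels, outcome_labels, outputs = random_scored_cohort(rng)
            wa = weighted_accuracy(murmur_confusion(murmur_labels, outputs))
            assert wa == pytest.approx(naive_weighted_accuracy(murmur_labels, outputs),
                                       abs=1e-12)
            total, mean = outcome_cost(outcome_confusion(outcome_labels, outputs))
            ntotal, nmean = naive_outcome_cost(outcome_labels, outputs)
            assert total == pytest.approx(ntotal, abs=1e-9)
            assert mean == pytest.approx(nmean, abs=1e-9)
            for task, labels in (("murmur", murmur_labels), ("outcome", outcome_labels)):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # class-exclusion warnings
                    tm = traditional_metrics(labels, outputs, task)
                for got, want in zip(tm, naive_traditional(labels, outputs, task)):
                    assert got == pytest.approx(want, abs=1e-12)


class TestCrossTaskVariants:
    def test_perfect_outcome_classifier_scores_one(self):
        labels = {"a": "Abnormal", "b": "Normal"}
        outputs = [make_output("a", outcome_class="Abnormal"),
                   make_output("b", outcome_class="Normal")]
        ct = cross_task_metrics({"a": "Absent", "b": "Absent"}, labels, outputs)
        assert ct.outcome_weighted_accuracy == 1.0

    def test_all_absent_murmur_cost(self):
        n = 100
        murmur_labels = {f"P{i}": ("Present" if i < 15 else "Unknown" if i < 20 else "Absent")
                         for i in range(n)}
        outcome_labels = {f"P{i}": "Normal" for i in range(n)}
        outputs = [make_output(f"P{i}", murmur_class="Absent") for i in range(n)]
        ct = cross_task_metrics(murmur_labels, outcome_labels, outputs)
        # 20 referral-positive labels all missed: 10*100 + 25*100 + 50000*20
        assert ct.murmur_mean_cost == pytest.approx(10_035.0, abs=1e-9)

    def test_all_abnormal_output_variant_accuracy(self):
        labels = {f"P{i}": ("Abnormal" if i < 48 else "Normal") for i in range(100)}
        outputs = [make_output(f"P{i}", outcome_class="Abnormal") for i in range(100)]
        ct = cross_task_metrics({p: "Absent" for p in labels}, labels, outputs)
        assert ct.outcome_weighted_accuracy == pytest.approx(5 * 48 / (5 * 48 + 52), abs=1e-12)


class TestRanking:
    def test_published_top_five_tie_pattern(self):
        assert rank_entries([0.780, 0.776, 0.776, 0.771, 0.767], "maximize") == [1, 2, 2, 4, 5]

    def test_strictly_decreasing_scores(self):
        assert rank_entries([5.0, 4.0, 3.0], "maximize") == [1, 2, 3]
        assert rank_entries([5.0, 4.0, 3.0], "minimize") == [3, 2, 1]

    def test_total_tie(self):
        assert rank_entries([1.0, 1.0, 1.0], "maximize") == [1, 1, 1]

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValidationError):
            rank_entries([1.0, float("nan")])
        with pytest.raises(ValidationError):
            rank_entries([])


class TestConcordance:
    def test_identity_and_reversal(self):
        a = [0.1, 0.5, 0.3, 0.9]
        rho, _ = metric_concordance(a, a)
        assert rho == pytest.approx(1.0)
        rho, _ = metric_concordance(a, [-x for x in a])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        rho, _ = metric_concordance([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_robust_line_recovers_clean_linear_trend(self):
        rng = np.random.default_rng(0)
        a = rng.random(30)
        b = 2.0 * a + 1.0
        _, line = metric_concordance(a, b)
        assert line.slope == pytest.approx(2.0, abs=1e-6)
        assert line.intercept == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points_undefined(self):
        with pytest.raises(UndefinedMetricError):
            metric_concordance([1, 2], [1, 2])
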