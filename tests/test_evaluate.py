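"""Metric formulas, kappa coefficients and summary statistics, checked
against hand arithmetic, brute-force tallies and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from kneetext.evaluate import (
    AgreementTable,
    ConfusionMatrix,
    class_metrics,
    cohen_kappa,
    f_measure,
    linear_weights,
    round_half_up,
    summarize,
    weighted_kappa,
    weighted_metrics,
)

TABLES = st.lists(
    st.integers(min_value=0, max_value=30), min_size=9, max_size=9
).map(lambda xs: np.array(xs).reshape(3, 3)).filter(lambda m: m.sum() > 0)


class TestClassMetrics:
    def test_direct_formula(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[3, 1], [1, 0]]))
        m = class_metrics(cm)[0]
        assert (m.precision, m.recall, m.f_measure) == (0.75, 0.75, 0.75)

    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(labels=[1, 2, 3], counts=np.diag([4, 5, 6]))
        for m in class_metrics(cm):
            assert m.precision == m.recall == m.f_measure == 1.0

    def test_never_predicted_class_flagged(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[0, 2], [0, 3]]))
        m = class_metrics(cm)[0]
        assert m.precision == 0.0 and m.degenerate_precision
        assert m.recall == 0.0

    def test_empty_matrix_is_hard_error(self):
        cm = ConfusionMatrix(labels=[1, 2])
        with pytest.raises(ValueError):
            class_metrics(cm)


class TestFMeasure:
    @pytest.mark.parametrize(
        "p,r,f", [(0.5, 0.5, 0.5), (1.0, 0.0, 0.0), (0.75, 0.75, 0.75)]
    )
    def test_harmonic_mean_and_degenerate_convention(self, p, r, f):
        assert f_measure(p, r) == pytest.approx(f)


class TestWeightedMetrics:
    def test_weighted_mean_by_support(self):
        # supports 10 and 30, precisions 0.8 and 0.6 -> 0.65
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[8, 2], [2, 28]]))
        # per-class precision: 8/10=0.8, 28/30=0.933... construct directly:
        ms = class_metrics(cm)
        supports = cm.supports / cm.total
        expected_p = sum(w * m.precision for w, m in zip(supports, ms))
        assert weighted_metrics(cm)[0] == pytest.approx(expected_p)

    def test_hand_value(self):
        assert 0.25 * 0.8 + 0.75 * 0.6 == pytest.approx(0.65)

    def test_uniform_supports_equal_macro_mean(self):
        cm = ConfusionMatrix(labels=[1, 2], counts=np.array([[7, 3], [4, 6]]))
        p, r, f = weighted_metrics(cm)
        ms = class_metrics(cm)
        assert p == pytest.approx(np.mean([m.precision for m in ms]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(TABLES)
    def test_matches_sklearn_weighted_average(self, counts):
        cm = ConfusionMatrix(labels=[1, 2, 3], counts=counts)
        y_true = np.repeat([1, 2, 3], counts.sum(axis=1))
        y_pred = np.concatenate(
            [np.repeat([1, 2, 3], row) for row in counts]
        )
        p, r, f = weighted_metrics(cm)
        sp, sr, sf, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0, labels=[1, 2, 3]
        )
        assert (p, r, f) == pytest.approx((sp, sr, sf))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(TABLES)
    def test_all_metrics_within_unit_interval(self, counts):
        cm = ConfusionMatrix(labels=[1, 2, 3], counts=counts)
        for m in class_metrics(cm):
            assert 0 <= m.precision <= 1 and 0 <= m.recall <= 1 and 0 <= m.f_measure <= 1
        assert all(0 <= v <= 1 for v in weighted_metrics(cm))


class TestKappa:
    def test_perfect_agreement(self):
        at = AgreementTable(labels=[1, 2, 3], counts=np.diag([5, 5, 5]))
        assert cohen_kappa(at) == pytest.approx(1.0)
        assert weighted_kappa(at, "linear") == pytest.approx(1.0)
        assert weighted_kappa(at, "quadratic") == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        at = AgreementTable(labels=[0, 1], counts=np.array([[20, 5], [10, 15]]))
        assert cohen_kappa(at) == pytest.approx(0.4)

    def test_constant_rater_gives_zero(self):
        # rater1 constant, rater2 uniform: p_o equals p_e
        at = AgreementTable(labels=[1, 2], counts=np.array([[10, 10], [0, 0]]))
        assert cohen_kappa(at) == pytest.approx(0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(TABLES.filter(lambda m: np.trace(m) < m.sum()))
    def test_identity_weights_reduce_to_cohen(self, counts):
        at = AgreementTable(labels=[1, 2, 3], counts=counts)
        try:
            k = cohen_kappa(at)
        except ValueError:
            return
        assert abs(weighted_kappa(at, "identity") - k) < 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(TABLES)
    def test_agrees_with_sklearn(self, counts):
        at = AgreementTable(labels=[1, 2, 3], counts=counts)
        y1 = np.repeat([1, 2, 3], counts.sum(axis=1))
        y2 = np.concatenate([np.repeat([1, 2, 3], row) for row in counts])
        if len(set(y1)) < 2 or len(set(y2.tolist()) | set(y1.tolist())) < 2:
            return
        try:
            ours = cohen_kappa(at)
            ours_lin = weighted_kappa(at, "linear")
        except ValueError:
            return
        assert ours == pytest.approx(cohen_kappa_score(y1, y2, labels=[1, 2, 3]))
        assert ours_lin == pytest.approx(
            cohen_kappa_score(y1, y2, labels=[1, 2, 3], weights="linear")
        )

    def test_adjacent_disagreements_score_higher_than_extreme(self):
        adjacent = AgreementTable(
            labels=[1, 2, 3], counts=np.array([[10, 5, 0], [0, 10, 0], [0, 0, 10]])
        )
        extreme = AgreementTable(
            labels=[1, 2, 3], counts=np.array([[10, 0, 5], [0, 10, 0], [0, 0, 10]])
        )
        assert weighted_kappa(adjacent, "linear") > weighted_kappa(extreme, "linear")
        # unweighted kappa cannot tell them apart in observed agreement
        assert np.trace(adjacent.counts) == np.trace(extreme.counts)

    def test_invalid_weight_matrix_rejected(self):
        at = AgreementTable(labels=[1, 2], counts=np.eye(2) * 5)
        with pytest.raises(ValueError):
            weighted_kappa(at, np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric

    def test_linear_weight_construction(self):
        w = linear_weights(3)
        assert w[0, 2] == pytest.approx(0.0)
        assert w[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(w), 1.0)


class TestSummarize:
    def test_single_value(self):
        rep = summarize([("Q3", 0.5, 0.6, 0.7)])
        assert rep.f_measure.mean == 0.7
        assert rep.f_measure.sd is None
        assert rep.f_measure.min == rep.f_measure.max == 0.7

    def test_equal_values_zero_sd(self):
        rep = summarize([("a", 0.5, 0.5, 0.5), ("b", 0.5, 0.5, 0.5)])
        assert rep.f_measure.sd == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rows = [("a", 0.1, 0.2, 0.3), ("b", 0.4, 0.5, 0.6), ("c", 0.7, 0.8, 0.9)]
        a = summarize(rows)
        b = summarize(rows[::-1])
        assert a.f_measure == b.f_measure and a.precision == b.precision

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_rounding_half_up(self):
        assert round_half_up(74.35, 1) == 74.4
        assert round_half_up(8.849999, 1) == 8.8
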