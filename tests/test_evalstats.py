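"""Evaluation statistics: matrices, exact CIs, pooling, kappa, reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from unlatem import (
    ConfusionMatrix,
    clopper_pearson,
    cohen_kappa,
    confusion,
    haldane_anscombe,
    metrics_from_matrix,
    pool_inverse_variance,
    reconstruct_matrix,
)

from conftest import SUMMARY_ROWS


class TestConfusion:
    def test_cell_definitions(self):
        m = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert m.as_tuple() == (1, 1, 1, 1)

    def test_identical_vectors_have_no_errors(self):
        m = confusion([1, 0, 1], [1, 0, 1])
        assert (m.fp, m.fn) == (0, 0)

    def test_all_negative(self):
        assert confusion([0] * 10, [0] * 10).tn == 10

    def test_length_mismatch_is_usage_error(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariant(self, pairs):
        gold, pred = zip(*pairs)
        m1 = confusion(gold, pred)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pairs))
        m2 = confusion(np.array(gold)[perm], np.array(pred)[perm])
        assert m1 == m2


class TestMetricsFromMatrix:
    def test_published_laterality_row(self):
        # 248 true and 7 false laterality flags among 980 internal records
        met = metrics_from_matrix(ConfusionMatrix(tp=248, fp=7, fn=0, tn=725))
        assert met.recall.point == 1.0
        assert round(100 * met.specificity.point, 1) == 99.0
        assert round(100 * met.precision.point, 1) == 97.3
        assert round(100 * met.actual_prevalence.point, 1) == 25.3
        # perfect-recall exact lower bound: 0.025^(1/248) = 98.5%
        assert round(100 * met.recall.lower, 1) == 98.5
        assert round(100 * met.actual_prevalence.lower, 1) == 22.6
        assert round(100 * met.actual_prevalence.upper, 1) == 28.2

    def test_zero_denominator_is_undefined_not_zero(self):
        met = metrics_from_matrix(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert met.recall is None
        assert met.precision is None
        assert met.specificity.point == 1.0

    def test_point_estimates_inside_ci(self):
        met = metrics_from_matrix(ConfusionMatrix(tp=9, fp=6, fn=1, tn=964))
        for p in (met.recall, met.specificity, met.precision, met.actual_prevalence):
            assert 0 <= p.lower <= p.point <= p.upper <= 1


class TestClopperPearson:
    @pytest.mark.parametrize("x, n", [(248, 248), (10, 10), (1, 1), (500, 500)])
    def test_closed_form_at_full_success(self, x, n):
        ci = clopper_pearson(x, n)
        assert ci.upper == 1.0
        assert math.isclose(ci.lower, 0.025 ** (1 / n), abs_tol=1e-9)

    def test_zero_successes_mirror(self):
        ci = clopper_pearson(0, 20)
        assert ci.lower == 0.0
        assert math.isclose(ci.upper, 1 - 0.025 ** (1 / 20), abs_tol=1e-9)

    def test_matches_beta_quantiles(self):
        ci = clopper_pearson(9, 15)
        assert math.isclose(ci.lower, stats.beta.ppf(0.025, 9, 7), abs_tol=1e-12)
        assert math.isclose(ci.upper, stats.beta.ppf(0.975, 10, 6), abs_tol=1e-12)

    def test_half_integer_counts_accepted(self):
        ci = clopper_pearson(9.5, 981.5)
        assert 0 < ci.lower < ci.point < ci.upper < 1


class TestHaldaneAnscombe:
    def test_zero_cell_shifts_all(self):
        m = haldane_anscombe(ConfusionMatrix(9, 6, 0, 965))
        assert m.as_tuple() == (9.5, 6.5, 0.5, 965.5)

    def test_no_zero_cell_unchanged(self):
        m = ConfusionMatrix(5, 5, 5, 5)
        assert haldane_anscombe(m) is m

    def test_all_zero(self):
        assert haldane_anscombe(ConfusionMatrix(0, 0, 0, 0)).as_tuple() == (
            0.5,
            0.5,
            0.5,
            0.5,
        )

    def test_idempotent_after_correction(self):
        m = haldane_anscombe(ConfusionMatrix(9, 6, 0, 965))
        assert haldane_anscombe(m) is m


class TestPooling:
    def test_identical_estimates_pool_to_themselves(self):
        s = pool_inverse_variance([(0.9, 90, 100), (0.9, 90, 100)])
        assert math.isclose(s.pooled, 0.9, abs_tol=1e-12)

    def test_agreement_narrows_the_interval(self):
        a = pool_inverse_variance([(0.8, 80, 100), (0.8, 800, 1000)])
        solo = 1.96 * math.sqrt(0.8 * 0.2 / 1000)
        assert a.upper - a.lower < 2 * solo
        assert math.isclose(a.pooled, 0.8, abs_tol=1e-12)

    def test_hand_computed_oracle(self):
        # w1 = 1/(0.9*0.1/100) = 1111.11..., w2 = 1/(0.6*0.4/100) = 416.66...
        # pooled = (w1*0.9 + w2*0.6)/(w1+w2) = 1250/1527.77... = 0.8181818...
        s = pool_inverse_variance([(0.9, 90, 100), (0.6, 60, 100)])
        assert math.isclose(s.pooled, 0.8181818181818, abs_tol=1e-9)
        assert math.isclose(s.weights[0], 1111.1111111, rel_tol=1e-9)
        assert math.isclose(s.weights[1], 416.6666667, rel_tol=1e-9)

    def test_pooled_stays_within_input_range(self):
        s = pool_inverse_variance([(0.3, 30, 100), (0.7, 70, 100), (0.5, 5, 10)])
        assert 0.3 <= s.pooled <= 0.7

    def test_degenerate_proportion_weight_capped(self):
        from unlatem.evalstats import MAX_WEIGHT

        s = pool_inverse_variance([(1.0, 10, 10), (0.5, 50, 100)])
        assert s.weights[0] == MAX_WEIGHT
        assert s.pooled == pytest.approx(1.0, abs=1e-6)

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            pool_inverse_variance([(0.5, 5, 10)])


def _brute_force_kappa(a1, a2):
    """Independent oracle: enumerate the 2x2 agreement table directly."""
    n = len(a1)
    po = sum(x == y for x, y in zip(a1, a2)) / n
    pe = 0.0
    for cat in (True, False):
        pe += (sum(x == cat for x in a1) / n) * (sum(y == cat for y in a2) / n)
    return None if pe == 1 else (po - pe) / (1 - pe)


class TestCohenKappa:
    def test_identical_vectors(self):
        res = cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0])
        assert res.kappa == 1.0

    def test_hand_computed_table(self):
        # agreement table (40, 5, 5, 50): po 0.90, pe 0.505, kappa 0.79798
        a1 = [1] * 45 + [0] * 55
        a2 = [1] * 40 + [0] * 5 + [1] * 5 + [0] * 50
        res = cohen_kappa(a1, a2)
        assert res.table == (40, 5, 5, 50)
        assert math.isclose(res.po, 0.90, abs_tol=1e-12)
        assert math.isclose(res.pe, 0.505, abs_tol=1e-12)
        assert math.isclose(res.kappa, 0.395 / 0.495, abs_tol=1e-12)
        assert (res.n_pos_1, res.n_pos_2) == (45, 45)

    def test_published_internal_laterality_agreement(self):
        # 980 records, 98.0% agreement, positives 245 vs 233 -> table
        # (229, 16, 4, 731); the printed kappa is 0.94
        a1 = [1] * 229 + [1] * 16 + [0] * 4 + [0] * 731
        a2 = [1] * 229 + [0] * 16 + [1] * 4 + [0] * 731
        res = cohen_kappa(a1, a2)
        assert (res.n_pos_1, res.n_pos_2) == (245, 233)
        assert 0.93 <= res.kappa <= 0.96

    def test_constant_identical_vectors_undefined(self):
        res = cohen_kappa([1, 1, 1], [1, 1, 1])
        assert res.pe == 1 and res.kappa is None

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=20))
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_oracle(self, pairs):
        a1, a2 = zip(*pairs)
        res = cohen_kappa(a1, a2)
        expected = _brute_force_kappa(a1, a2)
        if expected is None:
            assert res.kappa is None
        else:
            assert math.isclose(res.kappa, expected, abs_tol=1e-12)
            assert res.kappa <= 1

    def test_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        a1 = rng.random(500) < 0.3
        a2 = a1 ^ (rng.random(500) < 0.1)
        assert math.isclose(
            cohen_kappa(a1, a2).kappa,
            sklearn_metrics.cohen_kappa_score(a1, a2),
            abs_tol=1e-12,
        )


class TestReconstructMatrix:
    @pytest.mark.parametrize("key", sorted(SUMMARY_ROWS), ids="-".join)
    def test_error_counts_match_published_error_analysis(self, key):
        row = SUMMARY_ROWS[key]
        m = reconstruct_matrix(
            row["n"], row["prevalence"], row["recall"], row["precision"]
        )
        assert (m.fp, m.fn) == (row["fp"], row["fn"])
        assert m.n == row["n"]

    def test_degenerate_perfect_classifier(self):
        m = reconstruct_matrix(100, 100, 100, 100)
        assert m.as_tuple() == (100, 0, 0, 0)

    def test_inconsistent_inputs_raise(self):
        # prevalence 100% but precision < 100% forces a negative tn
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct_matrix(100, 100, 100, 50)

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ValueError):
            reconstruct_matrix(100, 0, 50, 50)
        with pytest.raises(ValueError):
            reconstruct_matrix(0, 10, 50, 50)
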