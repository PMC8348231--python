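"""Confusion-matrix metrics, checked against published benchmark counts.

The golden numbers come from the printed evaluation tables of the blind-test
benchmark for three-class solubility predictors: class sizes 338 decreasing /
237 no-effect / 87 increasing, with per-class counts reported as
raw/normalized pairs (normalization rescales every true-class row to the
no-effect row size).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from solvar import (
    ConfusionMatrix,
    confusion_from_predictions,
    cpr,
    gc2,
    normalize_confusion,
    per_class_measures,
    reconstruct_full_matrix,
)
from solvar.metrics import evaluate, table_report

# Blind-test column of the reference two-layer 34-feature classifier.
BLIND_CLASS_SIZES = (338, 237, 87)          # decrease, no_effect, increase
BLIND_RAW_TP = (271, 159, 14)
BLIND_RAW_FP = (66, 106, 46)
BLIND_NORM_FP = (105.7, 175.5, 42.7)
#: Full 3x3 matrix implied by the raw + normalized marginals above.
BLIND_MATRIX = np.array([[271, 56, 11], [43, 159, 35], [23, 50, 14]])


@pytest.fixture(scope="module")
def blind_cm():
    return ConfusionMatrix(BLIND_MATRIX.astype(float))


class TestConfusionConstruction:
    def test_perfect_predictions_identity_pattern(self):
        cm = confusion_from_predictions(
            ["decrease", "no_effect", "increase"],
            ["decrease", "no_effect", "increase"])
        assert np.array_equal(cm.z, np.eye(3))

    def test_all_predicted_decrease_single_column(self):
        cm = confusion_from_predictions(
            ["decrease", "no_effect", "increase"], ["decrease"] * 3)
        assert cm.z[:, 0].sum() == 3 and cm.z[:, 1:].sum() == 0

    def test_total_preserved(self):
        rng = np.random.default_rng(0)
        true = rng.choice(["decrease", "no_effect", "increase"], 40)
        pred = rng.choice(["decrease", "no_effect", "increase"], 40)
        assert confusion_from_predictions(true, pred).N == 40

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_predictions(["soluble"], ["decrease"])


class TestNormalization:
    def test_published_tp_pairs(self, blind_cm):
        norm = normalize_confusion(blind_cm, "no_effect")
        # 14 x 237/87 = 38.1 (increase), 271 x 237/338 = 190.0 (decrease)
        assert norm.z[2, 2] == pytest.approx(38.1, abs=0.05)
        assert norm.z[0, 0] == pytest.approx(190.0, abs=0.05)
        # reference row unchanged
        np.testing.assert_allclose(norm.z[1], blind_cm.z[1])

    def test_balanced_classes_identity(self):
        z = np.array([[5, 1, 0], [2, 3, 1], [1, 1, 4]], float)
        np.testing.assert_allclose(normalize_confusion(ConfusionMatrix(z)).z, z)

    def test_empty_class_rejected(self):
        z = np.array([[3, 0, 0], [0, 0, 0], [0, 0, 2]], float)
        with pytest.raises(ValueError, match="empty"):
            normalize_confusion(ConfusionMatrix(z))

    def test_sensitivity_invariant_specificity_not(self, blind_cm):
        raw = per_class_measures(blind_cm)
        norm = per_class_measures(normalize_confusion(blind_cm))
        np.testing.assert_allclose(raw["sensitivity"], norm["sensitivity"])
        assert not np.allclose(raw["specificity"], norm["specificity"])

    @pytest.mark.parametrize("reference", ["decrease", "no_effect", "increase"])
    def test_metrics_invariant_to_reference_class(self, blind_cm, reference):
        base = normalize_confusion(blind_cm, "no_effect")
        other = normalize_confusion(blind_cm, reference)
        np.testing.assert_allclose(per_class_measures(base).to_numpy()[:, 4:],
                                   per_class_measures(other).to_numpy()[:, 4:])
        assert cpr(base) == pytest.approx(cpr(other))
        assert gc2(base) == pytest.approx(gc2(other))


class TestPerClassMeasures:
    def test_published_decreasing_class_ratios(self, blind_cm):
        pc = per_class_measures(blind_cm)
        row = pc.loc["decrease"]
        assert (row.TP, row.FP, row.FN, row.TN) == (271, 66, 67, 258)
        assert row.PPV == pytest.approx(0.804, abs=5e-4)
        assert row.sensitivity == pytest.approx(0.802, abs=5e-4)
        assert row.NPV == pytest.approx(0.794, abs=5e-4)
        assert row.specificity == pytest.approx(0.796, abs=5e-4)

    def test_perfect_classifier_all_ones(self):
        pc = per_class_measures(ConfusionMatrix(np.diag([5.0, 7, 3])))
        assert (pc[["PPV", "NPV", "sensitivity", "specificity"]] == 1).all().all()

    def test_published_low_sensitivity_column(self):
        # an earlier predictor's decreasing class: TP 89 of 338
        z = np.array([[89, 0, 249], [0, 108, 129], [0, 48, 39]], float)
        pc = per_class_measures(ConfusionMatrix(z))
        assert pc.loc["decrease", "sensitivity"] == pytest.approx(89 / 338, abs=5e-4)

    def test_zero_denominator_reported_nan(self):
        # nothing predicted as class 2 -> PPV undefined, not zero
        z = np.array([[4, 1, 0], [2, 3, 0], [1, 1, 0]], float)
        pc = per_class_measures(ConfusionMatrix(z))
        assert np.isnan(pc.loc["increase", "PPV"])


class TestOverallScores:
    def test_published_raw_cpr(self, blind_cm):
        assert cpr(blind_cm) == pytest.approx(444 / 662, abs=1e-9)
        assert round(cpr(blind_cm), 3) == 0.671

    def test_published_normalized_cpr(self, blind_cm):
        assert round(cpr(normalize_confusion(blind_cm)), 3) == 0.545

    def test_perfect_classifier_cpr_one(self):
        assert cpr(ConfusionMatrix(np.diag([3.0, 3, 3]))) == 1.0

    def test_random_assignment_near_third(self):
        rng = np.random.default_rng(1)
        true = rng.choice(["decrease", "no_effect", "increase"], 30000)
        pred = rng.choice(["decrease", "no_effect", "increase"], 30000)
        assert cpr(confusion_from_predictions(true, pred)) == pytest.approx(1 / 3, abs=0.01)

    def test_gc2_perfect_equal_classes_is_one(self):
        assert gc2(ConfusionMatrix(np.diag([10.0, 10, 10]))) == pytest.approx(1.0)

    def test_gc2_independence_is_zero(self):
        x = np.array([30.0, 20, 10])
        y = np.array([15.0, 25, 20])
        z = np.outer(x, y) / 60
        assert gc2(ConfusionMatrix(z)) == pytest.approx(0.0, abs=1e-12)

    def test_published_blind_gc2(self, blind_cm):
        assert round(gc2(blind_cm), 3) == 0.181

    def test_gc2_zero_margin_nan(self):
        z = np.array([[4, 1, 0], [2, 3, 0], [1, 1, 0]], float)
        assert np.isnan(gc2(ConfusionMatrix(z)))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_gc2_equals_scaled_chisquare(self, seed):
        """GC² must equal Pearson chi-square / (N(K-1)) — independent oracle."""
        rng = np.random.default_rng(seed)
        z = rng.integers(1, 60, size=(3, 3)).astype(float)
        chi2 = chi2_contingency(z, correction=False).statistic
        assert gc2(ConfusionMatrix(z)) == pytest.approx(chi2 / (z.sum() * 2), rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_scores_bounded(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.integers(1, 50, size=(3, 3)).astype(float)
        assert 0 <= cpr(ConfusionMatrix(z)) <= 1
        assert 0 <= gc2(ConfusionMatrix(z)) <= 1


class TestReconstruction:
    def test_published_blind_matrix(self):
        cm = reconstruct_full_matrix(BLIND_RAW_TP, BLIND_RAW_FP, BLIND_NORM_FP,
                                     BLIND_CLASS_SIZES)
        np.testing.assert_array_equal(cm.z, BLIND_MATRIX)

    def test_roundtrip_from_own_marginals(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            z = rng.integers(0, 80, size=(3, 3)).astype(float)
            z += np.diag(rng.integers(30, 60, size=3))  # keep rows nonzero
            cm = ConfusionMatrix(z)
            norm = normalize_confusion(cm)
            raw_fp = per_class_measures(cm)["FP"].to_numpy()
            norm_fp = per_class_measures(norm)["FP"].to_numpy()
            rec = reconstruct_full_matrix(np.diag(z), raw_fp, norm_fp, cm.row_totals,
                                          atol=1e-6)
            np.testing.assert_array_equal(rec.z, z)

    def test_inconsistent_marginals_rejected(self):
        bad_norm_fp = (BLIND_NORM_FP[0] + 9, BLIND_NORM_FP[1], BLIND_NORM_FP[2])
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct_full_matrix(BLIND_RAW_TP, BLIND_RAW_FP, bad_norm_fp,
                                    BLIND_CLASS_SIZES)

    def test_equal_weights_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            reconstruct_full_matrix((5, 5, 5), (2, 2, 2), (2.0, 2.0, 2.0), (10, 10, 10))


def test_table_report_layout(blind_cm):
    rep = table_report(blind_cm)
    assert rep.loc["TP", "increase"] == "14.0/38.1"
    assert rep.loc["CPR", "decrease"] == "0.671/0.545"
    assert rep.loc["GC2", "decrease"] == "0.181/0.157"


def test_evaluate_bundles_measures(blind_cm):
    rep = evaluate(blind_cm)
    assert rep.cpr == pytest.approx(cpr(blind_cm))
    assert set(rep.per_class.columns) >= {"PPV", "NPV", "sensitivity", "specificity"}
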