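"""Agreement statistics: closed forms, branch gating, and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivcflow.metrics import (
    agreement_report,
    bland_altman,
    chi_square_association,
    confusion_and_macro,
    location_test,
    overlap_scores,
    pearson_r,
)


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_point_eight(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 10),
           b=st.floats(-5, 5))
    def test_invariant_under_positive_affine(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


class TestBlandAltman:
    def test_identical_series(self):
        bias, lo, hi, _ = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        bias, lo, hi, _ = bland_altman([2.0, 3, 4], [1.0, 2, 3])
        assert bias == 1.0 and lo == hi == 1.0

    def test_closed_form_two_pairs(self):
        # differences (0, 2): bias 1, SD sqrt(2), LoA 1 +- 1.96*sqrt(2)
        bias, lo, hi, _ = bland_altman([1.0, 3.0], [1.0, 1.0])
        assert bias == pytest.approx(1.0)
        assert hi == pytest.approx(1 + 1.96 * np.sqrt(2))
        assert lo == pytest.approx(1 - 1.96 * np.sqrt(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2], [1.0, 2, 3])


class TestLocationTest:
    def test_identical_series_degenerate(self):
        name, _, p = location_test([1.0, 2, 3], [1.0, 2, 3])
        assert name == "degenerate" and p == 1.0

    def test_gaussian_differences_choose_t(self):
        chosen = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            manual = rng.normal(10, 2, 25)
            auto = manual + rng.normal(0.1, 0.5, 25)
            chosen.append(location_test(auto, manual)[0])
        assert np.mean([c == "paired-t" for c in chosen]) >= 0.9

    def test_heavy_tailed_differences_choose_rank(self):
        chosen = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            manual = rng.normal(10, 2, 40)
            auto = manual + rng.standard_cauchy(40)
            chosen.append(location_test(auto, manual)[0])
        assert np.mean([c == "wilcoxon" for c in chosen]) > 0.5

    def test_unpaired_form_available(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        name, _, p = location_test(a, b, force="mannwhitney")
        assert name == "mann-whitney" and 0 <= p <= 1


class TestChiSquare:
    def test_perfect_association_2x2(self):
        stat, dof, p = chi_square_association([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0) and dof == 1

    def test_independent_uniform_zero(self):
        stat, _, p = chi_square_association([[5, 5], [5, 5]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_one_by_two_rejected(self):
        with pytest.raises(ValueError):
            chi_square_association([[3, 4]])

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            stat, dof, _ = chi_square_association([[5, 5, 0], [5, 5, 0]])
        assert dof == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_expected_counts(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 30, size=(rng.integers(2, 5), rng.integers(2, 5)))
        stat, dof, _ = chi_square_association(table)
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        brute = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, rel=1e-12)
        assert dof == (table.shape[0] - 1) * (table.shape[1] - 1)


class TestConfusionAndMacro:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        cm, norm, macro, per = confusion_and_macro(y, y, ["a", "b", "c"])
        assert macro == 1.0
        assert all(v["f1"] == 1.0 for v in per.values())
        assert np.allclose(norm.sum(axis=1), 1.0)

    def test_one_class_fully_misassigned(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 5 + ["a"] * 5
        _, _, macro, per = confusion_and_macro(y_true, y_pred, ["a", "b"])
        assert macro == 0.5  # mean of recalls (1.0, 0.0)
        assert per["b"]["precision"] == 0.0  # empty predicted class

    def test_all_one_class_predictor_on_balanced_k(self):
        y_true = ["a", "b", "c"] * 4
        y_pred = ["a"] * 12
        _, _, macro, _ = confusion_and_macro(y_true, y_pred, ["a", "b", "c"])
        assert macro == pytest.approx(1 / 3)

    def test_permutation_matrix_macro_one(self):
        y_true = ["a", "b", "c"]
        y_pred = ["a", "b", "c"]
        _, _, macro, _ = confusion_and_macro(y_true, y_pred, ["a", "b", "c"])
        assert macro == 1.0

    def test_unseen_label_named_in_error(self):
        with pytest.raises(ValueError, match="z"):
            confusion_and_macro(["a"], ["z"], ["a", "b"])


class TestOverlap:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((10, 10)) > 0.5
        assert overlap_scores(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0], b[3, 3] = True, True
        assert overlap_scores(a, b) == (0.0, 0.0)

    def test_half_overlap_counts(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True  # |A| = 4
        b[0, 2:], b[1, :2] = True, True  # |B| = 4, intersection 2
        iou, dsc = overlap_scores(a, b)
        assert iou == pytest.approx(1 / 3) and dsc == pytest.approx(0.5)

    def test_both_empty_convention(self):
        assert overlap_scores(np.zeros((3, 3)), np.zeros((3, 3))) == (1.0, 1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            overlap_scores(np.zeros((3, 3)), np.zeros((4, 4)))

    @pytest.mark.parametrize("seed", range(100))
    def test_dice_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) > rng.uniform(0.2, 0.8)
        b = rng.random((16, 16)) > rng.uniform(0.2, 0.8)
        iou, dsc = overlap_scores(a, b)
        assert dsc == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


class TestAgreementReport:
    def test_full_report_assembles(self):
        rng = np.random.default_rng(5)
        manual = rng.normal(15, 3, 40)
        auto = manual + rng.normal(0, 0.5, 40)
        lab_m = ["high" if v > 15 else "low" for v in manual]
        lab_a = ["high" if v > 15 else "low" for v in auto]
        rep = agreement_report(auto, manual, lab_a, lab_m)
        assert -1 <= rep.pearson_r <= 1
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert 0 <= rep.macro_accuracy <= 1
        d = rep.to_dict()
        assert set(d) >= {"pearson_r", "bland_altman", "location_test"}
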