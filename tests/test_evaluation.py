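"""IoU matching, precision/recall/F1, AP and verification statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomatophen.errors import InputError, UndefinedMetricError
from tomatophen.evaluation import (
    Detection,
    MatchResult,
    apply_practical_corrections,
    mask_iou,
    match_instances,
    pr_curve_and_ap,
    precision_recall_f1,
    relative_rmse,
    verification_report,
)


def _box(shape, r0, c0, r1, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestMaskIoU:
    def test_identical_masks(self):
        m = _box((6, 6), 1, 1, 4, 4)
        assert mask_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        assert mask_iou(_box((6, 6), 0, 0, 2, 2), _box((6, 6), 3, 3, 5, 5)) == 0.0

    def test_one_third_overlap(self):
        a = _box((1, 6), 0, 0, 1, 2)
        b = _box((1, 6), 0, 1, 1, 3)
        assert mask_iou(a, b) == pytest.approx(1.0 / 3.0)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            mask_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mask_iou(np.zeros((2, 2), bool), np.zeros((2, 2), bool))


def brute_force_match(pred_masks, gt_masks, thr=0.5):
    """Oracle: exhaustive one-to-one assignment maximizing the TP count
    (then total IoU), considering only pairs with IoU > thr."""
    iou = np.zeros((len(pred_masks), len(gt_masks)))
    for i, p in enumerate(pred_masks):
        for j, g in enumerate(gt_masks):
            u = (p | g).sum()
            iou[i, j] = (p & g).sum() / u if u else 0.0
    best_tp, best_iou_sum = 0, -1.0
    n_p, n_g = len(pred_masks), len(gt_masks)
    k = min(n_p, n_g)
    for size in range(k, -1, -1):
        found_at_size = False
        for preds in itertools.permutations(range(n_p), size):
            for gts in itertools.combinations(range(n_g), size):
                if all(iou[p, g] > thr for p, g in zip(preds, gts)):
                    s = sum(iou[p, g] for p, g in zip(preds, gts))
                    found_at_size = True
                    if size > best_tp or (size == best_tp and s > best_iou_sum):
                        best_tp, best_iou_sum = size, s
        if found_at_size:
            break
    return best_tp


def random_instance_set(rng, shape=(32, 32), max_gt=3):
    """Well-separated case: each prediction is a jittered copy of its own
    ground truth (no cross-overlaps), plus occasional background boxes."""
    gts, preds = [], []
    n_gt = rng.integers(1, max_gt + 1)
    cells = rng.permutation(9)[:n_gt + 1]
    for k in range(n_gt):
        r0 = (cells[k] // 3) * 10 + 1
        c0 = (cells[k] % 3) * 10 + 1
        h, w = rng.integers(5, 8), rng.integers(5, 8)
        gt = _box(shape, r0, c0, r0 + h, c0 + w)
        gts.append(gt)
        jr, jc = rng.integers(0, 2, size=2)
        preds.append(Detection(_box(shape, r0 + jr, c0 + jc, r0 + jr + h, c0 + jc + w),
                               float(rng.uniform(0.3, 1.0))))
    if rng.uniform() < 0.5:  # a pure false positive in the spare cell
        r0 = (cells[n_gt] // 3) * 10 + 1
        c0 = (cells[n_gt] % 3) * 10 + 1
        preds.append(Detection(_box(shape, r0, c0, r0 + 5, c0 + 5),
                               float(rng.uniform(0.3, 1.0))))
    return preds, gts


class TestMatching:
    def test_perfect_single_prediction(self):
        gt = _box((8, 8), 2, 2, 6, 6)
        m = match_instances([Detection(gt, 0.9)], [gt])
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_duplicate_predictions_higher_score_wins(self):
        gt = _box((8, 8), 2, 2, 6, 6)
        a = Detection(_box((8, 8), 2, 2, 6, 6), 0.6)
        b = Detection(_box((8, 8), 2, 2, 6, 5), 0.9)
        m = match_instances([a, b], [gt])
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs[0][0] == 1  # the higher-scored prediction holds the match

    def test_iou_threshold_is_strict(self):
        # IoU exactly 0.5: 2x2 vs 2x4 sharing a 2x2 cell -> 4/8
        gt = _box((4, 8), 0, 0, 2, 4)
        pred = _box((4, 8), 0, 2, 2, 4)
        assert mask_iou(pred, gt) == 0.5
        m = match_instances([Detection(pred, 0.9)], [gt], iou_threshold=0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_agrees_with_bruteforce_on_separated_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            preds, gts = random_instance_set(rng)
            m = match_instances(preds, gts)
            assert m.tp == brute_force_match([p.mask for p in preds], gts)


class TestPrecisionRecallF1:
    def test_formula_values(self):
        p, r, f1 = precision_recall_f1(MatchResult(3, 1, 1, [], 0.5))
        assert (p, r, f1) == (0.75, 0.75, 0.75)

    def test_undefined_recall_reported_as_none(self):
        p, r, f1 = precision_recall_f1(MatchResult(0, 5, 0, [], 0.5))
        assert p == 0.0 and r is None and f1 is None

    def test_equal_fp_fn_makes_f1_equal_p(self):
        for tp, k in ((4, 2), (7, 3), (1, 1)):
            p, r, f1 = precision_recall_f1(MatchResult(tp, k, k, [], 0.5))
            assert f1 == pytest.approx(p)


def brute_force_ap(preds, gts, thr=0.5):
    """Oracle AP: optimal matching at every threshold, then a fine Riemann
    integration of the precision envelope over recall."""
    scores = sorted({p.score for p in preds}, reverse=True)
    pts = []
    for s in scores:
        kept = [p for p in preds if p.score >= s]
        tp = brute_force_match([p.mask for p in kept], gts, thr)
        pts.append((tp / len(gts), tp / len(kept)))
    grid = np.linspace(0, 1, 2001)
    env = np.zeros_like(grid)
    for recall, precision in pts:
        env[grid <= recall + 1e-12] = np.maximum(env[grid <= recall + 1e-12], precision)
    return float(np.trapezoid(env, grid) + env[0] * 0)  # left edge starts at 0


class TestAveragePrecision:
    def test_single_perfect_prediction(self):
        gt = _box((8, 8), 2, 2, 6, 6)
        assert pr_curve_and_ap([Detection(gt, 0.9)], [gt]).ap == 1.0

    def test_envelope_ignores_trailing_false_positive(self):
        gt = _box((8, 8), 2, 2, 6, 6)
        fp = _box((8, 8), 0, 6, 2, 8)
        curve = pr_curve_and_ap([Detection(gt, 0.9), Detection(fp, 0.8)], [gt])
        assert curve.ap == 1.0

    def test_trapezoid_option_is_not_higher(self):
        gt = _box((8, 8), 2, 2, 6, 6)
        fp = _box((8, 8), 0, 6, 2, 8)
        preds = [Detection(fp, 0.9), Detection(gt, 0.8)]
        env = pr_curve_and_ap(preds, [gt]).ap
        trap = pr_curve_and_ap(preds, [gt], interpolation="trapezoid").ap
        assert trap <= env + 1e-12

    def test_monotone_score_rescaling_preserves_ap(self):
        rng = np.random.default_rng(11)
        preds, gts = random_instance_set(rng)
        base = pr_curve_and_ap(preds, gts).ap
        squeezed = [Detection(p.mask, p.score ** 3) for p in preds]
        assert pr_curve_and_ap(squeezed, gts).ap == pytest.approx(base)

    def test_lowest_scored_zero_iou_prediction_never_changes_ap(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            preds, gts = random_instance_set(rng)
            base = pr_curve_and_ap(preds, gts).ap
            lowest = min(p.score for p in preds) / 2.0
            extra = preds + [Detection(_box((32, 32), 29, 29, 31, 31), lowest)]
            assert pr_curve_and_ap(extra, gts).ap == pytest.approx(base)

    def test_matches_bruteforce_envelope_integration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            preds, gts = random_instance_set(rng)
            got = pr_curve_and_ap(preds, gts).ap
            assert got == pytest.approx(brute_force_ap(preds, gts), abs=2e-3)

    def test_no_ground_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pr_curve_and_ap([Detection(_box((4, 4), 0, 0, 2, 2), 0.5)], [])


class TestPracticalCorrections:
    def _result(self):
        return MatchResult(8, 1, 2, [(0, 0, 0.9)], 0.5,
                           unmatched_pred_ids=[5], unmatched_gt_ids=[3, 4])

    def test_fn_reclassified_as_tp(self):
        m, audit = apply_practical_corrections(
            self._result(), [{"kind": "fn", "id": 3, "reason": "correct count"}])
        assert (m.tp, m.fp, m.fn) == (9, 1, 1)
        assert audit[0]["id"] == 3 and audit[0]["reclassified_as"] == "tp"

    def test_empty_rules_identity(self):
        base = self._result()
        m, audit = apply_practical_corrections(base, [])
        assert (m.tp, m.fp, m.fn) == (base.tp, base.fp, base.fn)
        assert audit == []

    def test_corrections_never_decrease_recall(self):
        base = self._result()
        r0 = precision_recall_f1(base)[1]
        for rules in ([{"kind": "fn", "id": 3}], [{"kind": "fp", "id": 5}],
                      [{"kind": "fn", "id": 3}, {"kind": "fn", "id": 4}]):
            m, _ = apply_practical_corrections(base, rules)
            assert precision_recall_f1(m)[1] >= r0

    def test_unknown_id_rejected(self):
        with pytest.raises(InputError):
            apply_practical_corrections(self._result(), [{"kind": "fn", "id": 99}])


class TestRelativeRmse:
    def test_identical_inputs_zero(self):
        assert relative_rmse([3.2, 5.1, 7.7], [3.2, 5.1, 7.7]) == 0.0

    def test_single_term(self):
        assert relative_rmse([11], [10]) == pytest.approx(0.1)

    def test_symmetric_errors(self):
        assert relative_rmse([11, 9], [10, 10]) == pytest.approx(0.1)

    def test_zero_manual_value_undefined(self):
        with pytest.raises(UndefinedMetricError):
            relative_rmse([1.0], [0.0])

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            relative_rmse([1.0, 2.0], [1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0), flip=st.booleans())
    def test_scale_invariance(self, c, flip):
        if flip:
            c = -c
        r = np.array([11.0, 9.5, 10.2])
        m = np.array([10.0, 10.0, 10.0])
        assert relative_rmse(r * c, m * c) == pytest.approx(relative_rmse(r, m))


class TestVerificationReport:
    def test_perfect_agreement(self):
        rep = verification_report([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep.rmse_rel == 0.0
        assert rep.pearson_r2 == pytest.approx(1.0)

    def test_constant_shift_gives_zero_variance_statistic(self):
        rep = verification_report([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert rep.variance_test_p > 0.99  # identical spreads

    def test_constant_input_flags_correlation(self):
        rep = verification_report([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert rep.pearson_r2 is None
        assert rep.notes

    def test_one_percent_multiplicative_noise(self):
        rng = np.random.default_rng(19)
        manual = rng.uniform(5.0, 15.0, size=100)
        recognized = manual * (1.0 + rng.normal(0.0, 0.01, size=100))
        rep = verification_report(recognized, manual)
        assert 0.005 <= rep.rmse_rel <= 0.015
        assert rep.mean_difference_p > 0.05
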