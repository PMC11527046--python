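"""Detection metrics: IoU, matching, image metrics, AP, tuning, phenotypes."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardioreclass.detection import (
    Box,
    aggregate_phenotypes,
    average_precision_50,
    box_iou,
    detection_pr,
    image_classification_metrics,
    match_detections,
    tune_confidence_threshold,
)


def _box(x0, y0, x1, y1, conf=None):
    return Box(x0, y0, x1, y1, conf)


class TestIoU:
    def test_identical_boxes(self):
        b = _box(3, 4, 10, 12)
        assert box_iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou(_box(0, 0, 1, 1), _box(5, 5, 6, 6)) == 0.0

    def test_partial_overlap_hand_value(self):
        # inter = 1, union = 4 + 4 - 1 = 7
        assert box_iou(_box(0, 0, 2, 2), _box(1, 1, 3, 3)) == pytest.approx(1 / 7)

    @given(st.lists(st.floats(0, 100), min_size=8, max_size=8))
    def test_symmetry_and_range(self, vals):
        x = sorted(vals[:2]) + sorted(vals[2:4])
        y = sorted(vals[4:6]) + sorted(vals[6:])
        if x[0] == x[1] or x[2] == x[3] or y[0] == y[1] or y[2] == y[3]:
            return
        a = _box(x[0], x[2], x[1], x[3])
        b = _box(y[0], y[2], y[1], y[3])
        iou = box_iou(a, b)
        assert iou == pytest.approx(box_iou(b, a))
        assert 0.0 <= iou <= 1.0

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            Box(2, 0, 1, 1)


class TestMatching:
    def test_single_pair(self):
        gt = [_box(0, 0, 10, 10)]
        preds = [_box(0, 0, 10, 6, conf=0.9)]  # IoU 0.6
        m = match_detections(gt, preds, 0.13, 0.5)
        assert m.n_tp == 1 and m.n_fp == 0 and m.n_fn == 0

    def test_low_confidence_discarded(self):
        gt = [_box(0, 0, 10, 10)]
        preds = [_box(0, 0, 10, 10, conf=0.10)]
        m = match_detections(gt, preds, conf_threshold=0.13)
        assert m.n_tp == 0 and m.n_fn == 1 and m.n_fp == 0

    def test_higher_confidence_wins_shared_gt(self):
        gt = [_box(0, 0, 10, 10)]
        preds = [
            _box(0, 0, 10, 7, conf=0.8),   # IoU 0.7
            _box(0, 0, 10, 9, conf=0.6),   # IoU 0.9
        ]
        m = match_detections(gt, preds, 0.13, 0.5)
        assert m.pairs[0][1] == 0  # conf-0.8 prediction matched
        assert m.unmatched_pred == [1]

    @staticmethod
    def _optimal_match_count(gt, preds, iou_thr):
        """Brute-force maximum-cardinality assignment among admissible pairs."""
        admissible = {
            (i, j)
            for i, g in enumerate(gt)
            for j, p in enumerate(preds)
            if box_iou(g, p) >= iou_thr
        }
        best = 0
        idx = range(len(preds))
        for r in range(min(len(gt), len(preds)), 0, -1):
            for gsub in itertools.permutations(range(len(gt)), r):
                for psub in itertools.combinations(idx, r):
                    if all((g, p) in admissible for g, p in zip(gsub, psub)):
                        best = max(best, r)
                if best == r:
                    break
            if best:
                break
        return best

    def test_greedy_equals_exhaustive_on_random_instances(self):
        """Confidence-ordered greedy matching yields the same match count as
        exhaustive optimal assignment for up to 3 boxes per side."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            gt = []
            preds = []
            for _ in range(rng.integers(0, 4)):
                x0, y0 = rng.uniform(0, 80, 2)
                gt.append(_box(x0, y0, x0 + rng.uniform(5, 40), y0 + rng.uniform(5, 40)))
            for _ in range(rng.integers(0, 4)):
                x0, y0 = rng.uniform(0, 80, 2)
                preds.append(_box(x0, y0, x0 + rng.uniform(5, 40),
                                  y0 + rng.uniform(5, 40), conf=float(rng.uniform(0.2, 1))))
            m = match_detections(gt, preds, conf_threshold=0.1, iou_threshold=0.5)
            assert m.n_tp == self._optimal_match_count(gt, preds, 0.5)

    def test_recall_monotone_in_conf_threshold(self, detection_fixtures):
        ann, preds = detection_fixtures
        recalls = []
        for t in (0.9, 0.5, 0.2, 0.05):
            ms = [match_detections(a["boxes"], p["boxes"], t, 0.5)
                  for a, p in zip(ann, preds)]
            r = detection_pr(ms)["recall"]
            recalls.append(-1.0 if r is None else r)
        assert all(a <= b + 1e-12 for a, b in zip(recalls, recalls[1:]))


class TestImageMetrics:
    def test_study_test_set_composition(self):
        """103 images, 38 positive, TP=34, FP=7 reproduce the published
        quartet: accuracy 89.3%, sensitivity 89.5%, specificity 89.2%,
        PPV 82.9%."""
        gt = [True] * 38 + [False] * 65
        pred = [True] * 34 + [False] * 4 + [True] * 7 + [False] * 58
        m = image_classification_metrics(gt, pred)
        assert m["accuracy"] == pytest.approx(92 / 103)
        assert m["sensitivity"] == pytest.approx(34 / 38)
        assert m["specificity"] == pytest.approx(58 / 65)
        assert m["ppv"] == pytest.approx(34 / 41)
        assert round(100 * m["accuracy"], 1) == 89.3
        assert round(100 * m["sensitivity"], 1) == 89.5
        assert round(100 * m["specificity"], 1) == 89.2
        assert round(100 * m["ppv"], 1) == 82.9

    def test_perfect_and_degenerate(self):
        m = image_classification_metrics([True, False], [True, False])
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "ppv"))
        m = image_classification_metrics([True, True, False], [False, False, False])
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["ppv"] is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            image_classification_metrics([], [])


class TestDetectionPR:
    def test_published_counts(self):
        """38 matched pairs, 16 FP and 15 FN reproduce precision 70.3% and
        recall 71.7% against 53 true plaques."""
        from cardioreclass.detection import MatchResult

        m = MatchResult(pairs=[(i, i, 0.8) for i in range(38)],
                        unmatched_gt=list(range(15)),
                        unmatched_pred=list(range(16)))
        pr = detection_pr(m)
        assert round(100 * pr["precision"], 1) == 70.4  # 38/54
        assert round(100 * pr["recall"], 1) == 71.7     # 38/53
        assert pr["precision"] == pytest.approx(38 / 54)
        assert pr["recall"] == pytest.approx(38 / 53)

    def test_all_matched_and_empty(self):
        from cardioreclass.detection import MatchResult

        assert detection_pr(MatchResult(pairs=[(0, 0, 1.0)]) ) == {"precision": 1.0, "recall": 1.0}
        empty = detection_pr(MatchResult(unmatched_gt=[0]))
        assert empty["precision"] is None
        assert empty["recall"] == 0.0


class TestAveragePrecision:
    def _rec(self, image_id, boxes):
        return {"image_id": image_id, "boxes": boxes}

    def test_perfect_predictions(self):
        gt = [self._rec("a", [dict(x_min=0, y_min=0, x_max=10, y_max=10)])]
        preds = [self._rec("a", [dict(x_min=0, y_min=0, x_max=10, y_max=10, confidence=0.4)])]
        assert average_precision_50(gt, preds) == pytest.approx(1.0)

    def test_single_wrong_prediction(self):
        gt = [self._rec("a", [dict(x_min=0, y_min=0, x_max=10, y_max=10)])]
        preds = [self._rec("a", [dict(x_min=50, y_min=50, x_max=60, y_max=60, confidence=0.9)])]
        assert average_precision_50(gt, preds) == 0.0

    def test_hand_computed_envelope(self):
        # 2 gt; ranked preds: hit (0.9), miss (0.8), hit (0.7) -> AP = 5/6
        gt = [self._rec("a", [dict(x_min=0, y_min=0, x_max=10, y_max=10),
                              dict(x_min=100, y_min=100, x_max=110, y_max=110)])]
        preds = [self._rec("a", [
            dict(x_min=0, y_min=0, x_max=10, y_max=10, confidence=0.9),
            dict(x_min=50, y_min=50, x_max=60, y_max=60, confidence=0.8),
            dict(x_min=100, y_min=100, x_max=110, y_max=110, confidence=0.7),
        ])]
        assert average_precision_50(gt, preds) == pytest.approx(5 / 6)

    def test_no_gt_is_missing(self):
        assert average_precision_50([self._rec("a", [])], [self._rec("a", [])]) is None

    def test_invariant_to_monotone_confidence_transform(self, detection_fixtures):
        ann, preds = detection_fixtures
        ap = average_precision_50(ann, preds)
        warped = [
            {"image_id": r["image_id"],
             "boxes": [{**b, "confidence": b["confidence"] ** 3} for b in r["boxes"]]}
            for r in preds
        ]
        assert average_precision_50(ann, warped) == pytest.approx(ap)


class TestThresholdTuning:
    def test_tie_breaks_to_lowest(self):
        gt = [{"image_id": "a", "boxes": [dict(x_min=0, y_min=0, x_max=10, y_max=10)]}]
        preds = [{"image_id": "a",
                  "boxes": [dict(x_min=0, y_min=0, x_max=10, y_max=10, confidence=0.95)]}]
        assert tune_confidence_threshold(gt, preds, [0.1, 0.5, 0.9]) == 0.1

    def test_constructed_optimum_at_13_percent(self):
        # positives predicted at conf 0.2; spurious boxes on negatives at conf 0.10:
        # only thresholds in (0.10, 0.2] are perfect, so 0.13 wins the grid scan
        gt, preds = [], []
        for i in range(6):
            pos = i < 3
            gt.append({"image_id": str(i),
                       "boxes": [dict(x_min=0, y_min=0, x_max=10, y_max=10)] if pos else []})
            boxes = [dict(x_min=0, y_min=0, x_max=10, y_max=10, confidence=0.2)] if pos else \
                    [dict(x_min=0, y_min=0, x_max=10, y_max=10, confidence=0.10)]
            preds.append({"image_id": str(i), "boxes": boxes})
        grid = [0.05, 0.10, 0.13, 0.5]
        assert tune_confidence_threshold(gt, preds, grid) == 0.13

    def test_single_point_grid(self):
        gt = [{"image_id": "a", "boxes": []}]
        preds = [{"image_id": "a", "boxes": []}]
        assert tune_confidence_threshold(gt, preds, [0.37]) == 0.37

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_confidence_threshold([], [], [])


class TestPhenotypeAggregation:
    def test_simple_sum(self):
        out = aggregate_phenotypes({"left": [2], "right": [0]})
        assert out == {"plaque_present": True, "plaque_count": 2,
                       "per_artery": {"left": 2, "right": 0}}

    def test_positive_image_prioritised(self):
        out = aggregate_phenotypes({"left": [0, 1], "right": [0]})
        assert out["plaque_count"] >= 1 and out["per_artery"]["left"] == 1

    def test_seeded_choice_among_positives(self):
        a = aggregate_phenotypes({"left": [2, 3, 1], "right": []}, seed=5)
        b = aggregate_phenotypes({"left": [2, 3, 1], "right": []}, seed=5)
        assert a == b
        assert a["plaque_count"] in (1, 2, 3)

    def test_all_negative_and_missing(self):
        assert aggregate_phenotypes({"left": [0], "right": [0]})["plaque_present"] is False
        assert aggregate_phenotypes({})["plaque_present"] is None
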