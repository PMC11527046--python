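"""Object-detection evaluation for plaque bounding boxes.

Implements the evaluation protocol for an ultrasound plaque detector:
IoU between axis-aligned boxes, greedy confidence-ordered matching against
ground truth (COCO-style), image-level classification metrics from the
any-box-present confusion matrix, box-level precision/recall, average
precision at a fixed IoU threshold with all-point interpolation, tuning of
the confidence threshold, and aggregation of per-image detections into
per-individual plaque phenotypes.

Boxes use pixel coordinates with origin at the top-left and half-open
``[min, max)`` extents, so the area of ``(x_min, y_min, x_max, y_max)`` is
``(x_max - x_min) * (y_max - y_min)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CONF_THRESHOLD = 0.13
DEFAULT_IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class Box:
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("box must have positive width and height")
        if self.confidence is not None and not (0.0 < self.confidence <= 1.0):
            raise ValueError("confidence must lie in (0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @classmethod
    def from_dict(cls, d: dict) -> "Box":
        return cls(d["x_min"], d["y_min"], d["x_max"], d["y_max"], d.get("confidence"))


@dataclass
class MatchResult:
    """Per-image matching outcome: matched (gt, pred, iou) triples plus
    the indices of unmatched ground truths (FN) and predictions (FP)."""

    pairs: list = field(default_factory=list)
    unmatched_gt: list = field(default_factory=list)
    unmatched_pred: list = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def n_fn(self) -> int:
        return len(self.unmatched_gt)


def box_iou(a: Box | dict, b: Box | dict) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint boxes."""
    if isinstance(a, dict):
        a = Box.from_dict(a)
    if isinstance(b, dict):
        b = Box.from_dict(b)
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _as_boxes(boxes) -> list:
    return [Box.from_dict(b) if isinstance(b, dict) else b for b in boxes]


def match_detections(
    gt,
    preds,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy confidence-ordered matching of predictions to ground truth.

    Predictions below ``conf_threshold`` are discarded.  Survivors are
    visited in descending confidence, each taking its highest-IoU still
    unmatched ground truth provided IoU >= ``iou_threshold``; ties in
    confidence break by input order.
    """
    gt = _as_boxes(gt)
    preds = _as_boxes(preds)
    kept = [i for i, p in enumerate(preds) if (p.confidence or 1.0) >= conf_threshold]
    order = sorted(kept, key=lambda i: -(preds[i].confidence or 1.0))
    matched_gt: set = set()
    result = MatchResult()
    for pi in order:
        best_iou, best_gi = 0.0, None
        for gi, g in enumerate(gt):
            if gi in matched_gt:
                continue
            iou = box_iou(g, preds[pi])
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi is None:
            result.unmatched_pred.append(pi)
        else:
            matched_gt.add(best_gi)
            result.pairs.append((best_gi, pi, best_iou))
    result.unmatched_gt = [gi for gi in range(len(gt)) if gi not in matched_gt]
    return result


def image_classification_metrics(gt_positive, pred_positive) -> dict:
    """Image-level 2x2 metrics: an image counts as predicted positive when
    any box survives thresholding.  PPV is ``None`` (missing) when no image
    is predicted positive; likewise sensitivity/specificity on empty margins."""
    gt_positive = np.asarray(gt_positive, dtype=bool)
    pred_positive = np.asarray(pred_positive, dtype=bool)
    if gt_positive.size == 0:
        raise ValueError("need at least one image")
    if gt_positive.shape != pred_positive.shape:
        raise ValueError("flag vectors must have equal length")
    tp = int(np.sum(gt_positive & pred_positive))
    fp = int(np.sum(~gt_positive & pred_positive))
    fn = int(np.sum(gt_positive & ~pred_positive))
    tn = int(np.sum(~gt_positive & ~pred_positive))
    n = tp + fp + fn + tn

    def _ratio(num, den):
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def detection_pr(matches) -> dict:
    """Box-level precision and recall pooled over a set of MatchResults."""
    if isinstance(matches, MatchResult):
        matches = [matches]
    tp = sum(m.n_tp for m in matches)
    fp = sum(m.n_fp for m in matches)
    fn = sum(m.n_fn for m in matches)
    return {
        "precision": tp / (tp + fp) if tp + fp > 0 else None,
        "recall": tp / (tp + fn) if tp + fn > 0 else None,
    }


def average_precision_50(
    annotations: list,
    predictions: list,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> float | None:
    """Single-class average precision at the given IoU threshold.

    All predictions across images are ranked by confidence; each is a TP if
    it matches a still-unmatched ground-truth box of its image with
    IoU >= threshold (highest IoU first).  AP is the area under the
    precision-recall curve with the all-point interpolation (precision
    envelope).  Returns ``None`` when there are no ground-truth boxes.
    """
    gt_by_image = {r["image_id"]: _as_boxes(r["boxes"]) for r in annotations}
    n_gt = sum(len(b) for b in gt_by_image.values())
    if n_gt == 0:
        return None
    ranked = []
    for rec in predictions:
        for b in _as_boxes(rec["boxes"]):
            ranked.append((b.confidence if b.confidence is not None else 1.0, rec["image_id"], b))
    ranked.sort(key=lambda t: -t[0])
    matched: dict = {img: set() for img in gt_by_image}
    tp_flags = []
    for _, img, pred in ranked:
        gts = gt_by_image.get(img, [])
        best_iou, best_gi = 0.0, None
        for gi, g in enumerate(gts):
            if gi in matched.setdefault(img, set()):
                continue
            iou = box_iou(g, pred)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi is None:
            tp_flags.append(0)
        else:
            matched[img].add(best_gi)
            tp_flags.append(1)
    if not tp_flags:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1 - np.asarray(tp_flags))
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope + integration over recall steps (all-point interpolation)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    return float(np.sum((r[1:] - r[:-1]) * env))


def tune_confidence_threshold(
    annotations: list,
    predictions: list,
    grid,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> float:
    """Grid value maximising the unweighted mean of image-level accuracy,
    sensitivity and specificity; ties resolve to the lowest threshold."""
    grid = sorted(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    gt_pos = [len(r["boxes"]) > 0 for r in annotations]
    best_t, best_score = None, -np.inf
    for t in grid:
        pred_pos = [
            any((b.get("confidence", 1.0) if isinstance(b, dict) else (b.confidence or 1.0)) >= t
                for b in rec["boxes"])
            for rec in predictions
        ]
        m = image_classification_metrics(gt_pos, pred_pos)
        parts = [m["accuracy"], m["sensitivity"], m["specificity"]]
        score = np.mean([0.0 if v is None else v for v in parts])
        if score > best_score:  # strict: earlier (lower) grid value wins ties
            best_t, best_score = t, score
    return best_t


def aggregate_phenotypes(images_by_artery: dict, seed: int = 0) -> dict:
    """Aggregate per-image box counts into an individual's plaque phenotype.

    ``images_by_artery`` maps artery name (e.g. ``"left"``/``"right"``) to a
    list of per-image box counts or box lists.  Per artery one image is
    selected: plaque-positive images are prioritised, and among several
    positives a seeded-random one is used.  The individual's count is the
    sum over arteries; presence is count >= 1.
    """
    if not images_by_artery or all(len(v) == 0 for v in images_by_artery.values()):
        return {"plaque_present": None, "plaque_count": None, "per_artery": {}}
    rng = np.random.default_rng(seed)
    per_artery = {}
    for artery, images in images_by_artery.items():
        if len(images) == 0:
            per_artery[artery] = 0
            continue
        counts = [img if isinstance(img, int) else len(img) for img in images]
        positive = [c for c in counts if c > 0]
        if not positive:
            per_artery[artery] = 0
        elif len(positive) == 1:
            per_artery[artery] = positive[0]
        else:
            per_artery[artery] = int(positive[rng.integers(len(positive))])
    total = sum(per_artery.values())
    return {"plaque_present": total >= 1, "plaque_count": total, "per_artery": per_artery}
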