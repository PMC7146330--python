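"""Detection-quality evaluation against VOC-style ground truth.

Implements the PASCAL VOC evaluation protocol: a prediction is a true
positive (TP) when its IoU with a same-class ground-truth box reaches the
matching threshold ``thr_iou`` (default 0.5) and that ground-truth box has
not already been claimed by a more confident prediction; otherwise it is a
false positive (FP).  Ground-truth objects left unmatched are false
negatives (FN).  From TP/FP/FN follow precision, recall and the F1 score;
per-class average precision (AP) is the area under the monotone
(interpolated) precision envelope over recall, and mAP its unweighted mean
over classes.

The operating threshold Cthr1 is chosen by sweeping the confidence cutoff
from 0% to 100% in 1% steps and keeping the cutoff with the highest F1
(ties resolved toward the lowest cutoff, which retains more detections).

Also provides the 10-fold cross-validation splitter in which each run tests
on two consecutive folds (20% of the items) and trains on the remaining
eight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Literal, Sequence

import numpy as np

from .geometry import Detection, FrameAnnotation, GroundTruthObject, iou
from .nms import filter_by_confidence

DEFAULT_IOU_THRESHOLD = 0.5


@dataclass
class MatchResult:
    """Outcome of matching predictions to ground truth at one threshold."""

    tp: list[tuple[Detection, GroundTruthObject]] = field(default_factory=list)
    fp: list[Detection] = field(default_factory=list)
    fn_count: dict[str, int] = field(default_factory=dict)

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return sum(self.fn_count.values())


@dataclass
class EvaluationReport:
    """Per-class AP, mAP and the full confidence-sweep curves."""

    per_class_ap: dict[str, float]
    map_score: float
    sweep: list[tuple[int, float, float, float]]  # (threshold %, P, R, F1)
    optimal_cthr1: int
    best_f1: float

    def to_dict(self) -> dict:
        return {
            "per_class_ap": self.per_class_ap,
            "mAP": self.map_score,
            "sweep": [
                {"cthr1": t, "precision": p, "recall": r, "f1": f}
                for t, p, r, f in self.sweep
            ],
            "optimal_cthr1": self.optimal_cthr1,
            "best_f1": self.best_f1,
        }


def _validate_thr(thr_iou: float) -> None:
    if not 0.0 < thr_iou < 1.0:
        raise ValueError(f"thr_iou must be a fraction in (0, 1), got {thr_iou}")


def match_predictions(
    preds: Sequence[Detection],
    gts: Sequence[FrameAnnotation],
    thr_iou: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Classify every prediction as TP or FP and count per-class FNs.

    Within each frame and class, predictions sorted by descending confidence
    are greedily assigned to the unmatched ground-truth box of the same
    class with highest IoU >= ``thr_iou``; a ground-truth box is matched at
    most once, so a duplicate detection of an already-claimed object is an
    FP.  Cross-class overlap can never produce a TP.
    """
    _validate_thr(thr_iou)
    result = MatchResult()

    gt_by_frame: dict[int, list[GroundTruthObject]] = {ann.frame_id: list(ann.objects) for ann in gts}
    preds_by_frame: dict[int, list[Detection]] = {}
    for d in preds:
        preds_by_frame.setdefault(d.frame_id, []).append(d)

    for frame_id, frame_gts in gt_by_frame.items():
        frame_preds = preds_by_frame.get(frame_id, [])
        matched = [False] * len(frame_gts)
        for det in sorted(frame_preds, key=lambda d: -d.confidence):
            best_j, best_iou = -1, 0.0
            for j, gt in enumerate(frame_gts):
                if matched[j] or gt.class_label != det.class_label:
                    continue
                v = iou(det.box, gt.box)
                if v >= thr_iou and v > best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                matched[best_j] = True
                result.tp.append((det, frame_gts[best_j]))
            else:
                result.fp.append(det)
        for j, gt in enumerate(frame_gts):
            if not matched[j]:
                result.fn_count[gt.class_label] = result.fn_count.get(gt.class_label, 0) + 1

    # predictions on frames with no annotation entry are all FPs
    annotated = set(gt_by_frame)
    for frame_id, frame_preds in preds_by_frame.items():
        if frame_id not in annotated:
            result.fp.extend(sorted(frame_preds, key=lambda d: -d.confidence))
    return result


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN); 0 when the denominator is 0."""
    tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    preds: Sequence[Detection],
    gts: Sequence[FrameAnnotation],
    class_label: str,
    thr_iou: float = DEFAULT_IOU_THRESHOLD,
    interpolation: Literal["all_points", "11_points"] = "all_points",
) -> float:
    """Average precision for one class.

    All detections of the class are ranked by descending confidence across
    frames; walking down the ranking, each is matched greedily to the
    unmatched same-class ground-truth box with highest IoU >= ``thr_iou``
    in its frame, yielding a TP/FP flag per rank and hence a cumulative
    precision–recall staircase.  AP is the area under the monotone
    (non-increasing) precision envelope over recall in [0, 1]
    (``all_points``, the VOC2010+ rule), or the mean of the envelope
    sampled at recall = 0, 0.1, ..., 1.0 (``11_points``).

    Raises ``ValueError`` when no ground-truth object of the class exists
    (AP is undefined there).
    """
    _validate_thr(thr_iou)
    gt_by_frame: dict[int, list[GroundTruthObject]] = {}
    n_gt = 0
    for ann in gts:
        cls_objs = [o for o in ann.objects if o.class_label == class_label]
        gt_by_frame[ann.frame_id] = cls_objs
        n_gt += len(cls_objs)
    if n_gt == 0:
        raise ValueError(f"AP undefined: no ground-truth objects of class {class_label!r}")

    ranked = sorted(
        (d for d in preds if d.class_label == class_label),
        key=lambda d: -d.confidence,
    )
    matched: dict[int, list[bool]] = {
        fid: [False] * len(objs) for fid, objs in gt_by_frame.items()
    }
    tp_flags = np.zeros(len(ranked), dtype=bool)
    for rank, det in enumerate(ranked):
        objs = gt_by_frame.get(det.frame_id, [])
        taken = matched.get(det.frame_id, [])
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(objs):
            if taken[j]:
                continue
            v = iou(det.box, gt.box)
            if v >= thr_iou and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            tp_flags[rank] = True

    if len(ranked) == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    return _staircase_area(recall, precision, interpolation)


def _staircase_area(
    recall: np.ndarray,
    precision: np.ndarray,
    interpolation: str,
) -> float:
    # monotone envelope: p_interp(r) = max precision at recall >= r
    r = np.concatenate(([0.0], recall, [1.0]))
    p = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    if interpolation == "all_points":
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    if interpolation == "11_points":
        # envelope evaluated at recall = 0.0, 0.1, ..., 1.0
        vals = []
        for t in np.linspace(0, 1, 11):
            mask = r >= t - 1e-12
            vals.append(float(p[mask].max()) if mask.any() else 0.0)
        return float(np.mean(vals))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_average_precision(
    preds: Sequence[Detection],
    gts: Sequence[FrameAnnotation],
    classes: Sequence[str],
    thr_iou: float = DEFAULT_IOU_THRESHOLD,
    interpolation: Literal["all_points", "11_points"] = "all_points",
) -> float:
    """Unweighted mean of per-class AP over ``classes``.

    Raises ``ValueError`` if AP is undefined for any listed class.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    aps = [average_precision(preds, gts, c, thr_iou, interpolation) for c in classes]
    return float(np.mean(aps))


def confidence_sweep(
    preds: Sequence[Detection],
    gts: Sequence[FrameAnnotation],
    thr_iou: float = DEFAULT_IOU_THRESHOLD,
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Sweep the confidence cutoff Cthr1 from 0% to 100% in 1% steps.

    For each of the 101 cutoffs, predictions with lower confidence are
    removed and precision/recall/F1 are recomputed from a fresh matching
    (so true positives removed by the cutoff count as false negatives).
    The optimal Cthr1 attains the maximum F1; ties resolve to the lowest
    cutoff.  Per-class AP and mAP are computed over ``classes`` (default:
    every class present in the ground truth).
    """
    _validate_thr(thr_iou)
    if classes is None:
        classes = sorted({o.class_label for ann in gts for o in ann.objects})

    sweep: list[tuple[int, float, float, float]] = []
    best_thr, best_f1 = 0, -1.0
    for threshold in range(0, 101):
        kept = filter_by_confidence(preds, threshold)
        m = match_predictions(kept, gts, thr_iou)
        p, r = precision_recall(m)
        f = f1_score(p, r)
        sweep.append((threshold, p, r, f))
        if f > best_f1:
            best_thr, best_f1 = threshold, f

    per_class_ap = {c: average_precision(preds, gts, c, thr_iou) for c in classes}
    map_score = float(np.mean(list(per_class_ap.values()))) if per_class_ap else 0.0
    return EvaluationReport(
        per_class_ap=per_class_ap,
        map_score=map_score,
        sweep=sweep,
        optimal_cthr1=best_thr,
        best_f1=best_f1,
    )


def kfold_split(
    item_ids: Sequence[Hashable],
    k: int = 10,
    seed: int | None = None,
) -> list[tuple[list, list]]:
    """Cross-validation splits with two consecutive test folds per run.

    The items are shuffled deterministically by ``seed`` and cut into ``k``
    folds of sizes differing by at most one.  Run ``i`` tests on folds
    ``i`` and ``(i+1) mod k`` (20% of the data for k=10) and trains on the
    remaining folds (80%), so each item appears in exactly two test sets
    across the k runs.
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    items = list(item_ids)
    if len(items) < k:
        raise ValueError(f"need at least k={k} items, got {len(items)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(items[idx])
    splits = []
    for i in range(k):
        test = folds[i] + folds[(i + 1) % k]
        train = [x for j in range(k) if j not in (i, (i + 1) % k) for x in folds[j]]
        splits.append((train, test))
    return splits
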