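"""Post-inference cleanup: non-maxima suppression and confidence filtering.

A detector typically emits several overlapping boxes for one animal.  NMS
keeps, within each cluster of mutually overlapping detections, only the most
confident one.  Suppression is greedy by descending confidence and
class-agnostic: jellyfish of different species essentially never appear
superimposed, so overlap is a purely geometric signal regardless of label.

The default overlap measure is IoU with a threshold of 0.40 — restrictive,
because true superimposition is rare in this application (typical NMS
thresholds run 30–70%).  Intersection-over-min-area is available as an
alternative reading of an "intersection area" threshold.
"""

from __future__ import annotations

from typing import Callable, Literal, Sequence

from .geometry import BoundingBox, Detection, intersection_over_min_area, iou

DEFAULT_NMS_THRESHOLD = 0.40

_OVERLAP_MEASURES: dict[str, Callable[[BoundingBox, BoundingBox], float]] = {
    "iou": iou,
    "iom": intersection_over_min_area,
}


def non_maxima_suppression(
    dets: Sequence[Detection],
    overlap_thr: float = DEFAULT_NMS_THRESHOLD,
    measure: Literal["iou", "iom"] = "iou",
) -> list[Detection]:
    """Greedy non-maxima suppression over the detections of a single frame.

    Detections are visited in order of descending confidence (ties broken by
    input order, then lower xmin, for determinism); each kept detection
    suppresses every remaining detection whose overlap with it exceeds
    ``overlap_thr``.  The result is a subset of the input in which no
    surviving pair overlaps more than the threshold, and within any
    suppressed cluster the highest-confidence member survives.

    Idempotent: applying it twice equals applying it once.

    Raises ``ValueError`` if detections come from mixed frames or the
    threshold is not a fraction in (0, 1).
    """
    if not 0.0 < overlap_thr < 1.0:
        raise ValueError(f"overlap_thr must be in (0, 1), got {overlap_thr}")
    if measure not in _OVERLAP_MEASURES:
        raise ValueError(f"unknown overlap measure {measure!r}")
    if not dets:
        return []
    frame_ids = {d.frame_id for d in dets}
    if len(frame_ids) > 1:
        raise ValueError(
            f"non_maxima_suppression expects detections of one frame, got {sorted(frame_ids)}"
        )
    overlap = _OVERLAP_MEASURES[measure]

    order = sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].confidence, i, dets[i].box.xmin),
    )
    kept: list[int] = []
    suppressed = [False] * len(dets)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in order:
            if j != i and not suppressed[j]:
                if overlap(dets[i].box, dets[j].box) > overlap_thr:
                    suppressed[j] = True
    kept.sort()  # preserve the input order of survivors
    return [dets[i] for i in kept]


def nms_stream(frames, overlap_thr: float = DEFAULT_NMS_THRESHOLD, measure: str = "iou"):
    """Apply NMS frame by frame over ``(frame_id, detections)`` pairs."""
    return [
        (fid, non_maxima_suppression(dets, overlap_thr, measure))
        for fid, dets in frames
    ]


def filter_by_confidence(dets: Sequence[Detection], threshold: float) -> list[Detection]:
    """Keep detections whose confidence (in percent) is >= ``threshold``.

    ``threshold`` is a percentage in [0, 100], matching how confidence
    thresholds (Cthr1/Cthr2) are quoted in reports.  Instances with a
    confidence strictly lower than the threshold are deleted; order is
    preserved.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be a percentage in [0, 100], got {threshold}")
    cutoff = threshold / 100.0
    return [d for d in dets if d.confidence >= cutoff]
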