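"""Shared domain types and the intersection-over-union computation.

Boxes use a continuous, half-open pixel convention: a box covers the region
``[xmin, xmax) x [ymin, ymax)`` with the origin at the image's top-left
corner, so ``area = (xmax - xmin) * (ymax - ymin)`` exactly.  PASCAL VOC
1-based inclusive integer coordinates are converted at the I/O boundary
(see :mod:`jellyquant.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent box geometry."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel coordinates, half-open [min, max)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise GeometryError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class Detection:
    """One predicted instance: the unit of NMS, matching and counting."""

    frame_id: int
    class_label: str
    confidence: float
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame_id < 0:
            raise ValueError(f"frame_id must be non-negative, got {self.frame_id}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence must be a fraction in [0, 1], got {self.confidence}"
            )


@dataclass(frozen=True)
class GroundTruthObject:
    """One annotated instance: species label plus bounding box."""

    class_label: str
    box: BoundingBox


@dataclass
class FrameAnnotation:
    """Ground-truth objects of one image/frame (a LabelImg .xml file's content)."""

    frame_id: int
    image_width: int
    image_height: int
    objects: list[GroundTruthObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        for obj in self.objects:
            b = obj.box
            if b.xmin < 0 or b.ymin < 0 or b.xmax > self.image_width or b.ymax > self.image_height:
                raise GeometryError(
                    f"object box {b.as_tuple()} outside image "
                    f"{self.image_width}x{self.image_height}"
                )

    def count_by_class(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for obj in self.objects:
            counts[obj.class_label] = counts.get(obj.class_label, 0) + 1
        return counts


def intersection_area(a: BoundingBox, b: BoundingBox) -> float:
    """Area of the overlap region of two boxes; 0 when disjoint."""
    w = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    h = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, a fraction in [0, 1].

    IoU = A_intersection / A_union, where the union area is
    area(a) + area(b) - A_intersection.  Returns 0 for disjoint boxes and 1
    only for identical boxes.  Degenerate boxes cannot be constructed
    (:class:`BoundingBox` rejects them), so the denominator is always > 0.
    """
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def intersection_over_min_area(a: BoundingBox, b: BoundingBox) -> float:
    """Overlap of two boxes relative to the smaller box's area.

    Alternative overlap measure for NMS: reads an "intersection area"
    threshold as a fraction of the smaller box, so a small box fully inside
    a large one scores 1.
    """
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / min(a.area, b.area)
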