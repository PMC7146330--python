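"""Seeded simulator of monitoring scenes and imperfect detector output.

The scene model emulates a fixed underwater camera watching free-swimming
jellyfish: per species, individuals enter the field of view as a Poisson
process, stay for an exponentially distributed dwell time, and drift as a
reflected Gaussian random walk inside the image, so per-frame counts form a
birth–death process whose mean simultaneous count is
``arrival_rate * dwell_mean`` per species (Little's law) and which changes
on the time scale of minutes.

The detector model reproduces the failure modes of a real network under
changing illumination and turbidity: each true instance is sporadically
missed (``p_miss``), surviving instances get a jittered box, an occasional
species swap (``p_confuse``) and a confidence drawn from a high-concentrated
Beta law (true detections are mostly high-confidence); spurious false
detections appear as a per-frame Poisson stream with low-skewed Beta
confidences.  The separation between the two confidence laws is what lets a
low quantification cutoff beat a high one once windowing has removed the
spurious detections.

All randomness flows from a single seeded generator in documented order
(species by species for the scene; frame by frame, objects before false
positives, for the detector), so fixtures are byte-stable given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import (
    CountTimeline,
    DEFAULT_CLASSES,
    DetectionStream,
    write_count_timeline,
    write_detections,
    write_voc_annotation,
)
from .geometry import BoundingBox, Detection, FrameAnnotation, GroundTruthObject


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth scene parameters.

    Defaults describe a ten-minute clip analysed at 1.6 frames/second in
    which a handful of animals drift in and out of view: per species,
    arrivals at 0.0015 individuals/second (about one entry per 11 minutes)
    dwelling 150 s on average, i.e. counts that evolve slowly over minutes
    with rarely more than one or two individuals per species at once.
    """

    duration: float = 600.0  # seconds
    fps: float = 1.6  # analysed frames per second
    image_width: int = 1280
    image_height: int = 720
    classes: tuple[str, ...] = DEFAULT_CLASSES
    arrival_rate: float = 0.0015  # individuals / second / species
    dwell_mean: float = 150.0  # seconds
    box_size_range: tuple[float, float] = (60.0, 200.0)  # pixels
    motion_step: float = 4.0  # random-walk step scale, pixels / frame

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        if self.arrival_rate < 0 or self.dwell_mean <= 0:
            raise ValueError("arrival_rate must be >= 0 and dwell_mean > 0")
        lo, hi = self.box_size_range
        if not 0 < lo <= hi <= min(self.image_width, self.image_height):
            raise ValueError(f"box_size_range {self.box_size_range} must fit the image")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass(frozen=True)
class DetectorModel:
    """Stochastic model of an imperfect detector.

    ``tp_confidence`` / ``fp_confidence`` are Beta(a, b) shape parameters
    for true/spurious detections; the defaults concentrate true detections
    near 1 and spurious ones near 0.
    """

    p_miss: float = 0.1  # per-instance per-frame miss probability
    fp_rate: float = 0.05  # expected spurious detections per frame (Poisson)
    tp_confidence: tuple[float, float] = (14.0, 2.5)
    fp_confidence: tuple[float, float] = (1.5, 8.0)
    box_jitter: float = 3.0  # pixel sd added to each box edge
    p_confuse: float = 0.01  # probability of a species swap

    def __post_init__(self) -> None:
        for p in (self.p_miss, self.p_confuse):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fp_rate < 0 or self.box_jitter < 0:
            raise ValueError("fp_rate and box_jitter must be non-negative")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    if hi <= lo:
        return np.full_like(x, lo)
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def generate_scene(
    params: SceneParams, seed: int | None = None
) -> tuple[list[FrameAnnotation], CountTimeline]:
    """Simulate ground truth: one annotation per frame plus the count timeline.

    Per species, individuals arrive as a Poisson process over the scene
    duration and dwell for an exponential time; each individual's box does a
    reflected Gaussian random walk inside the image.  The returned timeline
    equals the per-frame box counts exactly.
    """
    rng = np.random.default_rng(seed)
    n_frames = params.n_frames
    frame_objects: list[list[GroundTruthObject]] = [[] for _ in range(n_frames)]

    for cls in params.classes:
        n_arrivals = rng.poisson(params.arrival_rate * params.duration)
        arrival_times = np.sort(rng.uniform(0.0, params.duration, n_arrivals))
        for t0 in arrival_times:
            dwell = rng.exponential(params.dwell_mean)
            w = rng.uniform(*params.box_size_range)
            h = rng.uniform(*params.box_size_range)
            first = int(np.ceil(t0 * params.fps))
            last = int(np.floor(min(t0 + dwell, params.duration) * params.fps))
            last = min(last, n_frames - 1)
            if first > last:
                continue
            n_active = last - first + 1
            cx0 = rng.uniform(w / 2.0, params.image_width - w / 2.0)
            cy0 = rng.uniform(h / 2.0, params.image_height - h / 2.0)
            steps = rng.normal(0.0, params.motion_step, size=(n_active, 2))
            steps[0] = 0.0
            cx = _reflect(cx0 + np.cumsum(steps[:, 0]), w / 2.0, params.image_width - w / 2.0)
            cy = _reflect(cy0 + np.cumsum(steps[:, 1]), h / 2.0, params.image_height - h / 2.0)
            for i, frame in enumerate(range(first, last + 1)):
                box = BoundingBox(
                    cx[i] - w / 2.0, cy[i] - h / 2.0, cx[i] + w / 2.0, cy[i] + h / 2.0
                )
                frame_objects[frame].append(GroundTruthObject(class_label=cls, box=box))

    annotations = [
        FrameAnnotation(
            frame_id=f,
            image_width=params.image_width,
            image_height=params.image_height,
            objects=objs,
        )
        for f, objs in enumerate(frame_objects)
    ]
    entries = []
    for ann in annotations:
        counts = {c: 0 for c in params.classes}
        counts.update(ann.count_by_class())
        entries.append((ann.frame_id, counts))
    timeline = CountTimeline(classes=params.classes, entries=entries)
    return annotations, timeline


def corrupt_to_detections(
    gt: Sequence[FrameAnnotation],
    model: DetectorModel,
    fps: float,
    seed: int | None = None,
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> DetectionStream:
    """Pass ground truth through the imperfect-detector model.

    Frame by frame: each true box is dropped with ``p_miss`` or emitted with
    jittered edges, a possible species swap and a Beta-distributed
    confidence; then Poisson(``fp_rate``) spurious detections with random
    boxes and low confidences are appended.  Fully reproducible given the
    seed.
    """
    rng = np.random.default_rng(seed)
    tp_a, tp_b = model.tp_confidence
    fp_a, fp_b = model.fp_confidence
    classes = tuple(classes)
    frames: list[tuple[int, list[Detection]]] = []
    for ann in gt:
        dets: list[Detection] = []
        W, H = ann.image_width, ann.image_height
        for obj in ann.objects:
            if rng.random() < model.p_miss:
                continue
            b = obj.box
            if model.box_jitter > 0:
                dx = rng.normal(0.0, model.box_jitter, 4)
            else:
                dx = np.zeros(4)
            xmin = float(np.clip(b.xmin + dx[0], 0.0, W - 1.0))
            ymin = float(np.clip(b.ymin + dx[1], 0.0, H - 1.0))
            xmax = float(np.clip(b.xmax + dx[2], xmin + 1.0, W))
            ymax = float(np.clip(b.ymax + dx[3], ymin + 1.0, H))
            label = obj.class_label
            if model.p_confuse > 0 and rng.random() < model.p_confuse:
                others = [c for c in classes if c != label]
                if others:
                    label = others[rng.integers(len(others))]
            conf = float(np.clip(rng.beta(tp_a, tp_b), 0.0, 1.0))
            dets.append(
                Detection(
                    frame_id=ann.frame_id,
                    class_label=label,
                    confidence=conf,
                    box=BoundingBox(xmin, ymin, xmax, ymax),
                )
            )
        for _ in range(rng.poisson(model.fp_rate)):
            w = rng.uniform(0.03 * W, 0.25 * W)
            h = rng.uniform(0.03 * H, 0.25 * H)
            x0 = rng.uniform(0.0, W - w)
            y0 = rng.uniform(0.0, H - h)
            dets.append(
                Detection(
                    frame_id=ann.frame_id,
                    class_label=classes[rng.integers(len(classes))],
                    confidence=float(np.clip(rng.beta(fp_a, fp_b), 0.0, 1.0)),
                    box=BoundingBox(x0, y0, x0 + w, y0 + h),
                )
            )
        frames.append((ann.frame_id, dets))
    return DetectionStream(fps=fps, frames=frames)


def write_fixture_bundle(
    annotations: Sequence[FrameAnnotation],
    timeline: CountTimeline,
    detections: DetectionStream,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: VOC XMLs, detections JSONL, truth CSV.

    Returns the paths written, all readable back through the format readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_dir = out_dir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    for ann in annotations:
        write_voc_annotation(ann, ann_dir / f"frame_{ann.frame_id:06d}.xml")
    det_path = out_dir / "detections.jsonl"
    write_detections(detections, det_path)
    truth_path = out_dir / "truth.csv"
    write_count_timeline(timeline, truth_path)
    return {"annotations": ann_dir, "detections": det_path, "truth": truth_path}
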