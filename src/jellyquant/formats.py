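"""Readers and writers for on-disk artifacts.

Four formats are supported:

* **PASCAL VOC XML** annotations in the LabelImg dialect, one file per
  image/frame.  VOC stores 1-based inclusive integer pixel coordinates;
  internally boxes are half-open and 0-based, so on read
  ``xmin_internal = xmin_voc - 1`` and ``xmax_internal = xmax_voc`` (same
  for y), and the inverse on write.  This conversion is its own inverse for
  integer-aligned boxes.
* **Detection streams** as JSON lines: a header line
  ``{"fps": <rate>, "frame_ids": [...]}`` (the frame list preserves frames
  in which nothing was detected) followed by one record per detection
  ``{"frame": i, "class": name, "confidence": c, "bbox": [xmin, ymin, xmax, ymax]}``.
  Streaming-friendly and appendable, which suits the real-time use case.
* **Count timelines** as CSV with a ``frame_id`` column plus one integer
  column per species, serialising the manually labelled per-frame counts.
* **Run configuration** as YAML.

Class vocabulary is configuration, defaulting to the three Mediterranean
jellyfish species under study; unknown labels are an error, never silently
added.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET

import pandas as pd
import yaml

from .geometry import BoundingBox, Detection, FrameAnnotation, GroundTruthObject

DEFAULT_CLASSES: tuple[str, ...] = (
    "Pelagia noctiluca",
    "Rhizostoma pulmo",
    "Cotylorhiza tuberculata",
)


class FormatError(ValueError):
    """Raised when an on-disk artifact cannot be parsed."""


def _check_classes(labels: Iterable[str], classes: Sequence[str] | None, where: str) -> None:
    if classes is None:
        return
    allowed = set(classes)
    for lab in labels:
        if lab not in allowed:
            raise FormatError(f"{where}: unknown class label {lab!r}; configured classes: {sorted(allowed)}")


@dataclass
class DetectionStream:
    """Ordered per-frame detections together with the analysis frame rate.

    ``fps`` is the rate at which frames were analysed (frames/second),
    which sets the wall-clock meaning of a frame index.  Frame ids are
    strictly increasing.
    """

    fps: float
    frames: list[tuple[int, list[Detection]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        ids = [fid for fid, _ in self.frames]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame_ids must be strictly increasing")

    def all_detections(self) -> list[Detection]:
        return [d for _, dets in self.frames for d in dets]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class CountTimeline:
    """Ordered per-frame ground-truth counts, one entry per analysed frame."""

    classes: tuple[str, ...]
    entries: list[tuple[int, dict[str, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.entries]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame_ids must be strictly increasing")
        for fid, counts in self.entries:
            for cls in self.classes:
                if cls not in counts:
                    raise ValueError(f"frame {fid}: missing count for class {cls!r}")
            for cls, n in counts.items():
                if n < 0:
                    raise ValueError(f"frame {fid}: negative count for {cls!r}")

    def as_dict(self) -> dict[int, dict[str, int]]:
        return {fid: counts for fid, counts in self.entries}


# ---------------------------------------------------------------------------
# PASCAL VOC XML (LabelImg dialect)
# ---------------------------------------------------------------------------

def read_voc_annotation(
    path: str | Path,
    frame_id: int = 0,
    classes: Sequence[str] | None = None,
) -> FrameAnnotation:
    """Parse a LabelImg PASCAL VOC XML file into a :class:`FrameAnnotation`.

    VOC 1-based inclusive integers are converted to the internal half-open
    0-based convention.  ``frame_id`` is assigned by the caller (VOC files
    carry only a filename).  If ``classes`` is given, unknown object names
    raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "annotation":
        raise FormatError(f"{path}: expected <annotation> root, got <{root.tag}>")
    size = root.find("size")
    if size is None:
        raise FormatError(f"{path}: missing <size> element")
    width = int(_required_text(size, "width", path))
    height = int(_required_text(size, "height", path))

    objects: list[GroundTruthObject] = []
    for obj in root.findall("object"):
        name = _required_text(obj, "name", path)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise FormatError(f"{path}: <object> '{name}' missing <bndbox>")
        xmin = float(_required_text(bnd, "xmin", path))
        ymin = float(_required_text(bnd, "ymin", path))
        xmax = float(_required_text(bnd, "xmax", path))
        ymax = float(_required_text(bnd, "ymax", path))
        # VOC -> internal: shift the inclusive minimum down by one pixel.
        box = _voc_to_internal(xmin, ymin, xmax, ymax, path)
        objects.append(GroundTruthObject(class_label=name, box=box))

    _check_classes((o.class_label for o in objects), classes, str(path))
    return FrameAnnotation(
        frame_id=frame_id, image_width=width, image_height=height, objects=objects
    )


def _required_text(parent: ET.Element, tag: str, path: Path) -> str:
    el = parent.find(tag)
    if el is None or el.text is None:
        raise FormatError(f"{path}: missing <{tag}> element")
    return el.text.strip()


def _voc_to_internal(
    xmin: float, ymin: float, xmax: float, ymax: float, path: Path
) -> BoundingBox:
    ixmin, iymin = xmin - 1.0, ymin - 1.0
    if xmax <= ixmin or ymax <= iymin:
        raise FormatError(
            f"{path}: bndbox ({xmin}, {ymin}, {xmax}, {ymax}) degenerate after conversion"
        )
    return BoundingBox(ixmin, iymin, xmax, ymax)


def write_voc_annotation(
    annotation: FrameAnnotation,
    path: str | Path,
    filename: str | None = None,
) -> None:
    """Write a :class:`FrameAnnotation` as LabelImg-style VOC XML.

    Internal coordinates are converted back to 1-based inclusive integers
    and rounded to the nearest integer, as LabelImg writes integers.
    """
    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = path.parent.name or "."
    ET.SubElement(root, "filename").text = filename or f"frame_{annotation.frame_id:06d}.jpg"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(annotation.image_width)
    ET.SubElement(size, "height").text = str(annotation.image_height)
    ET.SubElement(size, "depth").text = "3"
    for obj in annotation.objects:
        o = ET.SubElement(root, "object")
        ET.SubElement(o, "name").text = obj.class_label
        ET.SubElement(o, "pose").text = "Unspecified"
        ET.SubElement(o, "truncated").text = "0"
        ET.SubElement(o, "difficult").text = "0"
        b = ET.SubElement(o, "bndbox")
        ET.SubElement(b, "xmin").text = str(int(round(obj.box.xmin + 1.0)))
        ET.SubElement(b, "ymin").text = str(int(round(obj.box.ymin + 1.0)))
        ET.SubElement(b, "xmax").text = str(int(round(obj.box.xmax)))
        ET.SubElement(b, "ymax").text = str(int(round(obj.box.ymax)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


# ---------------------------------------------------------------------------
# Detection stream JSON lines
# ---------------------------------------------------------------------------

def read_detections(path: str | Path, classes: Sequence[str] | None = None) -> DetectionStream:
    """Read a JSON-lines detection stream.

    The first line must be a header object carrying ``fps``.  Records out of
    frame order are sorted with a warning; malformed records raise
    :class:`FormatError` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in (raw.strip() for raw in fh) if ln]
    if not lines:
        raise FormatError(f"{path}: empty file (expected an fps header line)")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}:1: malformed header: {exc}") from exc
    if "fps" not in header:
        raise FormatError(f"{path}:1: header must carry 'fps'")
    fps = float(header["fps"])
    # the header may enumerate every analysed frame, so frames in which no
    # detection survived still yield an (empty) entry on read
    declared = [int(f) for f in header.get("frame_ids", [])]

    by_frame: dict[int, list[Detection]] = {fid: [] for fid in declared}
    last_frame = None
    out_of_order = False
    for lineno, line in enumerate(lines[1:], start=2):
        try:
            rec = json.loads(line)
            frame = int(rec["frame"])
            label = str(rec["class"])
            conf = float(rec["confidence"])
            bbox = rec["bbox"]
            if len(bbox) != 4:
                raise ValueError(f"bbox must have 4 elements, got {len(bbox)}")
            det = Detection(
                frame_id=frame,
                class_label=label,
                confidence=conf,
                box=BoundingBox(*map(float, bbox)),
            )
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}:{lineno}: bad detection record: {exc}") from exc
        if last_frame is not None and frame < last_frame:
            out_of_order = True
        last_frame = frame
        by_frame.setdefault(frame, []).append(det)

    if out_of_order:
        warnings.warn(f"{path}: detection records out of frame order; sorted", stacklevel=2)
    _check_classes(
        (d.class_label for dets in by_frame.values() for d in dets), classes, str(path)
    )
    frames = [(fid, by_frame[fid]) for fid in sorted(by_frame)]
    return DetectionStream(fps=fps, frames=frames)


def write_detections(stream: DetectionStream, path: str | Path) -> None:
    """Write a detection stream as JSON lines (header line carries fps)."""
    with open(path, "w") as fh:
        header = {"fps": stream.fps, "frame_ids": [fid for fid, _ in stream.frames]}
        fh.write(json.dumps(header) + "\n")
        for frame_id, dets in stream.frames:
            for d in dets:
                rec = {
                    "frame": frame_id,
                    "class": d.class_label,
                    "confidence": round(d.confidence, 6),
                    "bbox": list(d.box.as_tuple()),
                }
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Count timeline CSV
# ---------------------------------------------------------------------------

def read_count_timeline(path: str | Path, classes: Sequence[str] | None = None) -> CountTimeline:
    """Read a per-frame count timeline CSV (``frame_id`` + one column per class)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "frame_id" not in df.columns:
        raise FormatError(f"{path}: missing 'frame_id' column")
    cols = [c for c in df.columns if c != "frame_id"]
    if classes is not None:
        missing = [c for c in classes if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing class columns {missing}")
        cols = list(classes)
    if (df[cols].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts are not allowed")
    frame_ids = df["frame_id"].astype(int).to_list()
    count_matrix = df[cols].astype(int).to_numpy()
    entries = [
        (fid, dict(zip(cols, map(int, row))))
        for fid, row in zip(frame_ids, count_matrix)
    ]
    return CountTimeline(classes=tuple(cols), entries=entries)


def write_count_timeline(timeline: CountTimeline, path: str | Path) -> None:
    rows = [{"frame_id": fid, **counts} for fid, counts in timeline.entries]
    df = pd.DataFrame(rows, columns=["frame_id", *timeline.classes])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML run configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
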