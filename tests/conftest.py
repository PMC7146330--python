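"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jellyquant import (
    BoundingBox,
    Detection,
    DetectorModel,
    SceneParams,
    corrupt_to_detections,
    generate_scene,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_box(rng: np.random.Generator, max_coord: int = 64) -> BoundingBox:
    """Random integer-aligned box within [0, max_coord]^2."""
    x0, y0 = rng.integers(0, max_coord - 1, 2)
    w = int(rng.integers(1, max_coord - x0))
    h = int(rng.integers(1, max_coord - y0))
    return BoundingBox(float(x0), float(y0), float(x0 + w), float(y0 + h))


def random_detections(
    rng: np.random.Generator,
    n: int,
    frame_id: int = 0,
    classes=("Pelagia noctiluca", "Rhizostoma pulmo"),
    max_coord: int = 64,
) -> list[Detection]:
    return [
        Detection(
            frame_id=frame_id,
            class_label=classes[rng.integers(len(classes))],
            confidence=float(rng.uniform(0.001, 0.999)),
            box=random_box(rng, max_coord),
        )
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def dense_scene():
    """A busy two-minute scene in which every species appears."""
    params = SceneParams(duration=120.0, arrival_rate=0.05, dwell_mean=30.0)
    annotations, timeline = generate_scene(params, seed=5)
    assert all(
        any(c[cls] > 0 for _, c in timeline.entries) for cls in params.classes
    ), "fixture must contain every species"
    return params, annotations, timeline


@pytest.fixture(scope="session")
def noiseless_detections(dense_scene):
    params, annotations, _ = dense_scene
    model = DetectorModel(p_miss=0.0, fp_rate=0.0, box_jitter=0.0, p_confuse=0.0)
    return corrupt_to_detections(annotations, model, fps=params.fps, seed=6, classes=params.classes)
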