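"""Shared fixtures: digitized reference shapes and a standard synthetic scene."""

from __future__ import annotations

import numpy as np
import pytest

from fibromet import segment, synthgen


def make_disk_mask(radius_px: float, pad: int = 3) -> np.ndarray:
    """Boolean mask of a digitized disk (pixel centers within radius)."""
    size = 2 * int(np.ceil(radius_px)) + 2 * pad + 1
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def make_ellipse_mask(a_px: float, b_px: float, theta: float = 0.0, pad: int = 3) -> np.ndarray:
    """Boolean mask of a digitized ellipse with semi-axes a_px >= b_px."""
    size = 2 * int(np.ceil(a_px)) + 2 * pad + 1
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - c
    y = yy - c
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def single_roi(mask: np.ndarray) -> segment.RoiObject:
    rois = segment.detect_objects(mask, 1)
    assert len(rois) == 1
    return rois[0]


def caliper_feret_bruteforce(points: np.ndarray, n_angles: int = 3600) -> float:
    """Independent feret oracle: max projection width over a dense angle scan."""
    ang = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    proj = points @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).max())


@pytest.fixture(scope="session")
def pixel_size() -> float:
    return 0.5


@pytest.fixture(scope="session")
def five_object_scene():
    """A 764×560 scene with 2 spindle + 3 signet objects and ground truth."""
    truth = synthgen.random_scene_truth(2, 3, seed=42)
    return synthgen.render_scene(truth)
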