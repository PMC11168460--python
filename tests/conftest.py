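"""Shared fixtures and independent oracles.

The oracles here re-derive quantities by deliberately simple means (manual
bilinear interpolation, direct pixel scans, textbook formulas) and never
call the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from beadpull.synth import BeadSceneSpec, BeadSpec, generate_bead_scene


def bilinear_oracle(image: np.ndarray, x: float, y: float) -> float:
    """Hand-rolled bilinear interpolation at (x, y), pixel centers at
    integers.  Independent of scipy.ndimage."""
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    rows, cols = image.shape

    def px(r: int, c: int) -> float:
        # clamp like 'nearest' edge handling
        return float(image[min(max(r, 0), rows - 1), min(max(c, 0), cols - 1)])

    return (
        px(y0, x0) * (1 - fx) * (1 - fy)
        + px(y0, x0 + 1) * fx * (1 - fy)
        + px(y0 + 1, x0) * (1 - fx) * fy
        + px(y0 + 1, x0 + 1) * fx * fy
    )


def ray_minmax_oracle(
    image: np.ndarray,
    center: tuple[float, float],
    angle: float,
    distances: np.ndarray,
) -> float:
    """Brute-force rasterized-ray score: sample the ray at the given grid
    points with the manual interpolator and scan min/max."""
    vals = [
        bilinear_oracle(
            image,
            center[0] + d * np.cos(angle),
            center[1] + d * np.sin(angle),
        )
        for d in distances
    ]
    return max(vals) - min(vals)


def disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Boolean disk: pixel centers within `radius` of (x, y)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - center[0], yy - center[1]) <= radius


def single_bead_scene(
    rim: float = 100.0,
    core: float = 0.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    radius: float = 20.0,
    rim_thickness: float = 3.0,
    channel: str = "EGFP",
):
    spec = BeadSceneSpec(
        image_shape=(120, 120),
        beads=[
            BeadSpec(
                center=(60.0, 60.0),
                radius=radius,
                rim_thickness=rim_thickness,
                rim_intensity={channel: rim},
                core_intensity={channel: core},
            )
        ],
        background_level={channel: background},
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_bead_scene(spec)


@pytest.fixture
def clean_bead_scene():
    """Noise-free single coated bead: rim 100, core 0, background 0."""
    return single_bead_scene()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
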