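"""Core in-memory containers shared by all image-analysis stages.

An :class:`ImageScene` is a set of named, equally shaped 2-D intensity
channels plus free-form acquisition metadata.  A :class:`SceneTruth` is the
machine-readable ground truth emitted alongside every synthetic scene: one
record per rendered object (bead or diffraction-limited spot) plus the
scene-level background and noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class ImageScene:
    """Named 2-D intensity channels of identical shape.

    Parameters
    ----------
    channels:
        Mapping from channel name (e.g. ``"mCherry"``, ``"EGFP"``) to a
        2-D float array of gray values.
    metadata:
        Acquisition metadata (position index, time point, channel order,
        seed, ...).  Round-tripped through TIFF tags by :mod:`beadpull.io`.
    """

    channels: dict[str, np.ndarray]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageScene requires at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"all channels must be 2-D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; scene has {self.channel_names}"
            ) from None


@dataclass
class SceneTruth:
    """Ground truth for a synthetic scene: one row per rendered object.

    ``objects`` columns: ``object_id``, ``kind`` (``bead`` | ``spot``),
    ``center_x``, ``center_y`` (px, 0-based, pixel-center convention),
    ``radius`` or ``sigma`` (px), one ``intensity_<channel>`` column per
    channel with the programmed peak/rim intensity, ``coloc`` flag for
    spots, and ``time_point`` where the scene belongs to a series.
    """

    objects: pd.DataFrame
    background: dict[str, float]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.objects) and self.objects["object_id"].duplicated().any():
            dup = self.objects.loc[
                self.objects["object_id"].duplicated(), "object_id"
            ].tolist()
            raise ValueError(f"duplicate object_ids in truth table: {dup}")

    @property
    def n_objects(self) -> int:
        return len(self.objects)
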