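"""Scene/table I/O and run configuration.

Scenes are stored as multi-channel TIFF, one file per position, channels
stacked on the first axis with the channel order recorded in the TIFF
description (JSON).  Label masks are 16-bit integer TIFF.  All tables are
comma-separated UTF-8 CSV with a header row and '.' decimal, which keeps
round-trip tests bit-exact.

:class:`RunConfig` holds every stage parameter with the package defaults;
unknown keys in a config file are rejected, and every pipeline run writes
the fully resolved config next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .scene import ImageScene

__all__ = [
    "read_scene",
    "write_scene",
    "read_label_mask",
    "write_label_mask",
    "RunConfig",
    "load_config",
]


def write_scene(scene: ImageScene, path: str | Path) -> Path:
    """Write a scene as a multi-channel float32 TIFF.

    Channels are stacked on axis 0 in ``scene.metadata["channel_order"]``
    order (falling back to insertion order); the order and all metadata go
    into the TIFF description as JSON.
    """
    path = Path(path)
    order = scene.metadata.get("channel_order", scene.channel_names)
    stack = np.stack([scene.channels[name] for name in order]).astype(np.float32)
    meta = {k: v for k, v in scene.metadata.items() if k != "channel_order"}
    desc = json.dumps({"channel_order": list(order), "metadata": meta})
    tifffile.imwrite(path, stack, description=desc)
    return path


def read_scene(
    path: str | Path, channel_map: list[str] | None = None
) -> ImageScene:
    """Read a multi-channel TIFF back into an :class:`ImageScene`.

    ``channel_map`` overrides the channel names stored in the file (useful
    for TIFFs produced elsewhere); its length must match the number of
    channels.  A 2-D file is treated as a single channel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        info = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        info = {}

    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"{path}: expected a 2-D or channel-stacked 3-D TIFF, "
            f"got shape {stack.shape}"
        )

    names = channel_map or info.get("channel_order")
    if names is None:
        names = [f"ch{i}" for i in range(stack.shape[0])]
    if len(names) != stack.shape[0]:
        missing = names[stack.shape[0]:] or ["<none>"]
        raise ValueError(
            f"{path}: channel map names {len(names)} channels but the file "
            f"has {stack.shape[0]}; unmatched: {missing}"
        )
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    metadata = dict(info.get("metadata", {}))
    metadata["channel_order"] = list(names)
    metadata["source_path"] = str(path)
    return ImageScene(channels, metadata)


def write_label_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Store an integer label mask as 16-bit TIFF."""
    path = Path(path)
    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError(
            f"mask has {mask.max()} labels; exceeds 16-bit storage"
        )
    tifffile.imwrite(path, mask.astype(np.uint16))
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise ValueError(f"{path}: label mask must be 2-D, got {mask.shape}")
    return mask.astype(np.int32)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters for an end-to-end pipeline run.

    Defaults are the package defaults for every stage.  ``simulate`` holds
    the synthetic-scene block (or is None when images are supplied).
    """

    mode: str = "beads"  # beads | condensates
    seed: int = 0
    out_dir: str = "run_out"
    images: list[str] = field(default_factory=list)
    channel: str = "EGFP"
    simulate: dict[str, Any] | None = None
    # bead-stage parameters
    n_lines: int = 8
    extension_frac: float = 0.2
    step: float = 1.0
    min_radius: float = 3.0
    # condensate-stage parameters
    ref_channel: str = "mCherry"
    probe_channel: str = "EGFP"
    rolling_ball_radius: float = 2.0
    threshold_policy: str = "otsu"
    min_area: int = 4
    coloc_k: float = 3.0
    # grouping labels for the bead table
    well_id: str = "well1"
    replicate_id: str = "rep1"
    condition: str = "condition1"

    def validate(self) -> None:
        if self.mode not in ("beads", "condensates"):
            raise ValueError(f"mode must be 'beads' or 'condensates', got {self.mode!r}")
        if not self.images and self.simulate is None:
            raise ValueError(
                "config supplies neither input images nor a simulate block"
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def load_config(source: str | Path | dict[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or a dict.

    Unknown keys are rejected by name, so typos never silently fall back
    to defaults.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}"
        )
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
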