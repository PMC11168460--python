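"""Synthetic-data generators with machine-readable ground truth.

Every downstream stage of the package (bead scoring, condensate counting,
colocalization, FRAP, hierarchical statistics) is tested against scenes and
tables produced here, so each generator returns both the data and a
:class:`~beadpull.scene.SceneTruth` (or equivalent) describing exactly what
was rendered.

Determinism contract: every generator takes a single integer seed; all
random draws consume one ``numpy.random.default_rng(seed)`` stream in the
documented order, so identical spec + seed reproduces bitwise-identical
output.

Generators
----------
``generate_bead_scene``
    Agarose-bead pull-down scenes: bright circular rims (the fluorescent
    protein coat) over darker cores on a noisy background.  Rims are
    hard-edged annuli by default; an optional Gaussian blur emulates the
    microscope PSF.
``generate_condensate_series``
    Time series of condensate fields: diffraction-limited Gaussian spots
    with a programmable per-spot probability of carrying probe-channel
    signal (the ground-truth colocalization fraction).
``generate_frap_trace``
    Bleach-and-recovery traces following a single-exponential recovery
    with a programmed mobile fraction.
``generate_bead_table``
    Per-bead response tables with nested random effects (replicate and
    well intercepts) for validating the mixed-model inference layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .frap import FrapTrace
from .scene import ImageScene, SceneTruth

__all__ = [
    "BeadSpec",
    "BeadSceneSpec",
    "CondensateSceneSpec",
    "FrapSpec",
    "BeadTableSpec",
    "generate_bead_scene",
    "generate_condensate_series",
    "generate_frap_trace",
    "generate_bead_table",
]


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass
class BeadSpec:
    """One bead to render: geometry plus per-channel rim/core intensities."""

    center: tuple[float, float]  # (x, y) px, 0-based pixel centers
    radius: float  # px
    rim_thickness: float = 3.0  # px
    rim_intensity: dict[str, float] = field(default_factory=dict)
    core_intensity: dict[str, float] = field(default_factory=dict)


@dataclass
class BeadSceneSpec:
    """Parameters of one synthetic bead scene.

    ``allow_adjacent`` must be set to render overlapping/touching beads
    (used to exercise the adjacency-exclusion logic); otherwise overlap is
    rejected at validation time.
    """

    image_shape: tuple[int, int]  # (rows, cols)
    beads: list[BeadSpec]
    background_level: dict[str, float]
    noise_sd: float = 0.0
    seed: int = 0
    blur_sigma: float = 0.0  # optional PSF emulation, px
    allow_adjacent: bool = False

    def channel_names(self) -> list[str]:
        names = list(self.background_level)
        for b in self.beads:
            for n in itertools.chain(b.rim_intensity, b.core_intensity):
                if n not in names:
                    names.append(n)
        return names

    def validate(self) -> None:
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        for lvl in self.background_level.values():
            if lvl < 0:
                raise ValueError(f"background_level must be >= 0, got {lvl}")
        for i, b in enumerate(self.beads):
            if not (b.radius > b.rim_thickness >= 1):
                raise ValueError(
                    f"bead {i}: requires radius > rim_thickness >= 1, "
                    f"got radius={b.radius}, rim_thickness={b.rim_thickness}"
                )
            x, y = b.center
            if not (0 <= x < cols and 0 <= y < rows):
                raise ValueError(
                    f"bead {i}: center {b.center} outside image {self.image_shape}"
                )
            for v in itertools.chain(
                b.rim_intensity.values(), b.core_intensity.values()
            ):
                if v < 0:
                    raise ValueError(f"bead {i}: intensities must be >= 0, got {v}")
        if not self.allow_adjacent:
            for i, a in enumerate(self.beads):
                for j in range(i + 1, len(self.beads)):
                    b = self.beads[j]
                    d = np.hypot(
                        a.center[0] - b.center[0], a.center[1] - b.center[1]
                    )
                    if d < a.radius + b.radius:
                        raise ValueError(
                            f"beads {i} and {j} overlap (distance {d:.1f} < "
                            f"radius sum {a.radius + b.radius:.1f}); set "
                            "allow_adjacent=True to render adjacency scenes"
                        )


@dataclass
class CondensateSceneSpec:
    """Parameters of a synthetic condensate time series.

    ``n_spots`` gives the number of reference-channel spots at each time
    point; ``coloc_fraction`` is the per-spot Bernoulli probability that a
    matched probe-channel blob is co-placed at the same center.
    """

    image_shape: tuple[int, int]
    n_spots: list[int]
    time_points: list[float]  # acquisition times, minutes
    ref_channel: str = "mCherry"
    probe_channel: str = "EGFP"
    spot_peak_intensity: dict[str, float] = field(
        default_factory=lambda: {"mCherry": 200.0, "EGFP": 150.0}
    )
    spot_sigma: dict[str, float] = field(
        default_factory=lambda: {"mCherry": 1.5, "EGFP": 1.5}
    )
    coloc_fraction: float = 1.0
    background_level: dict[str, float] = field(
        default_factory=lambda: {"mCherry": 10.0, "EGFP": 10.0}
    )
    noise_sd: float = 0.0
    seed: int = 0
    min_separation: float | None = None  # px; default 8*max(sigma)

    def channel_names(self) -> list[str]:
        return [self.ref_channel, self.probe_channel]

    def validate(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError(
                f"coloc_fraction must be in [0, 1], got {self.coloc_fraction}"
            )
        if any(n < 0 for n in self.n_spots):
            raise ValueError(f"n_spots must be >= 0, got {self.n_spots}")
        if len(self.n_spots) != len(self.time_points):
            raise ValueError(
                f"n_spots ({len(self.n_spots)}) and time_points "
                f"({len(self.time_points)}) lengths differ"
            )
        if any(
            t1 >= t2 for t1, t2 in zip(self.time_points, self.time_points[1:])
        ):
            raise ValueError(
                f"time_points must be strictly increasing, got {self.time_points}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for s in self.spot_sigma.values():
            if s <= 0:
                raise ValueError(f"spot_sigma must be > 0, got {s}")


@dataclass
class FrapSpec:
    """Single-exponential FRAP recovery model.

    The trace holds ``n_prebleach`` frames at ``pre_bleach_level``, a
    bleach frame at ``pre_bleach_level - bleach_depth``, then recovery
    ``I(t) = post + m * (pre - post) * (1 - exp(-k t))`` sampled every
    ``frame_interval`` seconds for ``duration`` seconds, with additive
    Gaussian noise.
    """

    pre_bleach_level: float = 100.0
    bleach_depth: float = 80.0
    mobile_fraction: float = 0.5
    rate: float = 0.5  # 1/s
    frame_interval: float = 1.0  # s
    duration: float = 30.0  # s, recovery observed after the bleach frame
    n_prebleach: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError(
                f"mobile_fraction must be in [0, 1], got {self.mobile_fraction}"
            )
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.frame_interval <= 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        if self.duration < self.frame_interval:
            raise ValueError(
                f"duration {self.duration}s shorter than one frame "
                f"({self.frame_interval}s)"
            )
        if self.n_prebleach < 1:
            raise ValueError(f"n_prebleach must be >= 1, got {self.n_prebleach}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.bleach_depth <= 0:
            raise ValueError(
                f"bleach_depth must be > 0, got {self.bleach_depth}"
            )


@dataclass
class BeadTableSpec:
    """Hierarchical per-bead response table: condition fixed effects plus
    random intercepts for experiment replicate and for well nested in
    replicate.

    Defaults mirror a typical pull-down experiment: 3 independent
    replicates, 4 wells per replicate split evenly over the conditions,
    30 beads measured per well.
    """

    condition_effects: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "treated": 0.0}
    )
    baseline: float = 100.0
    n_replicates: int = 3
    n_wells: int = 4  # per replicate, assigned round-robin to conditions
    n_beads: int = 30  # per well
    replicate_sd: float = 5.0
    well_sd: float = 5.0
    residual_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name, v in [
            ("replicate_sd", self.replicate_sd),
            ("well_sd", self.well_sd),
            ("residual_sd", self.residual_sd),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, v in [
            ("n_replicates", self.n_replicates),
            ("n_wells", self.n_wells),
            ("n_beads", self.n_beads),
        ]:
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not self.condition_effects:
            raise ValueError("condition_effects must name at least one condition")
        if self.n_wells < len(self.condition_effects):
            raise ValueError(
                f"n_wells ({self.n_wells}) smaller than number of conditions "
                f"({len(self.condition_effects)})"
            )


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _distance_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Euclidean distance of every pixel center from (x, y)."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    return np.hypot(xx - center[0], yy - center[1])


def _add_noise(
    channels: dict[str, np.ndarray], noise_sd: float, rng: np.random.Generator
) -> None:
    """Additive Gaussian noise, clipped at 0; consumed in channel order."""
    if noise_sd <= 0:
        return
    for name in channels:
        channels[name] += rng.normal(0.0, noise_sd, size=channels[name].shape)
        np.clip(channels[name], 0.0, None, out=channels[name])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_bead_scene(spec: BeadSceneSpec) -> tuple[ImageScene, SceneTruth]:
    """Render a bead pull-down scene: annular rims over cores on background.

    A pixel belongs to bead *k*'s rim if its center lies within
    ``(radius - rim_thickness, radius]`` of the bead center, to the core if
    within ``radius - rim_thickness``.  Rim/core intensities replace (not
    add to) the background inside the bead, matching an opaque bead
    occluding the medium.  Draw order: one noise field per channel, in
    channel order.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = spec.channel_names()
    channels = {
        name: np.full(
            spec.image_shape, spec.background_level.get(name, 0.0), dtype=float
        )
        for name in names
    }

    records = []
    for k, bead in enumerate(spec.beads):
        dist = _distance_grid(spec.image_shape, bead.center)
        core = dist <= bead.radius - bead.rim_thickness
        rim = (dist <= bead.radius) & ~core
        rec = {
            "object_id": k,
            "kind": "bead",
            "center_x": bead.center[0],
            "center_y": bead.center[1],
            "radius": bead.radius,
            "rim_thickness": bead.rim_thickness,
        }
        for name in names:
            ch = channels[name]
            ch[rim] = bead.rim_intensity.get(name, 0.0)
            ch[core] = bead.core_intensity.get(name, 0.0)
            rec[f"rim_{name}"] = bead.rim_intensity.get(name, 0.0)
            rec[f"core_{name}"] = bead.core_intensity.get(name, 0.0)
        records.append(rec)

    if spec.blur_sigma > 0:
        for name in names:
            channels[name] = ndimage.gaussian_filter(
                channels[name], spec.blur_sigma
            )
    _add_noise(channels, spec.noise_sd, rng)

    truth = SceneTruth(
        objects=pd.DataFrame(records),
        background=dict(spec.background_level),
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    scene = ImageScene(
        channels,
        metadata={"kind": "bead_scene", "seed": spec.seed, "channel_order": names},
    )
    return scene, truth


def _place_spots(
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    rng: np.random.Generator,
    max_attempts_per_spot: int = 200,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping (x, y) centers."""
    rows, cols = shape
    if cols - 2 * margin <= 0 or rows - 2 * margin <= 0:
        raise ValueError(
            f"image {shape} too small for spot margin {margin:.1f} px"
        )
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = max(1, n) * max_attempts_per_spot
    while len(centers) < n:
        if attempts >= budget:
            # rough capacity: disks of radius min_sep/2 packed in the frame
            capacity = int(
                (rows - 2 * margin) * (cols - 2 * margin) / max(min_sep, 1.0) ** 2
            )
            raise ValueError(
                f"could not place {n} spots with min separation "
                f"{min_sep:.1f} px in a {rows}x{cols} image "
                f"(approximate capacity {capacity}); placed {len(centers)}"
            )
        attempts += 1
        x = rng.uniform(margin, cols - 1 - margin)
        y = rng.uniform(margin, rows - 1 - margin)
        if all(np.hypot(x - cx, y - cy) >= min_sep for cx, cy in centers):
            centers.append((x, y))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _render_gaussian_spot(
    channel: np.ndarray, center: tuple[float, float], peak: float, sigma: float
) -> None:
    """Add a symmetric 2-D Gaussian truncated at 4*sigma, in place."""
    rows, cols = channel.shape
    x0, y0 = center
    r = 4.0 * sigma
    c0, c1 = max(0, int(np.floor(x0 - r))), min(cols, int(np.ceil(x0 + r)) + 1)
    r0, r1 = max(0, int(np.floor(y0 - r))), min(rows, int(np.ceil(y0 + r)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (xx - x0) ** 2 + (yy - y0) ** 2
    blob = peak * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > r**2] = 0.0
    channel[r0:r1, c0:c1] += blob


def generate_condensate_series(
    spec: CondensateSceneSpec,
) -> tuple[list[ImageScene], SceneTruth]:
    """Render one scene per time point with ground-truth coloc flags.

    Draw order per time point: spot centers (rejection sampling), then the
    per-spot coloc Bernoulli flags, then one noise field per channel.
    Reference spots are Gaussian blobs in ``ref_channel``; a spot flagged
    colocalized receives a matched blob at the same center in
    ``probe_channel``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = spec.channel_names()
    sig_max = max(spec.spot_sigma.get(n, 1.5) for n in names)
    min_sep = (
        spec.min_separation if spec.min_separation is not None else 8.0 * sig_max
    )
    margin = 4.0 * sig_max

    scenes: list[ImageScene] = []
    records = []
    oid = 0
    for t_idx, (t, n) in enumerate(zip(spec.time_points, spec.n_spots)):
        channels = {
            name: np.full(
                spec.image_shape,
                spec.background_level.get(name, 0.0),
                dtype=float,
            )
            for name in names
        }
        centers = _place_spots(n, spec.image_shape, margin, min_sep, rng)
        flags = rng.random(n) < spec.coloc_fraction if n else np.zeros(0, bool)
        for (x, y), coloc in zip(centers, flags):
            _render_gaussian_spot(
                channels[spec.ref_channel],
                (x, y),
                spec.spot_peak_intensity.get(spec.ref_channel, 200.0),
                spec.spot_sigma.get(spec.ref_channel, 1.5),
            )
            if coloc:
                _render_gaussian_spot(
                    channels[spec.probe_channel],
                    (x, y),
                    spec.spot_peak_intensity.get(spec.probe_channel, 150.0),
                    spec.spot_sigma.get(spec.probe_channel, 1.5),
                )
            records.append(
                {
                    "object_id": oid,
                    "kind": "spot",
                    "time_point": t,
                    "center_x": x,
                    "center_y": y,
                    "sigma": spec.spot_sigma.get(spec.ref_channel, 1.5),
                    "coloc": bool(coloc),
                }
            )
            oid += 1
        _add_noise(channels, spec.noise_sd, rng)
        scenes.append(
            ImageScene(
                channels,
                metadata={
                    "kind": "condensate_scene",
                    "time_point": t,
                    "position": t_idx,
                    "seed": spec.seed,
                    "channel_order": names,
                },
            )
        )

    columns = [
        "object_id", "kind", "time_point", "center_x", "center_y",
        "sigma", "coloc",
    ]
    truth = SceneTruth(
        objects=pd.DataFrame(records, columns=columns),
        background=dict(spec.background_level),
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    return scenes, truth


def generate_frap_trace(spec: FrapSpec) -> FrapTrace:
    """Simulate a bleach-and-recovery trace.

    Frames: ``n_prebleach`` pre-bleach frames at the pre-bleach level, the
    bleach frame at ``pre - bleach_depth``, then recovery sampled at
    ``frame_interval`` up to ``duration`` seconds after the bleach.  Noise
    is added to every frame in temporal order.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pre = spec.pre_bleach_level
    post = pre - spec.bleach_depth
    m, k = spec.mobile_fraction, spec.rate

    n_rec = int(np.floor(spec.duration / spec.frame_interval))
    t_rec = np.arange(1, n_rec + 1) * spec.frame_interval
    recovery = post + m * (pre - post) * (1.0 - np.exp(-k * t_rec))

    intensities = np.concatenate(
        [np.full(spec.n_prebleach, pre), [post], recovery]
    )
    # time axis: bleach frame at t=0, pre-bleach frames at negative times
    times = np.concatenate(
        [
            -np.arange(spec.n_prebleach, 0, -1) * spec.frame_interval,
            [0.0],
            t_rec,
        ]
    )
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(
            0.0, spec.noise_sd, size=intensities.shape
        )
    return FrapTrace(
        times=times,
        intensities=intensities,
        pre_bleach_indices=np.arange(spec.n_prebleach),
        bleach_index=spec.n_prebleach,
    )


def generate_bead_table(spec: BeadTableSpec) -> pd.DataFrame:
    """Simulate per-bead mean scores with nested random effects.

    ``response = baseline + condition effect + replicate intercept
    + well intercept + residual``.  Wells within each replicate are
    assigned to conditions round-robin.  Draw order: replicate intercepts,
    then well intercepts (replicate-major), then residuals (bead-major).

    Returns a table with columns ``bead_id``, ``replicate_id``,
    ``well_id``, ``condition``, ``mean_score`` — the schema consumed by
    :func:`beadpull.stats.fit_bead_mixed_model`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    conditions = list(spec.condition_effects)

    rep_eff = rng.normal(0.0, spec.replicate_sd, size=spec.n_replicates)
    well_eff = rng.normal(
        0.0, spec.well_sd, size=(spec.n_replicates, spec.n_wells)
    )
    resid = rng.normal(
        0.0,
        spec.residual_sd,
        size=(spec.n_replicates, spec.n_wells, spec.n_beads),
    )

    rows = []
    bead_id = 0
    for r in range(spec.n_replicates):
        for w in range(spec.n_wells):
            cond = conditions[w % len(conditions)]
            for b in range(spec.n_beads):
                rows.append(
                    {
                        "bead_id": bead_id,
                        "replicate_id": f"rep{r + 1}",
                        "well_id": f"well{w + 1}",
                        "condition": cond,
                        "mean_score": (
                            spec.baseline
                            + spec.condition_effects[cond]
                            + rep_eff[r]
                            + well_eff[r, w]
                            + resid[r, w, b]
                        ),
                    }
                )
                bead_id += 1
    return pd.DataFrame(rows)
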