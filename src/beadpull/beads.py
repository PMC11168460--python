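"""Bead pull-down quantification: radial min–max line-profile scoring.

The assay reads out protein–protein interaction as fluorescence at the rim
of protein-coated agarose beads.  The pipeline is:

1. ``detect_beads`` — segment beads in one channel into a label mask
   (built-in robust-threshold detector, or any registered external
   backend such as a deep-learning segmenter honouring the same contract);
2. ``fit_circular_roi`` — fit a circle to each labeled component
   (centroid + equivalent-area radius);
3. ``draw_profiles`` — cast equally spaced radial line profiles from the
   center to beyond the rim, sampling the channel by bilinear
   interpolation;
4. ``exclude_adjacent`` — drop profiles that protrude into a neighbouring
   bead, using the combined label mask;
5. ``score_profile`` — score each retained profile by the difference
   between its maximum and minimum gray value (the rim shows up as the
   max, core/background as the min);
6. ``summarize_bead`` / ``qc_filter`` — per-bead mean and SD of the
   profile scores; beads whose SD reaches half their mean are excluded as
   unreliable.

``quantify_scene`` chains all steps for one image channel.

Coordinate conventions: 0-based, ``(x=col, y=row)``, pixel centers at
integer coordinates; profile angles measured from the +x axis,
counterclockwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "BeadROI",
    "LineProfile",
    "BeadMeasurement",
    "register_backend",
    "detect_beads",
    "fit_circular_roi",
    "draw_profiles",
    "exclude_adjacent",
    "score_profile",
    "summarize_bead",
    "qc_filter",
    "quantify_scene",
    "MIN_RADIUS_PX",
]

MIN_RADIUS_PX = 3.0  # beads smaller than this are flagged, not scored


@dataclass
class BeadROI:
    """Circle fitted to one segmented bead."""

    bead_id: int
    center: tuple[float, float]  # (x, y) px
    radius: float  # px


@dataclass
class LineProfile:
    """One radial intensity profile of a bead.

    ``distances`` are the sample positions from the center (constant
    spacing); ``samples`` the bilinearly interpolated gray values.
    ``excluded`` with ``reason`` in {"adjacent-bead", "out-of-bounds"}
    marks profiles removed before scoring.
    """

    bead_id: int
    angle: float  # rad in [0, 2*pi)
    distances: np.ndarray
    samples: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the ROI center
    excluded: bool = False
    reason: str = "none"

    def sample_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) of every sample point along the ray."""
        xs = self.origin[0] + self.distances * np.cos(self.angle)
        ys = self.origin[1] + self.distances * np.sin(self.angle)
        return xs, ys


@dataclass
class BeadMeasurement:
    """Per-bead summary over retained profile scores."""

    bead_id: int
    well_id: str = ""
    replicate_id: str = ""
    condition: str = ""
    scores: list[float] = field(default_factory=list)
    n_profiles_retained: int = 0
    mean_score: float = float("nan")
    sd_score: float = float("nan")
    qc_pass: bool = False
    exclusion_reason: str = ""


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[..., np.ndarray]] = {}


def register_backend(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register an external segmentation backend.

    ``fn(image_channel, **params)`` must return an integer label mask of
    the same shape (0 = background).  This is the plug-in point for AI
    segmenters; the built-in ``"reference"`` detector is always available.
    """
    _BACKENDS[name] = fn


def _compact_labels(mask: np.ndarray) -> np.ndarray:
    """Relabel to a gap-free {1..n} label set."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask, dtype=np.int32)
    for new, old in enumerate(labels, start=1):
        out[mask == old] = new
    return out


def _fill_fraction(component: np.ndarray, centroid_xy: tuple[float, float]) -> float:
    """Area of the component over the area of its smallest enclosing
    circle around the centroid.  ~1 for a disk, ~0.5 for a merged doublet.
    """
    ys, xs = np.nonzero(component)
    r_max = np.hypot(xs - centroid_xy[0], ys - centroid_xy[1]).max() + 0.5
    return float(len(xs) / (np.pi * r_max**2))


def _reference_detect(
    image: np.ndarray,
    k_mad: float = 5.0,
    min_area: int = 100,
    min_fill_fraction: float = 0.6,
) -> np.ndarray:
    """Built-in detector: robust threshold + hole filling + shape gate.

    Threshold at background median + ``k_mad`` * MAD (strict >), fill
    holes (bead cores are darker than rims), connected components, then
    discard components below ``min_area`` px or whose fill fraction
    against the enclosing circle falls under ``min_fill_fraction``
    (rejects merged doublets and ragged debris).
    """
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    binary = image > med + k_mad * mad
    binary = ndimage.binary_fill_holes(binary)
    labeled = measure.label(binary, connectivity=2)

    keep = np.zeros_like(labeled)
    next_id = 0
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            logger.info(
                "discarding component %d: area %d < min_area %d",
                region.label, region.area, min_area,
            )
            continue
        cy, cx = region.centroid
        comp = labeled == region.label
        ff = _fill_fraction(comp, (cx, cy))
        if ff < min_fill_fraction:
            logger.info(
                "discarding component %d: fill fraction %.2f < %.2f "
                "(likely merged beads)", region.label, ff, min_fill_fraction,
            )
            continue
        next_id += 1
        keep[comp] = next_id
    return keep.astype(np.int32)


def detect_beads(
    image_channel: np.ndarray,
    backend: str = "reference",
    **params,
) -> np.ndarray:
    """Segment beads in a single channel into a compacted label mask.

    An empty or constant image yields an empty mask (0 labels), never an
    error.  Backend failures are re-raised with the image identifier so
    batch runs can report which position failed.
    """
    image = np.asarray(image_channel, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a single 2-D channel, got shape {image.shape}")
    image_id = params.pop("image_id", "<unnamed>")
    if backend == "reference":
        fn: Callable[..., np.ndarray] = _reference_detect
    else:
        try:
            fn = _BACKENDS[backend]
        except KeyError:
            raise KeyError(
                f"unknown detection backend {backend!r}; registered: "
                f"{['reference', *sorted(_BACKENDS)]}"
            ) from None
    try:
        mask = fn(image, **params)
    except Exception as exc:
        raise RuntimeError(
            f"detection backend {backend!r} failed on image {image_id!r}: {exc}"
        ) from exc
    if mask.shape != image.shape:
        raise ValueError(
            f"backend {backend!r} returned mask of shape {mask.shape} "
            f"for image of shape {image.shape}"
        )
    return _compact_labels(np.asarray(mask))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def fit_circular_roi(mask: np.ndarray, label: int) -> BeadROI:
    """Fit the equivalent-area circle to one labeled component.

    Center is the (intensity-free) centroid of the labeled pixels; radius
    is ``sqrt(area / pi)``.  Exact for disk-shaped masks, deterministic
    and parameter-free for everything else.
    """
    ys, xs = np.nonzero(mask == label)
    if len(xs) == 0:
        raise ValueError(f"label {label} not present in mask")
    area = float(len(xs))
    return BeadROI(
        bead_id=int(label),
        center=(float(xs.mean()), float(ys.mean())),
        radius=float(np.sqrt(area / np.pi)),
    )


def draw_profiles(
    roi: BeadROI,
    image_channel: np.ndarray,
    n_lines: int = 8,
    extension_frac: float = 0.2,
    step: float = 1.0,
) -> list[LineProfile]:
    """Cast ``n_lines`` equally spaced radial profiles from the ROI center.

    Angles start at 0 rad (+x axis) and advance counterclockwise.  Each
    profile samples the channel by bilinear interpolation at distances
    ``0, step, 2*step, ...`` up to ``(1 + extension_frac) * radius``
    (final grid point <= that length, inclusive).  Profiles with any
    sample outside the image are flagged excluded (reason
    ``out-of-bounds``).
    """
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    if extension_frac < 0:
        raise ValueError(f"extension_frac must be >= 0, got {extension_frac}")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")

    image = np.asarray(image_channel, dtype=float)
    rows, cols = image.shape
    length = (1.0 + extension_frac) * roi.radius
    n_samples = int(np.floor(length / step)) + 1
    distances = np.arange(n_samples) * step

    profiles = []
    cx, cy = roi.center
    for i in range(n_lines):
        angle = 2.0 * np.pi * i / n_lines
        xs = cx + distances * np.cos(angle)
        ys = cy + distances * np.sin(angle)
        oob = (xs < 0) | (xs > cols - 1) | (ys < 0) | (ys > rows - 1)
        samples = ndimage.map_coordinates(
            image, np.vstack([ys, xs]), order=1, mode="nearest"
        )
        profiles.append(
            LineProfile(
                bead_id=roi.bead_id,
                angle=angle,
                distances=distances,
                samples=samples,
                origin=(cx, cy),
                excluded=bool(oob.any()),
                reason="out-of-bounds" if oob.any() else "none",
            )
        )
    return profiles


def exclude_adjacent(
    profiles: list[LineProfile],
    combined_mask: np.ndarray,
    own_label: int,
) -> list[LineProfile]:
    """Flag profiles that protrude into another detected bead.

    A profile is excluded (reason ``adjacent-bead``) iff any of its sample
    points, rounded to the nearest pixel, lands on a pixel of the combined
    mask carrying a label other than ``own_label``.  Flags already set
    (out-of-bounds) are untouched.
    """
    mask = np.asarray(combined_mask)
    if not (mask == own_label).any():
        raise ValueError(f"own label {own_label} not present in combined mask")
    rows, cols = mask.shape
    for p in profiles:
        if p.excluded:
            continue
        xs, ys = p.sample_coords()
        xi = np.clip(np.rint(xs), 0, cols - 1).astype(int)
        yi = np.clip(np.rint(ys), 0, rows - 1).astype(int)
        hit = mask[yi, xi]
        if np.any((hit != 0) & (hit != own_label)):
            p.excluded = True
            p.reason = "adjacent-bead"
    return profiles


def score_profile(profile: LineProfile) -> float:
    """Min–max score: ``max(samples) - min(samples)``, always >= 0.

    The bright rim contributes the max, the dark core or background the
    min, so a coated bead scores its rim-over-core contrast.  Excluded
    profiles must be filtered by the caller.
    """
    if profile.excluded:
        raise ValueError(
            f"profile at angle {profile.angle:.3f} rad of bead "
            f"{profile.bead_id} is excluded ({profile.reason}); "
            "filter before scoring"
        )
    return float(profile.samples.max() - profile.samples.min())


def summarize_bead(
    profiles: list[LineProfile],
    bead_id: int,
    well_id: str = "",
    replicate_id: str = "",
    condition: str = "",
) -> BeadMeasurement:
    """Mean and SD of the min–max scores over retained profiles.

    SD uses the sample (n-1) definition; a single retained profile gives
    SD 0 by convention (logged).  A bead with zero retained profiles is
    returned as dropped with reason ``no-retained-profiles``.
    QC verdict: ``qc_pass`` iff ``sd < mean / 2`` (beads whose score SD is
    equal to or greater than half the mean are unreliable and excluded).
    """
    retained = [p for p in profiles if not p.excluded]
    m = BeadMeasurement(
        bead_id=bead_id,
        well_id=well_id,
        replicate_id=replicate_id,
        condition=condition,
    )
    if not retained:
        m.exclusion_reason = "no-retained-profiles"
        m.n_profiles_retained = 0
        return m
    scores = [score_profile(p) for p in retained]
    m.scores = scores
    m.n_profiles_retained = len(scores)
    m.mean_score = float(np.mean(scores))
    if len(scores) == 1:
        logger.info("bead %d: single retained profile, SD set to 0", bead_id)
        m.sd_score = 0.0
    else:
        m.sd_score = float(np.std(scores, ddof=1))
    m.qc_pass = bool(m.sd_score < m.mean_score / 2.0)
    return m


def qc_filter(
    measurements: list[BeadMeasurement],
) -> tuple[list[BeadMeasurement], pd.DataFrame]:
    """Apply the SD-vs-mean exclusion rule.

    Retains exactly the beads with ``sd_score < mean_score / 2``; a bead
    whose SD equals half its mean is excluded (the boundary case counts as
    unreliable), and so is a zero-mean bead (its SD >= 0 = mean / 2).
    Returns the retained list and an exclusion report (bead_id, mean, sd,
    ratio, reason).
    """
    retained: list[BeadMeasurement] = []
    report_rows = []
    for m in measurements:
        if m.exclusion_reason:
            report_rows.append(
                {
                    "bead_id": m.bead_id,
                    "mean_score": m.mean_score,
                    "sd_score": m.sd_score,
                    "sd_over_mean": np.nan,
                    "reason": m.exclusion_reason,
                }
            )
            continue
        if m.sd_score < m.mean_score / 2.0:
            retained.append(m)
        else:
            m.qc_pass = False
            report_rows.append(
                {
                    "bead_id": m.bead_id,
                    "mean_score": m.mean_score,
                    "sd_score": m.sd_score,
                    "sd_over_mean": (
                        m.sd_score / m.mean_score if m.mean_score else np.inf
                    ),
                    "reason": "sd>=mean/2",
                }
            )
    report = pd.DataFrame(
        report_rows,
        columns=["bead_id", "mean_score", "sd_score", "sd_over_mean", "reason"],
    )
    return retained, report


# ---------------------------------------------------------------------------
# per-scene pipeline
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements: list[BeadMeasurement]) -> pd.DataFrame:
    """Flatten measurements into the per-bead output table."""
    return pd.DataFrame(
        [
            {
                "bead_id": m.bead_id,
                "well_id": m.well_id,
                "replicate_id": m.replicate_id,
                "condition": m.condition,
                "n_profiles_retained": m.n_profiles_retained,
                "mean_score": m.mean_score,
                "sd_score": m.sd_score,
                "qc_pass": m.qc_pass,
                "exclusion_reason": m.exclusion_reason,
            }
            for m in measurements
        ],
        columns=[
            "bead_id", "well_id", "replicate_id", "condition",
            "n_profiles_retained", "mean_score", "sd_score", "qc_pass",
            "exclusion_reason",
        ],
    )


def quantify_scene(
    image_channel: np.ndarray,
    mask: np.ndarray | None = None,
    n_lines: int = 8,
    extension_frac: float = 0.2,
    step: float = 1.0,
    min_radius: float = MIN_RADIUS_PX,
    well_id: str = "",
    replicate_id: str = "",
    condition: str = "",
    detect_params: dict | None = None,
) -> tuple[pd.DataFrame, list[LineProfile]]:
    """Run detect → fit → profile → adjacency-exclude → score → summarize
    on one channel.

    ``mask`` may supply a precomputed label mask (e.g. from an external
    segmenter); otherwise the reference detector runs.  Returns the
    per-bead table (including dropped beads with their reason) and all
    profiles for audit.
    """
    image = np.asarray(image_channel, dtype=float)
    if mask is None:
        mask = detect_beads(image, **(detect_params or {}))
    else:
        mask = _compact_labels(np.asarray(mask))

    measurements: list[BeadMeasurement] = []
    all_profiles: list[LineProfile] = []
    for label in range(1, int(mask.max()) + 1):
        roi = fit_circular_roi(mask, label)
        if roi.radius < min_radius:
            m = BeadMeasurement(
                bead_id=label, well_id=well_id,
                replicate_id=replicate_id, condition=condition,
                exclusion_reason=f"radius<{min_radius}px",
            )
            measurements.append(m)
            logger.info(
                "bead %d: radius %.2f px below minimum %.2f px, excluded",
                label, roi.radius, min_radius,
            )
            continue
        profiles = draw_profiles(
            roi, image, n_lines=n_lines,
            extension_frac=extension_frac, step=step,
        )
        profiles = exclude_adjacent(profiles, mask, label)
        all_profiles.extend(profiles)
        measurements.append(
            summarize_bead(
                profiles, bead_id=label, well_id=well_id,
                replicate_id=replicate_id, condition=condition,
            )
        )
    return measurements_to_frame(measurements), all_profiles
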