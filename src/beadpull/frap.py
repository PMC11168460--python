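"""FRAP trace normalization and mobile-fraction estimation.

After photobleaching a condensate, the recovery of fluorescence reports the
mobile share of the bleached species.  Traces are normalized so the
pre-bleach mean maps to 1 and the bleach frame to 0; the mobile fraction is
then the plateau of the normalized recovery, estimated assumption-light as
the mean of the last few frames (tail mean).  A single-exponential fit is
available as a secondary estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapTrace", "normalize_frap", "mobile_fraction", "fit_exponential_recovery"]


@dataclass
class FrapTrace:
    """A bleach-and-recovery intensity time series.

    ``times`` are in seconds with the bleach frame at t = 0 and pre-bleach
    frames at negative times.  ``normalized`` and ``mobile_fraction_`` are
    filled by :func:`normalize_frap` / :func:`mobile_fraction`.
    """

    times: np.ndarray
    intensities: np.ndarray
    pre_bleach_indices: np.ndarray
    bleach_index: int
    normalized: np.ndarray | None = field(default=None)
    mobile_fraction_: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.pre_bleach_indices = np.asarray(self.pre_bleach_indices, dtype=int)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if self.pre_bleach_indices.size < 1:
            raise ValueError("at least one pre-bleach frame is required")
        if int(self.pre_bleach_indices.max()) >= self.bleach_index:
            raise ValueError(
                f"bleach_index ({self.bleach_index}) must come after all "
                f"pre-bleach frames (max index {self.pre_bleach_indices.max()})"
            )
        if not (0 <= self.bleach_index < len(self.intensities)):
            raise ValueError(f"bleach_index {self.bleach_index} out of range")

    @property
    def n_post_bleach(self) -> int:
        return len(self.intensities) - self.bleach_index - 1


def normalize_frap(trace: FrapTrace) -> FrapTrace:
    """Anchor the trace: pre-bleach mean -> 1, bleach frame -> 0.

    ``normalized(t) = (I(t) - I_bleach) / (I_pre - I_bleach)`` with
    ``I_pre`` the mean over the pre-bleach frames.  Degenerate traces with
    ``I_pre == I_bleach`` (no bleach happened) are rejected.
    """
    i_pre = float(trace.intensities[trace.pre_bleach_indices].mean())
    i_bleach = float(trace.intensities[trace.bleach_index])
    span = i_pre - i_bleach
    if span == 0:
        raise ValueError(
            "degenerate trace: pre-bleach mean equals bleach-frame intensity "
            f"({i_pre}); nothing was bleached"
        )
    trace.normalized = (trace.intensities - i_bleach) / span
    return trace


def mobile_fraction(trace: FrapTrace, tail_frames: int = 5) -> float:
    """Plateau of the normalized recovery: mean of the last ``tail_frames``
    post-bleach values, clamped to [0, 1].

    The trace must have been normalized first (:func:`normalize_frap` is
    applied on the fly if not).
    """
    if tail_frames < 1:
        raise ValueError(f"tail_frames must be >= 1, got {tail_frames}")
    if trace.normalized is None:
        normalize_frap(trace)
    n_post = trace.n_post_bleach
    if tail_frames > n_post:
        raise ValueError(
            f"tail_frames ({tail_frames}) exceeds the {n_post} post-bleach frames"
        )
    assert trace.normalized is not None
    tail = trace.normalized[-tail_frames:]
    m = float(np.clip(tail.mean(), 0.0, 1.0))
    trace.mobile_fraction_ = m
    return m


def fit_exponential_recovery(trace: FrapTrace) -> dict[str, float]:
    """Secondary estimator: fit ``m * (1 - exp(-k t))`` to the normalized
    post-bleach trace.  Returns ``{"mobile_fraction": m, "rate": k}``.
    """
    if trace.normalized is None:
        normalize_frap(trace)
    assert trace.normalized is not None
    post = slice(trace.bleach_index, None)
    t = trace.times[post]
    y = trace.normalized[post]
    if t.size < 3:
        raise ValueError("need at least 3 post-bleach frames for the fit")

    def model(t, m, k):
        return m * (1.0 - np.exp(-k * t))

    p0 = (float(np.clip(y[-1], 1e-3, 1.0)), 0.1)
    popt, _ = curve_fit(
        model, t, y, p0=p0, bounds=([0.0, 0.0], [1.5, np.inf]), maxfev=10000
    )
    return {"mobile_fraction": float(np.clip(popt[0], 0.0, 1.0)),
            "rate": float(popt[1])}
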