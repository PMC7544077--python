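"""Preprocessing chain for wrist-worn 3-axis accelerometer recordings.

Repeated forearm rotation (pronation-supination) shows up as quasi-periodic
oscillation on all three accelerometer axes.  To feed such recordings into
the same trajectory-based analysis used for pose-estimated joint
coordinates, each recording is reduced to a single pseudo-trajectory:

1. normalize each axis to [0, 1] (device offsets and gains drop out),
2. combine the axes into one magnitude sequence (Euclidean norm),
3. normalize the magnitude to [0, 1],
4. center it by subtracting a 20-frame sliding-window median (pulls the
   baseline toward 0 without blunting the oscillation),
5. integrate twice (acceleration -> velocity -> position), cumulative sums
   with zero initial conditions.

The result is analyzed with a 100-frame window shifted by 10 frames.
Naive double integration of noisy accelerometry drifts quadratically, so an
optional linear detrend after each integration is available (off by
default); the averaged short-time ACF downstream is insensitive to smooth
drift within a window, which is why the plain cumulative sum suffices.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .core import Sequence, TriaxialSequence

logger = logging.getLogger(__name__)

DEFAULT_MEDIAN_WIDTH = 20


def normalize01(v: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] via (v - min) / (max - min); constant -> zeros."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError(f"need >= 2 samples, got {v.size}")
    lo, hi = v.min(), v.max()
    if hi == lo:
        logger.warning("constant vector in normalize01: returning zeros")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def magnitude3(t: TriaxialSequence) -> Sequence:
    """Per-sample Euclidean norm of the three axes."""
    vals = np.sqrt(t.x ** 2 + t.y ** 2 + t.z ** 2)
    return Sequence(vals, fps=t.fps, kind="acceleration", meta=t.meta)


def center_sliding_median(seq: Sequence, width: int = DEFAULT_MEDIAN_WIDTH) -> Sequence:
    """Subtract a centered sliding-window median of nominal ``width`` frames.

    The window is centered on each sample and shrunk symmetrically at the
    boundaries, which avoids the phase lag a trailing window would add.
    """
    x = seq.values
    n = x.size
    radius = max(1, width // 2)
    med = np.empty(n)
    for t in range(n):
        r = min(radius, t, n - 1 - t)
        med[t] = np.median(x[t - r : t + r + 1])
    return seq.replace(values=x - med)


def double_integrate(
    seq: Sequence, detrend: bool = False, scheme: str = "rect"
) -> Sequence:
    """Integrate an acceleration sequence twice to a pseudo-trajectory.

    ``rect``: cumulative sums with unit frame step and zero initial
    conditions (exactly reproducible).  ``trap``: trapezoidal rule.  With
    ``detrend=True`` a linear trend is removed after each integration to
    suppress quadratic drift.
    """
    if seq.kind != "acceleration":
        raise ValueError(f"double_integrate expects kind='acceleration', got {seq.kind!r}")

    def integrate(v: np.ndarray) -> np.ndarray:
        if scheme == "rect":
            out = np.cumsum(v)
        elif scheme == "trap":
            out = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0)])
        else:
            raise ValueError(f"unknown integration scheme {scheme!r}")
        return _linear_detrend(out) if detrend else out

    velocity = integrate(seq.values)
    position = integrate(velocity)
    return seq.replace(values=position, kind="position")


def accel_to_trajectory(
    t: TriaxialSequence,
    median_width: int = DEFAULT_MEDIAN_WIDTH,
    detrend: bool = True,
    scheme: str = "rect",
) -> Sequence:
    """Full 3-axis chain: normalize, combine, center, double-integrate.

    The chain detrends after each integration by default: the median
    centering leaves a small residual baseline whose double integral
    grows quadratically and otherwise dwarfs the oscillation of interest
    (a ramp dominating every analysis window).  Pass ``detrend=False``
    for the plain cumulative-sum chain.
    """
    stage = "normalize axes"
    try:
        t = TriaxialSequence(
            normalize01(t.x), normalize01(t.y), normalize01(t.z), fps=t.fps, meta=t.meta
        )
        stage = "magnitude"
        mag = magnitude3(t)
        stage = "normalize magnitude"
        mag = mag.replace(values=normalize01(mag.values))
        stage = "sliding-median centering"
        centered = center_sliding_median(mag, width=median_width)
        stage = "double integration"
        return double_integrate(centered, detrend=detrend, scheme=scheme)
    except ValueError as e:
        raise ValueError(
            f"accelerometer chain failed at stage {stage!r} for "
            f"{t.meta.sequence_id!r}: {e}"
        ) from e
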