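"""Acceleration/deceleration decomposition of primary-saccade traces.

The 2-D speed of a saccade trace segment is ``sqrt(vel_h^2 + vel_v^2)``.
Its maximum defines the saccade's peak velocity, which splits the
horizontal trace into an acceleration phase (before the peak) and a
deceleration phase (after the peak).  The horizontal amplitude component
accumulated in each phase is the horizontal displacement of that phase.

Conventions: velocities come from the same central-difference estimator as
saccade detection, but the split defaults to *unsmoothed* positions
(``smooth_ms=1``): a boxcar window biases the location of the speed peak
by several samples when the peak lies near the saccade's steep onset or
offset edge, which systematically distorts the displacement split for
strongly skewed velocity profiles, whereas peak *detection* (in
:mod:`saccadapt.preprocess`) is insensitive to a small peak shift and
keeps its 5 ms window.  The peak sample itself belongs to the
acceleration phase; displacements are computed from position samples
(segment end minus segment start), so the two phase displacements sum to
the total displacement exactly, under either boundary convention.  Ties
between equal global speed maxima break to the earliest sample and are
recorded on the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FlatSegmentError, ShortSegmentError
from .preprocess import estimate_velocity
from .synthetic_data import GazeTrace

#: Default smoothing for the kinematic split: none (see module docstring).
SPLIT_SMOOTH_MS = 1

__all__ = ["KinematicSplit", "speed_profile", "split_at_peak", "SPLIT_SMOOTH_MS"]


@dataclass(frozen=True)
class KinematicSplit:
    """Horizontal displacement split at the 2-D peak speed, in degrees."""

    peak_time_ms: float
    peak_speed: float
    acc_hor_disp: float
    dec_hor_disp: float
    total_hor_disp: float
    peak_index: int
    peak_tie: bool = False


def speed_profile(segment: GazeTrace, smooth_ms: int = SPLIT_SMOOTH_MS) -> np.ndarray:
    """Per-sample 2-D speed (deg/s) of a trace segment.

    NaN samples propagate.  Segments shorter than 3 samples cannot support
    a central difference and are rejected.
    """
    if len(segment) < 3:
        raise ShortSegmentError(f"segment has {len(segment)} samples, need >= 3")
    vel_h, vel_v = estimate_velocity(segment, smooth_ms=smooth_ms)
    return np.hypot(vel_h, vel_v)


def split_at_peak(segment: GazeTrace, smooth_ms: int = SPLIT_SMOOTH_MS) -> KinematicSplit:
    """Split a single-saccade segment at its 2-D peak speed.

    ``acc_hor_disp`` is the horizontal displacement from segment start to
    the peak-speed sample, ``dec_hor_disp`` from the peak-speed sample to
    segment end; their sum telescopes to the total displacement exactly.
    """
    speed = speed_profile(segment, smooth_ms=smooth_ms)
    finite = np.isfinite(speed)
    if not finite.any() or np.nanmax(speed) == 0.0:
        raise FlatSegmentError("segment carries no motion; no speed peak")

    peak_val = np.nanmax(speed)
    peak_candidates = np.flatnonzero(finite & (speed == peak_val))
    peak = int(peak_candidates[0])
    tie = len(peak_candidates) > 1

    x = segment.x_deg
    acc = float(x[peak] - x[0])
    dec = float(x[-1] - x[peak])
    return KinematicSplit(
        peak_time_ms=float(segment.t_ms[peak]),
        peak_speed=float(peak_val),
        acc_hor_disp=acc,
        dec_hor_disp=dec,
        total_hor_disp=float(x[-1] - x[0]),
        peak_index=peak,
        peak_tie=tie,
    )
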