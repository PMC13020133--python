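"""Smooth-pursuit kinematics from raw gaze traces.

The measurement chain is: low-pass filter the position channels (zero-phase
second-order Butterworth, 30-Hz cutoff), differentiate numerically, detect
and mask saccades with a speed threshold, project velocity onto the stimulus
direction, and summarize three functional windows:

* anticipatory pursuit, -50 to 100 ms around stimulus onset;
* early (open-loop) acceleration, from the 100-120 ms and 200-220 ms
  window means divided by 0.1 s;
* steady-state (closed-loop) pursuit, 400 to 600 ms.

Times are in ms with t = 0 at stimulus motion onset; positions in degrees;
velocities in deg/s.  Traces are uniformly sampled at 500 Hz (2-ms period).
Windows are half-open [a, b) against the sample grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .angles import AngularHistogram, circ_wrap

SAMPLE_RATE_HZ = 500.0
DT_MS = 1000.0 / SAMPLE_RATE_HZ

#: Default analysis windows (ms, half-open).
ANTICIPATION_WINDOW = (-50.0, 100.0)
ACCEL_EARLY_WINDOW = (100.0, 120.0)
ACCEL_LATE_WINDOW = (200.0, 220.0)
STEADY_WINDOW = (400.0, 600.0)

#: Anticipation-amplitude validity band (deg/s): below is noise/unstable
#: fixation, above likely contains unmarked saccades.
AMP_VALID_RANGE = (0.25, 2.5)

DEFAULT_SACCADE_THRESHOLD = 30.0  # deg/s
DEFAULT_SACCADE_PAD_MS = 10.0


def _check_uniform(t: np.ndarray) -> None:
    dt = np.diff(t)
    if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
        raise ValueError("trace time base must be uniformly sampled")
    if dt.size and abs(dt[0] - DT_MS) > 1e-6:
        raise ValueError(f"expected {DT_MS} ms sampling, got {dt[0]:.4f} ms")


@dataclass
class EyeTrace:
    """Gaze position trace: t in ms (t=0 at stimulus onset), x/y in deg."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        _check_uniform(self.t)


@dataclass
class VelocityTrace:
    """Velocity trace with a saccade mask; masked samples carry NaN."""

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    mask: np.ndarray  # True where a saccade was detected (samples are NaN)
    events: list  # list of (t_start_ms, t_end_ms) masked runs

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass
class KinematicSummary:
    """Per-trial pursuit metrics for the three analysis windows."""

    anticipation_amp: float
    anticipation_angle: float
    anticipation_vproj: float
    anticipation_valid: bool
    accel: float
    steady_vproj: float
    steady_angle: float


def lowpass_position(trace: EyeTrace, cutoff_hz: float = 30.0) -> EyeTrace:
    """Zero-phase second-order Butterworth low-pass of both position channels.

    Forward-backward application keeps the filter phase-neutral, so window
    timing (pursuit latency, window edges) is not shifted; the price is that
    the effective attenuation is the squared single-pass magnitude.
    """
    if trace.t.size < 50:
        raise ValueError("need at least 50 samples to filter")
    sos = signal.butter(2, cutoff_hz, btype="low", fs=SAMPLE_RATE_HZ, output="sos")
    return EyeTrace(
        trace.t,
        signal.sosfiltfilt(sos, trace.x),
        signal.sosfiltfilt(sos, trace.y),
    )


def differentiate(trace: EyeTrace) -> VelocityTrace:
    """Central-difference velocity (deg/s); one-sided at the endpoints.

    Central differences are exact for locally quadratic position signals.
    """
    if trace.t.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    t_s = trace.t / 1000.0
    vx = np.gradient(trace.x, t_s)
    vy = np.gradient(trace.y, t_s)
    return VelocityTrace(trace.t, vx, vy, np.zeros(trace.t.size, dtype=bool), [])


def detect_and_mask_saccades(
    vel: VelocityTrace,
    speed_threshold: float = DEFAULT_SACCADE_THRESHOLD,
    pad_ms: float = DEFAULT_SACCADE_PAD_MS,
) -> VelocityTrace:
    """Mask samples whose speed exceeds ``speed_threshold``, padded both ways.

    Masked samples are replaced by NaN; unmasked samples pass through
    bit-identically.  Contiguous masked runs are reported as events.
    """
    if speed_threshold <= 0:
        raise ValueError("speed threshold must be positive")
    over = np.hypot(vel.vx, vel.vy) > speed_threshold
    pad = int(round(pad_ms / DT_MS))
    if pad > 0 and over.any():
        over = ndimage.binary_dilation(over, iterations=pad)
    vx = vel.vx.copy()
    vy = vel.vy.copy()
    vx[over] = np.nan
    vy[over] = np.nan
    events = []
    if over.any():
        labeled, n = ndimage.label(over)
        for sl in ndimage.find_objects(labeled):
            idx = sl[0]
            events.append((float(vel.t[idx.start]), float(vel.t[idx.stop - 1])))
    return VelocityTrace(vel.t, vx, vy, over | vel.mask, events)


def project_velocity(vx, vy, theta_deg):
    """Signed component of (vx, vy) along direction theta (degrees).

    v_proj = vx * cos(theta) + vy * sin(theta); NaN propagates.
    """
    th = np.deg2rad(theta_deg)
    return np.asarray(vx) * np.cos(th) + np.asarray(vy) * np.sin(th)


def _window_slice(t: np.ndarray, window: Sequence[float]) -> np.ndarray:
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + DT_MS + 1e-9:
        raise ValueError(f"window [{lo}, {hi}) ms lies outside the trace span")
    return (t >= lo - 1e-9) & (t < hi - 1e-9)


def _masked_mean(values: np.ndarray, min_coverage: float = 0.0) -> float:
    finite = np.isfinite(values)
    if values.size == 0 or finite.mean() < max(min_coverage, np.finfo(float).tiny):
        return np.nan
    return float(values[finite].mean())


def anticipation_metrics(
    vel: VelocityTrace,
    theta_deg: float,
    window: Sequence[float] = ANTICIPATION_WINDOW,
    valid_range: Sequence[float] = AMP_VALID_RANGE,
    min_coverage: float = 0.5,
):
    """Anticipatory-pursuit amplitude, angle, projected velocity, validity.

    Means of the horizontal and vertical velocity components over the
    anticipatory window; amplitude is the vector norm, angle its direction.
    A trial is valid only if the amplitude lies in ``valid_range`` (the
    default 0.25-2.5 deg/s band rejects unstable fixation and unmarked
    saccades) and at least ``min_coverage`` of the window is unmasked.
    """
    sel = _window_slice(vel.t, window)
    mvx = _masked_mean(vel.vx[sel], min_coverage)
    mvy = _masked_mean(vel.vy[sel], min_coverage)
    if not (np.isfinite(mvx) and np.isfinite(mvy)):
        return np.nan, np.nan, np.nan, False
    amp = float(np.hypot(mvx, mvy))
    angle = float(circ_wrap(np.rad2deg(np.arctan2(mvy, mvx))))
    vproj = float(project_velocity(mvx, mvy, theta_deg))
    valid = bool(valid_range[0] <= amp <= valid_range[1])
    return amp, angle, vproj, valid


def early_acceleration(
    vel: VelocityTrace,
    theta_deg: float,
    early_window: Sequence[float] = ACCEL_EARLY_WINDOW,
    late_window: Sequence[float] = ACCEL_LATE_WINDOW,
) -> float:
    """Open-loop acceleration (deg/s^2): difference of the mean projected
    velocity between the late and early 20-ms windows, divided by 0.1 s."""
    vproj = project_velocity(vel.vx, vel.vy, theta_deg)
    early = _masked_mean(vproj[_window_slice(vel.t, early_window)])
    late = _masked_mean(vproj[_window_slice(vel.t, late_window)])
    return float((late - early) / 0.1)


def steady_state(
    vel: VelocityTrace,
    theta_deg: float,
    window: Sequence[float] = STEADY_WINDOW,
    min_coverage: float = 0.5,
):
    """Mean projected velocity and mean-vector direction in the steady window."""
    sel = _window_slice(vel.t, window)
    mvx = _masked_mean(vel.vx[sel], min_coverage)
    mvy = _masked_mean(vel.vy[sel], min_coverage)
    if not (np.isfinite(mvx) and np.isfinite(mvy)):
        return np.nan, np.nan
    vproj = float(project_velocity(mvx, mvy, theta_deg))
    angle = float(circ_wrap(np.rad2deg(np.arctan2(mvy, mvx))))
    return vproj, angle


def anticipation_histogram(angles) -> AngularHistogram:
    """Normalized 16-bin histogram of anticipatory directions (valid trials)."""
    return AngularHistogram.from_angles(angles)


def analyze_trace(
    trace: EyeTrace,
    theta_deg: float,
    *,
    saccade_threshold: float = DEFAULT_SACCADE_THRESHOLD,
    saccade_pad_ms: float = DEFAULT_SACCADE_PAD_MS,
    anticipation_window: Sequence[float] = ANTICIPATION_WINDOW,
    accel_early_window: Sequence[float] = ACCEL_EARLY_WINDOW,
    accel_late_window: Sequence[float] = ACCEL_LATE_WINDOW,
    steady_window: Sequence[float] = STEADY_WINDOW,
    amp_valid_range: Sequence[float] = AMP_VALID_RANGE,
) -> KinematicSummary:
    """Full per-trial chain: filter -> differentiate -> mask -> window metrics."""
    vel = detect_and_mask_saccades(
        differentiate(lowpass_position(trace)), saccade_threshold, saccade_pad_ms
    )
    amp, angle, vproj, valid = anticipation_metrics(
        vel, theta_deg, anticipation_window, amp_valid_range
    )
    accel = early_acceleration(vel, theta_deg, accel_early_window, accel_late_window)
    steady_vproj, steady_angle = steady_state(vel, theta_deg, steady_window)
    return KinematicSummary(amp, angle, vproj, valid, accel, steady_vproj, steady_angle)
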