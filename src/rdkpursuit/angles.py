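"""Shared circular (angular) primitives.

All angles in this package are degrees on the half-open interval (-180, 180],
with 0 deg = rightward motion and positive angles = downward / clockwise
(screen coordinates, y grows downward).  The stimulus space is discretized
into 16 direction bins of 22.5 deg, each spanning [center - 11.25,
center + 11.25) so that the bins tile the circle exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BINS = 16
BIN_STEP = 360.0 / N_BINS           # 22.5 deg
BIN_HALF_WIDTH = BIN_STEP / 2.0     # 11.25 deg

#: The 16 bin centers on (-180, 180]: -157.5, -135, ..., 157.5, 180.
BIN_CENTERS = np.arange(-N_BINS // 2 + 1, N_BINS // 2 + 1) * BIN_STEP

#: Cardinal directions (horizontal/vertical axes).
CARDINAL_CENTERS = frozenset((0.0, 90.0, -90.0, 180.0))


def circ_wrap(angle):
    """Wrap angle(s) in degrees onto (-180, 180].

    The representative of each congruence class mod 360 is unique; the
    boundary maps +180 (and -180) to +180.
    """
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


def circ_diff(a, b):
    """Signed shortest-arc difference a - b, wrapped onto (-180, 180].

    E.g. the difference between 350 deg and 10 deg is -20 deg (magnitude
    20 deg, not 340 deg).
    """
    return circ_wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def bin_index(angle):
    """Index (0..15) of the 22.5-deg bin containing ``angle``.

    Bins are half-open [c - 11.25, c + 11.25), so a report exactly on a
    boundary belongs to the counterclockwise-larger bin.
    """
    a = circ_wrap(angle)
    k = np.floor(a / BIN_STEP + 0.5)        # nearest multiple, .5 rounds up
    k = np.mod(k + N_BINS // 2 - 1, N_BINS)  # -157.5 -> 0, ..., 180 -> 15
    return k.astype(int)


def bin_center(angle):
    """Center (degrees) of the bin containing ``angle``."""
    return BIN_CENTERS[bin_index(angle)]


def circ_mean_deg(angles, weights=None):
    """Circular mean direction of angles in degrees (NaN for zero resultant)."""
    a = np.deg2rad(np.asarray(angles, dtype=float))
    if weights is None:
        z = np.exp(1j * a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        z = (w * np.exp(1j * a)).sum() / w.sum()
    if np.abs(z) < 1e-12:
        return np.nan
    return float(circ_wrap(np.rad2deg(np.angle(z))))


def resultant_length(angles):
    """Mean resultant length r in [0, 1] of angles in degrees."""
    a = np.deg2rad(np.asarray(angles, dtype=float))
    return float(np.abs(np.exp(1j * a).mean()))


def circ_std_deg(angles):
    """Circular standard deviation sqrt(-2 ln r), in degrees."""
    r = resultant_length(angles)
    if r <= 0:
        return np.inf
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


@dataclass(frozen=True)
class DirectionBins:
    """The 16-bin discretization of direction space with its category sets.

    ``cardinal`` marks the four axis-aligned centers {0, +/-90, 180};
    ``upper`` the seven strictly negative (upward) centers; ``lower`` the
    seven strictly positive centers below 180.  The two boundary bins
    (0 and 180) belong to neither hemifield.
    """

    centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())

    @property
    def cardinal_mask(self) -> np.ndarray:
        return np.isin(self.centers, sorted(CARDINAL_CENTERS))

    @property
    def upper_mask(self) -> np.ndarray:
        return (self.centers < 0) & (self.centers > -180)

    @property
    def lower_mask(self) -> np.ndarray:
        return (self.centers > 0) & (self.centers < 180)


@dataclass
class AngularHistogram:
    """Normalized frequencies of angles over the 16 direction bins."""

    bin_centers: np.ndarray
    freq: np.ndarray
    n_trials: int

    @classmethod
    def from_angles(cls, angles) -> "AngularHistogram":
        angles = np.asarray(angles, dtype=float)
        angles = angles[np.isfinite(angles)]
        if angles.size == 0:
            raise ValueError("cannot build a histogram from zero valid angles")
        counts = np.bincount(bin_index(angles), minlength=N_BINS).astype(float)
        return cls(BIN_CENTERS.copy(), counts / counts.sum(), int(angles.size))

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.n_trials > 0 and abs(self.freq.sum() - 1.0) > 1e-10:
            raise ValueError("histogram frequencies must sum to 1")
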