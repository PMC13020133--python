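"""Synthetic RDK direction-estimation experiments.

This module generates everything the downstream analysis consumes: session
designs with biased or uniform direction statistics, trial tables, dot-field
stimuli, perceptual reports from a generative observer, and 500-Hz eye
traces with anticipatory drift, visually driven pursuit, saccades and noise.

The observer is a mixture model: with a coherence-dependent probability the
report is stimulus-locked (von Mises around the true direction); otherwise
it is a guess drawn from a cardinal-direction prior multiplied by an
"avoidance" factor that suppresses density around the session's frequent
direction; a small lapse rate yields uniform guesses.  This is a generative
stand-in for a human observer whose inaccurate estimates favor cardinal
axes and avoid (rather than get attracted to) the statistically dominant
direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .angles import BIN_CENTERS, BIN_STEP, N_BINS, circ_wrap
from .oculo import DT_MS, EyeTrace

# ---------------------------------------------------------------------------
# Stimulus constants
# ---------------------------------------------------------------------------

FRAME_RATE_HZ = 85.0
DOT_SPEED_DEG_S = 10.0
DOT_DENSITY = 1.5          # dots / deg^2
APERTURE_RADIUS_DEG = 10.0
DOT_DIAMETER_DEG = 0.14
BLOCK_FRAMES = 4           # signal/noise labels are reshuffled every 4 frames

COHERENCE_LEVELS = (0.05, 0.15, 0.40)
GAP_MS = 300.0
STIM_MS = 1000.0
FIXATION_RANGE_MS = (500.0, 1000.0)

N_TRIALS_UNBIASED = 480
N_TRIALS_BIASED = 474
FREQUENT_SHARE = 0.60


def default_dot_count(
    density: float = DOT_DENSITY, radius: float = APERTURE_RADIUS_DEG
) -> int:
    """Number of dots implied by density x aperture area (~470)."""
    return int(round(density * math.pi * radius**2))


def dot_block_lifetime_ms(
    n_frames: int = BLOCK_FRAMES, frame_rate: float = FRAME_RATE_HZ
) -> float:
    """Duration of one label block: 4 frames at 85 Hz is ~47 ms."""
    return 1000.0 * n_frames / frame_rate


# ---------------------------------------------------------------------------
# Session design and trial sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionDesign:
    """Direction statistics of one experimental session.

    ``frequent_direction`` is present iff the session is biased, in which
    case that direction carries probability ``frequent_share`` and the 15
    remaining directions share the rest equally.
    """

    session_kind: str  # "unbiased" | "biased"
    n_trials: int
    frequent_direction: Optional[float] = None
    frequent_share: float = FREQUENT_SHARE
    direction_centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())
    coherence_levels: tuple = COHERENCE_LEVELS
    seed: int = 0

    @property
    def label(self) -> str:
        if self.session_kind == "unbiased":
            return "unbiased"
        return f"biased_{self.frequent_direction:g}"

    @property
    def probabilities(self) -> np.ndarray:
        p = np.full(N_BINS, 1.0 / N_BINS)
        if self.session_kind == "biased":
            p[:] = (1.0 - self.frequent_share) / (N_BINS - 1)
            i = int(np.argmin(np.abs(self.direction_centers - self.frequent_direction)))
            p[i] = self.frequent_share
        return p


def make_session_design(
    session_kind: str,
    frequent_direction: Optional[float] = None,
    n_trials: Optional[int] = None,
    seed: int = 0,
) -> SessionDesign:
    """Build a session design with the standard direction probabilities.

    Unbiased: 16 equiprobable directions (p = 1/16 each) over ``n_trials``
    (default 480).  Biased: the frequent direction has p = 0.6 and every
    other direction p = 0.4/15, over 474 trials by default.
    """
    if session_kind not in ("unbiased", "biased"):
        raise ValueError(f"unknown session kind {session_kind!r}")
    if session_kind == "biased":
        if frequent_direction is None:
            raise ValueError("a biased design requires a frequent_direction")
        frequent_direction = float(circ_wrap(frequent_direction))
        if not np.any(np.isclose(BIN_CENTERS, frequent_direction)):
            raise ValueError("frequent_direction must be one of the 16 bin centers")
    elif frequent_direction is not None:
        raise ValueError("an unbiased design takes no frequent_direction")
    if n_trials is None:
        n_trials = N_TRIALS_UNBIASED if session_kind == "unbiased" else N_TRIALS_BIASED
    if n_trials < N_BINS:
        raise ValueError("need at least 16 trials")
    return SessionDesign(session_kind, int(n_trials), frequent_direction, seed=seed)


def _balanced_counts(probabilities: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n trials to the direction bins."""
    raw = probabilities * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for i in np.argsort(-remainder)[:short]:
        counts[i] += 1
    return counts


def sample_trials(
    design: SessionDesign,
    n_subjects: int = 1,
    rng: Optional[np.random.Generator] = None,
    balanced: bool = False,
) -> pd.DataFrame:
    """Draw per-subject trial tables (directions, coherences, fixation times).

    Directions are i.i.d. from the design probabilities and coherences i.i.d.
    uniform over the three levels; ``balanced=True`` instead fixes the
    per-direction counts by largest-remainder rounding and shuffles order.
    Reports are left empty (NaN) for the observer model to fill in.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    frames = []
    for s in range(n_subjects):
        if balanced:
            counts = _balanced_counts(design.probabilities, design.n_trials)
            dirs = rng.permutation(np.repeat(design.direction_centers, counts))
        else:
            dirs = rng.choice(
                design.direction_centers, size=design.n_trials, p=design.probabilities
            )
        coh = rng.choice(design.coherence_levels, size=design.n_trials)
        fix = rng.uniform(*FIXATION_RANGE_MS, size=design.n_trials)
        fix = np.round(fix / DT_MS) * DT_MS  # snap to the 2-ms sample grid
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s,
                    "session": design.label,
                    "trial": np.arange(design.n_trials),
                    "rdk_dir_deg": dirs,
                    "coherence": coh,
                    "report_dir_deg": np.nan,
                    "fixation_ms": fix,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Dot-field stimulus
# ---------------------------------------------------------------------------


@dataclass
class DotField:
    """Per-frame dot positions with signal/noise labels.

    positions: (n_frames, n_dots, 2) in deg, screen convention (y down);
    signal: (n_frames, n_dots) bool, constant within each 4-frame block.
    """

    positions: np.ndarray
    signal: np.ndarray
    rdk_dir: float
    coherence: float
    frame_rate: float = FRAME_RATE_HZ
    dot_speed: float = DOT_SPEED_DEG_S
    aperture_radius: float = APERTURE_RADIUS_DEG


def simulate_dot_field(
    rdk_dir: float,
    coherence: float,
    n_frames: int,
    rng: np.random.Generator,
    n_dots: Optional[int] = None,
) -> DotField:
    """Simulate the RDK dot field.

    Signal dots step by speed/frame_rate along the global direction; noise
    dots each get a fresh random direction at every 4-frame block, when the
    signal/noise labels are also reshuffled.  Dots leaving the 10-deg
    aperture re-enter from the diametrically opposite side.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    n_dots = default_dot_count() if n_dots is None else int(n_dots)
    n_signal = int(round(coherence * n_dots))
    step = DOT_SPEED_DEG_S / FRAME_RATE_HZ
    R = APERTURE_RADIUS_DEG

    # uniform start positions inside the aperture
    r = R * np.sqrt(rng.uniform(size=n_dots))
    phi = rng.uniform(0, 2 * np.pi, size=n_dots)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    positions = np.empty((n_frames, n_dots, 2))
    signal = np.zeros((n_frames, n_dots), dtype=bool)
    theta = np.deg2rad(rdk_dir)
    sig_step = step * np.array([np.cos(theta), np.sin(theta)])

    sig_idx = np.empty(0, dtype=int)
    noise_dirs = np.empty(n_dots)
    for f in range(n_frames):
        if f % BLOCK_FRAMES == 0:
            sig_idx = rng.choice(n_dots, size=n_signal, replace=False)
            noise_dirs = rng.uniform(0, 2 * np.pi, size=n_dots)
        is_sig = np.zeros(n_dots, dtype=bool)
        is_sig[sig_idx] = True
        positions[f] = pos
        signal[f] = is_sig
        steps = step * np.column_stack([np.cos(noise_dirs), np.sin(noise_dirs)])
        steps[is_sig] = sig_step
        pos = pos + steps
        rad = np.hypot(pos[:, 0], pos[:, 1])
        out = rad > R
        if out.any():
            # re-enter from the opposite side: shift by one diameter inward
            pos[out] *= (1.0 - 2.0 * R / rad[out])[:, None]
    return DotField(positions, signal, float(rdk_dir), float(coherence))


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------


@dataclass
class ObserverParams:
    """Generative parameters of the synthetic observer.

    Perceptual side: ``kappa_by_coherence`` and ``w_sensory_by_coherence``
    control stimulus-locked precision and the share of stimulus-locked
    reports; guesses come from a four-component cardinal von Mises mixture
    (``cardinal_weights`` over 0, +90, 180, -90 deg with shared
    ``kappa_cardinal``) times an avoidance factor
    1 - a * vM(theta; frequent, kappa_avoid)/max(vM); ``lapse_rate``
    replaces the report with a uniform draw.

    Oculomotor side: anticipatory drift ramps up during the gap to
    ``anticipation_gain`` deg/s toward a direction drawn around the expected
    one; visually driven pursuit starts at ``pursuit_latency_ms`` and rises
    toward gain x 10 deg/s along the stimulus direction; white velocity
    noise and Poisson raised-cosine saccade pulses are superimposed.
    """

    kappa_by_coherence: dict = field(
        default_factory=lambda: {0.05: 3.0, 0.15: 20.0, 0.40: 50.0}
    )
    w_sensory_by_coherence: dict = field(
        default_factory=lambda: {0.05: 0.45, 0.15: 0.75, 0.40: 0.95}
    )
    cardinal_weights: tuple = (1.0, 1.0, 1.0, 1.0)  # over 0, +90, 180, -90 deg
    kappa_cardinal: float = 3.0
    avoidance_strength: float = 0.8
    kappa_avoid: float = 8.0
    lapse_rate: float = 0.02
    anticipation_gain: float = 1.0  # deg/s
    anticipation_direction_spread: float = 25.0  # circular sd, deg
    idiosyncratic_direction: float = 0.0  # expected direction when unbiased
    pursuit_latency_ms: float = 140.0
    pursuit_rise_ms: float = 40.0
    pursuit_gain_by_coherence: dict = field(
        default_factory=lambda: {0.05: 0.30, 0.15: 0.60, 0.40: 0.90}
    )
    velocity_noise_sd: float = 0.5  # deg/s per sample
    saccade_rate: float = 1.0  # events/s
    saccade_peak_speed: float = 200.0  # deg/s
    saccade_duration_ms: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if any(w < 0 for w in self.cardinal_weights):
            raise ValueError("cardinal weights must be nonnegative")
        if not 0.0 <= self.avoidance_strength <= 1.0:
            raise ValueError("avoidance_strength must lie in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.pursuit_latency_ms <= 0:
            raise ValueError("pursuit latency must be positive")
        for d in (self.kappa_by_coherence, self.w_sensory_by_coherence):
            if any(v < 0 for v in d.values()):
                raise ValueError("concentrations and weights must be nonnegative")
        if any(not 0 <= w <= 1 for w in self.w_sensory_by_coherence.values()):
            raise ValueError("sensory weights must lie in [0, 1]")


CARDINAL_DIRECTIONS = (0.0, 90.0, 180.0, -90.0)

_GRID_DEG = np.arange(-180.0, 180.0, 0.1) + 0.1  # centers on (-180, 180]


def guess_density(
    observer: ObserverParams,
    frequent_direction: Optional[float],
    grid_deg: np.ndarray = _GRID_DEG,
) -> np.ndarray:
    """Normalized guess density on a degree grid (integrates to 1 over 360).

    Cardinal von Mises mixture, optionally multiplied by the avoidance
    factor around the frequent direction.  With all-equal zero-concentration
    cardinal components and no avoidance this is the uniform density.
    """
    g = np.deg2rad(grid_deg)
    w = np.asarray(observer.cardinal_weights, dtype=float)
    if w.sum() <= 0 or observer.kappa_cardinal <= 0:
        dens = np.full(grid_deg.size, 1.0 / 360.0)
    else:
        dens = np.zeros(grid_deg.size)
        for wi, mu in zip(w, CARDINAL_DIRECTIONS):
            dens += wi * sps.vonmises.pdf(g, observer.kappa_cardinal, loc=np.deg2rad(mu))
        dens /= w.sum()
    if frequent_direction is not None and observer.avoidance_strength > 0:
        avoid = sps.vonmises.pdf(
            g, observer.kappa_avoid, loc=np.deg2rad(frequent_direction)
        )
        dens = dens * (1.0 - observer.avoidance_strength * avoid / avoid.max())
    # renormalize on the grid (trapezoid step is uniform)
    step_deg = grid_deg[1] - grid_deg[0]
    dens = dens / (dens.sum() * step_deg)
    return dens


def _sample_from_grid(
    dens: np.ndarray, grid_deg: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    step = grid_deg[1] - grid_deg[0]
    p = dens * step
    p = p / p.sum()
    idx = rng.choice(grid_deg.size, size=size, p=p)
    return circ_wrap(grid_deg[idx] + rng.uniform(-step / 2, step / 2, size=size))


def simulate_report(
    trials: pd.DataFrame,
    observer: ObserverParams,
    rng: np.random.Generator,
    frequent_direction: Optional[float] = None,
) -> np.ndarray:
    """Draw perceptual reports for a trial table (vectorized mixture draw).

    ``frequent_direction`` is taken from the trial table's session label if
    not given; unbiased sessions have no avoidance term.
    """
    observer.validate()
    if frequent_direction is None and "session" in trials:
        lab = str(trials["session"].iloc[0])
        if lab.startswith("biased_"):
            frequent_direction = float(lab.split("_", 1)[1])
    n = len(trials)
    rdk = trials["rdk_dir_deg"].to_numpy(dtype=float)
    coh = trials["coherence"].to_numpy(dtype=float)
    kappa = np.array([observer.kappa_by_coherence[c] for c in coh])
    w_sens = np.array([observer.w_sensory_by_coherence[c] for c in coh])

    u = rng.uniform(size=n)
    lapse = u < observer.lapse_rate
    sensory = ~lapse & (rng.uniform(size=n) < w_sens)
    guess = ~lapse & ~sensory

    report = np.empty(n)
    report[lapse] = rng.uniform(-180.0, 180.0, size=int(lapse.sum()))
    if sensory.any():
        noise = sps.vonmises.rvs(kappa[sensory], size=int(sensory.sum()), random_state=rng)
        report[sensory] = circ_wrap(rdk[sensory] + np.rad2deg(noise))
    if guess.any():
        dens = guess_density(observer, frequent_direction)
        report[guess] = _sample_from_grid(dens, _GRID_DEG, int(guess.sum()), rng)
    return circ_wrap(report)


# ---------------------------------------------------------------------------
# Eye-trace generator
# ---------------------------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp from 0 to 1 on [0, 1] (zero slope at both ends)."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _raised_cosine(x: np.ndarray) -> np.ndarray:
    """C1 pulse on [0, 1], peak 1 at x = 0.5, zero outside."""
    y = np.zeros_like(x)
    inside = (x >= 0) & (x <= 1)
    y[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    return y


def simulate_eye_trace(
    rdk_dir: float,
    coherence: float,
    fixation_ms: float,
    observer: ObserverParams,
    rng: np.random.Generator,
    expected_direction: Optional[float] = None,
    n_saccades: Optional[int] = None,
):
    """Simulate a 500-Hz gaze trace for one trial.

    Returns ``(EyeTrace, ground_truth)`` where ``ground_truth`` holds the
    noise-free deterministic velocity, the injected-saccade intervals, and
    the window metrics (anticipation vector, acceleration, steady projected
    velocity) evaluated on the deterministic velocity at the sample grid --
    the quantities a correct analysis chain should recover.

    Velocity model (deg/s), all transitions C1-smooth so that zero-phase
    filtering does not bias the window means:

    * anticipatory component: smoothstep ramp from gap onset (-300 ms) to a
      plateau of ``anticipation_gain`` at -50 ms, held until the pursuit
      latency, then tapered to zero over 150 ms; direction drawn von Mises
      around ``expected_direction``;
    * visual component: gain(coh) x 10 deg/s x (1 - exp(-(t-lat)/tau))^2
      along the stimulus direction from ``pursuit_latency_ms`` on;
    * white Gaussian velocity noise per sample and channel;
    * saccades: Poisson-timed raised-cosine speed pulses in random
      directions (amplitude = peak x duration / 2).

    Position is the cumulative trapezoid integral of velocity.
    """
    fixation_ms = round(fixation_ms / DT_MS) * DT_MS
    t = np.arange(-(fixation_ms + GAP_MS), STIM_MS, DT_MS)
    lat = observer.pursuit_latency_ms
    tau = observer.pursuit_rise_ms

    # anticipation direction around the expected direction
    if expected_direction is None:
        expected_direction = observer.idiosyncratic_direction
    sd = observer.anticipation_direction_spread
    if sd > 0:
        kappa_ant = 1.0 / np.deg2rad(sd) ** 2
        ant_dir = circ_wrap(
            expected_direction
            + np.rad2deg(sps.vonmises.rvs(kappa_ant, random_state=rng))
        )
    else:
        ant_dir = float(expected_direction)

    ramp = _smoothstep((t + GAP_MS) / (GAP_MS - 50.0))  # 1 from t = -50 ms on
    taper = 1.0 - _smoothstep((t - lat) / 150.0)
    ant_profile = observer.anticipation_gain * ramp * taper
    ua = np.array([np.cos(np.deg2rad(ant_dir)), np.sin(np.deg2rad(ant_dir))])

    gain = observer.pursuit_gain_by_coherence[coherence]
    s = np.maximum(t - lat, 0.0) / tau
    vis_profile = gain * DOT_SPEED_DEG_S * (1.0 - np.exp(-s)) ** 2
    vis_profile[t < lat] = 0.0
    uv = np.array([np.cos(np.deg2rad(rdk_dir)), np.sin(np.deg2rad(rdk_dir))])

    det_vx = ant_profile * ua[0] + vis_profile * uv[0]
    det_vy = ant_profile * ua[1] + vis_profile * uv[1]

    vx = det_vx.copy()
    vy = det_vy.copy()
    if observer.velocity_noise_sd > 0:
        vx += rng.normal(0.0, observer.velocity_noise_sd, size=t.size)
        vy += rng.normal(0.0, observer.velocity_noise_sd, size=t.size)

    # saccades: Poisson count over the trace, raised-cosine speed pulses
    span_s = (t[-1] - t[0] + DT_MS) / 1000.0
    saccades = []
    if n_saccades is not None or observer.saccade_rate > 0:
        # a fixed count (for detector calibration) overrides the Poisson draw
        n_sacc = (
            n_saccades
            if n_saccades is not None
            else rng.poisson(observer.saccade_rate * span_s)
        )
        dur = observer.saccade_duration_ms
        for _ in range(n_sacc):
            t0 = rng.uniform(t[0], t[-1] - dur)
            direction = rng.uniform(0.0, 2.0 * np.pi)
            pulse = observer.saccade_peak_speed * _raised_cosine((t - t0) / dur)
            vx += pulse * np.cos(direction)
            vy += pulse * np.sin(direction)
            saccades.append((float(t0), float(t0 + dur)))

    dt_s = DT_MS / 1000.0
    x = np.concatenate([[0.0], np.cumsum((vx[1:] + vx[:-1]) / 2.0) * dt_s])
    y = np.concatenate([[0.0], np.cumsum((vy[1:] + vy[:-1]) / 2.0) * dt_s])

    def _wmean(profile_x, profile_y, lo, hi):
        sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
        return float(profile_x[sel].mean()), float(profile_y[sel].mean())

    ax, ay = _wmean(det_vx, det_vy, -50.0, 100.0)
    e1x, e1y = _wmean(det_vx, det_vy, 100.0, 120.0)
    e2x, e2y = _wmean(det_vx, det_vy, 200.0, 220.0)
    sx, sy = _wmean(det_vx, det_vy, 400.0, 600.0)
    proj = lambda px, py: px * uv[0] + py * uv[1]
    ground_truth = {
        "ant_vx": ax,
        "ant_vy": ay,
        "ant_amp": float(np.hypot(ax, ay)),
        "ant_angle": float(circ_wrap(np.rad2deg(np.arctan2(ay, ax)))),
        "ant_dir": float(ant_dir),
        "accel": float((proj(e2x, e2y) - proj(e1x, e1y)) / 0.1),
        "steady_vproj": float(proj(sx, sy)),
        "saccades": saccades,
        "vx": vx,
        "vy": vy,
        "det_vx": det_vx,
        "det_vy": det_vy,
    }
    return EyeTrace(t, x, y), ground_truth


def simulate_dataset(
    designs,
    observer: ObserverParams,
    n_subjects: int,
    seed: int = 0,
    with_traces: bool = False,
):
    """Simulate trials + reports (and optionally traces) for many subjects.

    One global seed is split into independent per-(subject, session, trial)
    streams via ``numpy`` seed sequences, so any single trial can be
    regenerated in isolation.  Yields a trial table; when ``with_traces`` is
    set, also a list of ``(index, EyeTrace, ground_truth)`` aligned with the
    table rows.
    """
    tables = []
    traces = []
    row0 = 0
    for d_i, design in enumerate(designs):
        for s in range(n_subjects):
            ss = np.random.SeedSequence(seed, spawn_key=(d_i, s))
            rng = np.random.default_rng(ss)
            trials = sample_trials(replace(design, seed=0), 1, rng)
            trials["subject_id"] = s
            trials["report_dir_deg"] = simulate_report(trials, observer, rng)
            if with_traces:
                expected = (
                    design.frequent_direction
                    if design.frequent_direction is not None
                    else observer.idiosyncratic_direction
                )
                for k in range(len(trials)):
                    trng = np.random.default_rng(
                        np.random.SeedSequence(seed, spawn_key=(d_i, s, k))
                    )
                    trace, gt = simulate_eye_trace(
                        trials["rdk_dir_deg"].iat[k],
                        trials["coherence"].iat[k],
                        trials["fixation_ms"].iat[k],
                        observer,
                        trng,
                        expected_direction=expected,
                    )
                    traces.append((row0 + k, trace, gt))
            row0 += len(trials)
            tables.append(trials)
    table = pd.concat(tables, ignore_index=True)
    return (table, traces) if with_traces else table
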