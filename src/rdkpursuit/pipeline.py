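"""Configuration, orchestration and file I/O for full analysis runs.

A run ties together: simulate (trial tables + eye traces) -> pursuit
kinematics -> perceptual classification -> inferential statistics ->
structured report.  All window constants and thresholds live in
``AnalysisConfig`` (single source of truth); every random draw derives
from the configured seed, so re-running a config reproduces every output
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .angles import BIN_HALF_WIDTH, circ_diff, circ_wrap
from .oculo import (
    AMP_VALID_RANGE,
    ANTICIPATION_WINDOW,
    ACCEL_EARLY_WINDOW,
    ACCEL_LATE_WINDOW,
    DT_MS,
    STEADY_WINDOW,
    EyeTrace,
    analyze_trace,
    anticipation_histogram,
)
from .percept import classify_trials, choice_histogram
from .stats import (
    angle_report_correlation,
    counts_from_angles,
    histogram_permutation_test,
    paired_comparison,
    serial_dependence_curve,
)
from .synthdata import (
    FIXATION_RANGE_MS,
    GAP_MS,
    STIM_MS,
    ObserverParams,
    make_session_design,
    simulate_dataset,
)

TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "trial",
    "rdk_dir_deg",
    "coherence",
    "report_dir_deg",
    "fixation_ms",
]
TRACE_COLUMNS = ["subject_id", "session", "trial", "t_ms", "x_deg", "y_deg"]


@dataclass
class SessionSpec:
    kind: str
    n_trials: Optional[int] = None
    frequent_direction: Optional[float] = None


@dataclass
class AnalysisConfig:
    """All tunable constants of a run, with the standard defaults."""

    seed: int = 0
    n_subjects: int = 21
    sessions: list = field(
        default_factory=lambda: [
            SessionSpec("unbiased"),
            SessionSpec("biased", frequent_direction=0.0),
            SessionSpec("biased", frequent_direction=-135.0),
        ]
    )
    observer: ObserverParams = field(default_factory=ObserverParams)
    anticipation_window: tuple = ANTICIPATION_WINDOW
    accel_early_window: tuple = ACCEL_EARLY_WINDOW
    accel_late_window: tuple = ACCEL_LATE_WINDOW
    steady_window: tuple = STEADY_WINDOW
    amp_valid_range: tuple = AMP_VALID_RANGE
    saccade_threshold: float = 30.0
    saccade_pad_ms: float = 10.0
    n_perm: int = 2000
    alpha: float = 0.01
    pooled_coherences: tuple = (0.05, 0.15)
    simulate_traces: bool = True
    write_traces: bool = False
    run_mixed_models: bool = False

    def validate(self) -> None:
        self.observer.validate()
        span_lo = -(FIXATION_RANGE_MS[0] + GAP_MS)
        for name in (
            "anticipation_window",
            "accel_early_window",
            "accel_late_window",
            "steady_window",
        ):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name}: empty window [{lo}, {hi})")
            if lo < span_lo or hi > STIM_MS:
                raise ValueError(
                    f"{name}: [{lo}, {hi}) ms falls outside the trace span "
                    f"[{span_lo}, {STIM_MS}] ms"
                )
        if self.amp_valid_range[0] <= 0 or self.amp_valid_range[1] <= self.amp_valid_range[0]:
            raise ValueError("amp_valid_range must be an increasing positive pair")
        if self.saccade_threshold <= 0:
            raise ValueError("saccade threshold must be positive")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "sessions" in d:
            d["sessions"] = [
                s if isinstance(s, SessionSpec) else SessionSpec(**s)
                for s in d["sessions"]
            ]
        if "observer" in d and not isinstance(d["observer"], ObserverParams):
            obs = dict(d["observer"])
            for key in ("kappa_by_coherence", "w_sensory_by_coherence",
                        "pursuit_gain_by_coherence"):
                if key in obs:
                    obs[key] = {float(k): float(v) for k, v in obs[key].items()}
            if "cardinal_weights" in obs:
                obs["cardinal_weights"] = tuple(obs["cardinal_weights"])
            d["observer"] = ObserverParams(**obs)
        for key in ("anticipation_window", "accel_early_window", "accel_late_window",
                    "steady_window", "amp_valid_range", "pooled_coherences"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON serialization."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for col in ("rdk_dir_deg", "report_dir_deg"):
        vals = df[col].to_numpy(dtype=float)
        wrapped = circ_wrap(vals)
        changed = np.isfinite(vals) & (np.abs(vals - wrapped) > 1e-9)
        if changed.any():
            import warnings

            warnings.warn(
                f"{col}: {int(changed.sum())} angles outside (-180, 180] were "
                "wrapped canonically",
                stacklevel=2,
            )
        df[col] = np.where(np.isfinite(vals), wrapped, vals)
    return df


def write_traces(traces: pd.DataFrame, path) -> None:
    traces.to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    for _, g in df.groupby(["subject_id", "session", "trial"]):
        dt = np.diff(g["t_ms"].to_numpy(dtype=float))
        if dt.size and (np.ptp(dt) > 1e-6 or abs(dt[0] - DT_MS) > 1e-6):
            raise ValueError("non-uniform trace sampling (expected 2-ms grid)")
    return df


def traces_to_long(trials: pd.DataFrame, traces) -> pd.DataFrame:
    """Stack per-trial EyeTrace objects into the long CSV schema."""
    rows = []
    for idx, trace, _gt in traces:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": trials["subject_id"].iat[idx],
                    "session": trials["session"].iat[idx],
                    "trial": trials["trial"].iat[idx],
                    "t_ms": trace.t,
                    "x_deg": trace.x,
                    "y_deg": trace.y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_plain(report), indent=2))


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def _designs_from_config(config: AnalysisConfig):
    return [
        make_session_design(s.kind, s.frequent_direction, s.n_trials)
        for s in config.sessions
    ]


def kinematics_from_traces(
    trials: pd.DataFrame, traces, config: AnalysisConfig
) -> pd.DataFrame:
    """Run the pursuit measurement chain on per-trial traces.

    ``traces`` is an iterable of (row_index, EyeTrace, ground_truth|None)
    aligned with ``trials`` rows.  Returns one KinematicSummary row per
    trial keyed by (subject_id, session, trial).
    """
    rows = []
    for idx, trace, _gt in traces:
        summ = analyze_trace(
            trace,
            trials["rdk_dir_deg"].iat[idx],
            saccade_threshold=config.saccade_threshold,
            saccade_pad_ms=config.saccade_pad_ms,
            anticipation_window=config.anticipation_window,
            accel_early_window=config.accel_early_window,
            accel_late_window=config.accel_late_window,
            steady_window=config.steady_window,
            amp_valid_range=config.amp_valid_range,
        )
        rows.append(
            {
                "subject_id": trials["subject_id"].iat[idx],
                "session": trials["session"].iat[idx],
                "trial": trials["trial"].iat[idx],
                **dataclasses.asdict(summ),
            }
        )
    return pd.DataFrame(rows)


def _stats_stage(
    classified: pd.DataFrame,
    kinematics: Optional[pd.DataFrame],
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> dict:
    out: dict = {}

    # accuracy by session x coherence
    acc = (
        classified.assign(correct=classified["label"] == "correct")
        .groupby(["session", "coherence"])["correct"]
        .mean()
    )
    out["accuracy"] = {f"{s}@{c:g}": float(v) for (s, c), v in acc.items()}

    sessions = list(classified["session"].unique())
    biased = [s for s in sessions if s.startswith("biased_")]

    # per-bin permutation tests on error-trial choice histograms
    err = classified[
        (classified["label"] != "correct")
        & classified["coherence"].isin(config.pooled_coherences)
    ]
    out["choice_permutation"] = {}
    for lab in biased:
        cb, _ = counts_from_angles(err[err["session"] == lab], "response_bin")
        cu, _ = counts_from_angles(err[err["session"] == "unbiased"], "response_bin")
        if cb.shape[0] != cu.shape[0] or (cb.sum(1) == 0).any() or (cu.sum(1) == 0).any():
            out["choice_permutation"][lab] = {"status": "skipped: missing subjects"}
            continue
        res = histogram_permutation_test(
            cb, cu, config.n_perm, rng, config.alpha
        )
        out["choice_permutation"][lab] = {
            "observed_diff": res.observed_diff,
            "p_per_bin": res.p_per_bin,
            "significant_bins": res.significant_bins,
        }

    if kinematics is not None and len(kinematics):
        valid = kinematics[kinematics["anticipation_valid"]]
        out["anticipation_permutation"] = {}
        for lab in biased:
            cb, _ = counts_from_angles(
                valid[valid["session"] == lab], "anticipation_angle"
            )
            cu, _ = counts_from_angles(
                valid[valid["session"] == "unbiased"], "anticipation_angle"
            )
            if (
                cb.shape[0] != cu.shape[0]
                or (cb.sum(1) == 0).any()
                or (cu.sum(1) == 0).any()
            ):
                out["anticipation_permutation"][lab] = {
                    "status": "skipped: missing subjects"
                }
                continue
            res = histogram_permutation_test(cb, cu, config.n_perm, rng, config.alpha)
            out["anticipation_permutation"][lab] = {
                "observed_diff": res.observed_diff,
                "p_per_bin": res.p_per_bin,
                "significant_bins": res.significant_bins,
            }

        # paired comparison of anticipatory vproj toward each frequent direction,
        # on trials whose anticipation points into the frequent-direction bin
        out["anticipation_paired"] = {}
        for lab in biased:
            freq_dir = float(lab.split("_", 1)[1])
            per_subj = {}
            for ses in ("unbiased", lab):
                sel = valid[
                    (valid["session"] == ses)
                    & (
                        np.abs(circ_diff(valid["anticipation_angle"], freq_dir))
                        < BIN_HALF_WIDTH
                    )
                ]
                per_subj[ses] = sel.groupby("subject_id")["anticipation_amp"].mean()
            both = pd.concat(per_subj, axis=1).dropna()
            if len(both) < 3:
                out["anticipation_paired"][lab] = {"status": "skipped: too few subjects"}
                continue
            pc = paired_comparison(both[lab].to_numpy(), both["unbiased"].to_numpy())
            out["anticipation_paired"][lab] = dataclasses.asdict(pc)

        # steady-state direction vs perceptual report, per session x coherence
        merged = kinematics.merge(
            classified[["subject_id", "session", "trial", "report_dir_deg", "coherence"]],
            on=["subject_id", "session", "trial"],
        )
        out["steady_report_correlation"] = {}
        for (ses, coh), g in merged.groupby(["session", "coherence"]):
            g = g.dropna(subset=["steady_angle", "report_dir_deg"])
            if len(g) >= 10:
                r, p = angle_report_correlation(
                    g["steady_angle"].to_numpy(), g["report_dir_deg"].to_numpy()
                )
                out["steady_report_correlation"][f"{ses}@{coh:g}"] = {"r": r, "p": p}

    # serial dependence, unbiased session only
    unb = classified[classified["session"] == "unbiased"]
    if len(unb) and unb.groupby("subject_id").size().min() >= 32:
        curve = serial_dependence_curve(unb)
        out["serial_dependence"] = {
            "bin_centers": curve.bin_centers,
            "group_mean": curve.group_mean,
            "group_sem": curve.group_sem,
            "ww_F": curve.ww_F,
            "ww_p": curve.ww_p,
        }

    if config.run_mixed_models:
        from .stats import fit_anticipation_lmm, fit_correctness_glmm

        try:
            glmm = fit_correctness_glmm(classified)
            out["correctness_glmm"] = {
                "params": glmm.params.to_dict(),
                "pvalues": glmm.pvalues.to_dict(),
                "converged": glmm.converged,
            }
        except (ValueError, RuntimeError) as e:
            out["correctness_glmm"] = {"status": f"failed: {e}"}
        if kinematics is not None and len(kinematics):
            lmm_df = _anticipation_history_table(classified, kinematics)
            try:
                lmm = fit_anticipation_lmm(lmm_df)
                out["anticipation_lmm"] = {
                    "params": lmm.params.to_dict(),
                    "pvalues": lmm.pvalues.to_dict(),
                    "converged": lmm.converged,
                }
            except (ValueError, RuntimeError, KeyError) as e:
                out["anticipation_lmm"] = {"status": f"failed: {e}"}
    return out


def _anticipation_history_table(
    classified: pd.DataFrame, kinematics: pd.DataFrame
) -> pd.DataFrame:
    """Anticipation angle on trial n vs stimulus direction on trial n-1
    (unbiased session, valid anticipation trials only)."""
    unb = classified[classified["session"] == "unbiased"].sort_values(
        ["subject_id", "trial"]
    )
    unb = unb.assign(
        prev_rdk_dir=unb.groupby("subject_id")["rdk_dir_deg"].shift(1)
    ).dropna(subset=["prev_rdk_dir"])
    kin = kinematics[kinematics["anticipation_valid"]][
        ["subject_id", "session", "trial", "anticipation_angle"]
    ]
    return unb.merge(kin, on=["subject_id", "session", "trial"])


def run_pipeline(config: AnalysisConfig, outdir) -> dict:
    """Execute the full simulate -> analyze -> report chain.

    Returns the run report (also written to ``outdir/report.json`` along
    with the trial, kinematics, and classified tables as CSV).  Idempotent:
    rerunning the same config and seed reproduces the outputs bit-exactly.
    """
    t0 = time.time()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    designs = _designs_from_config(config)

    stage = "simulate"
    try:
        if config.simulate_traces:
            trials, traces = simulate_dataset(
                designs, config.observer, config.n_subjects, config.seed, True
            )
        else:
            trials = simulate_dataset(
                designs, config.observer, config.n_subjects, config.seed, False
            )
            traces = []
        write_trials(trials, outdir / "trials.csv")
        if config.write_traces and traces:
            write_traces(traces_to_long(trials, traces), outdir / "traces.csv")

        stage = "kinematics"
        kinematics = (
            kinematics_from_traces(trials, traces, config) if traces else None
        )
        if kinematics is not None:
            kinematics.to_csv(outdir / "kinematics.csv", index=False)

        stage = "classify"
        classified = classify_trials(trials)
        classified.to_csv(outdir / "classified.csv", index=False)

        stage = "stats"
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(999,)))
        stats_out = _stats_stage(classified, kinematics, config, rng)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    counts = {
        "trials_generated": int(len(trials)),
        "error_trials": int((classified["label"] != "correct").sum()),
        "correct_trials": int((classified["label"] == "correct").sum()),
    }
    if kinematics is not None:
        amp = kinematics["anticipation_amp"]
        lo, hi = config.amp_valid_range
        counts.update(
            {
                "anticipation_valid": int(kinematics["anticipation_valid"].sum()),
                "anticipation_excluded_amplitude": int(
                    ((amp < lo) | (amp > hi)).sum()
                ),
                "anticipation_missing_window": int(amp.isna().sum()),
            }
        )

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "counts": counts,
        "stats": stats_out,
        "wall_clock_s": time.time() - t0,
    }
    write_report(report, outdir / "report.json")
    return report


def analyze_dataset(data_dir, config: AnalysisConfig, outdir) -> dict:
    """Run the analysis stages on a pre-existing dataset directory.

    Reads ``trials.csv`` (and ``traces.csv`` if present) from ``data_dir``;
    never mutates the inputs.
    """
    t0 = time.time()
    config.validate()
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = read_trials(data_dir / "trials.csv")
    kinematics = None
    if (data_dir / "traces.csv").exists():
        long = read_traces(data_dir / "traces.csv")
        traces = []
        for (_s, _ses, _tr), g in long.groupby(["subject_id", "session", "trial"]):
            idx = trials.index[
                (trials["subject_id"] == _s)
                & (trials["session"] == _ses)
                & (trials["trial"] == _tr)
            ][0]
            traces.append(
                (
                    idx,
                    EyeTrace(
                        g["t_ms"].to_numpy(), g["x_deg"].to_numpy(), g["y_deg"].to_numpy()
                    ),
                    None,
                )
            )
        kinematics = kinematics_from_traces(trials, traces, config)
        kinematics.to_csv(outdir / "kinematics.csv", index=False)
    classified = classify_trials(trials)
    classified.to_csv(outdir / "classified.csv", index=False)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(999,)))
    stats_out = _stats_stage(classified, kinematics, config, rng)
    report = {
        "version": __version__,
        "config": config.to_dict(),
        "counts": {"trials_analyzed": int(len(trials))},
        "stats": stats_out,
        "wall_clock_s": time.time() - t0,
    }
    write_report(report, outdir / "report.json")
    return report
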