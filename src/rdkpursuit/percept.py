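"""Circular angular errors, response classification, and bias scores.

A report is *correct* when it falls in the 22.5-deg bin centered on the
true direction, *opposite* when it falls in the bin centered 180 deg away,
and a *general* error otherwise.  On error trials two per-trial scores
summarize long-standing directional preferences: a cardinal score
(+1/4 for a cardinal response bin, -1/12 otherwise, so uniform guessing
scores 0 in expectation) and a hemifield score (+1/7 for a strictly
upward/negative bin, -1/7 for strictly downward/positive, 0 for the 0 and
180 deg boundary bins, which belong to neither hemifield).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import (
    BIN_CENTERS,
    BIN_HALF_WIDTH,
    AngularHistogram,
    DirectionBins,
    bin_center,
    bin_index,
    circ_diff,
    circ_wrap,
)

__all__ = [
    "circ_wrap",
    "circ_diff",
    "ClassifiedTrial",
    "classify_response",
    "classify_trials",
    "cardinal_score",
    "hemifield_score",
    "choice_histogram",
    "DirectionBins",
]

_BINS = DirectionBins()
_CARDINAL = _BINS.cardinal_mask
_UPPER = _BINS.upper_mask
_LOWER = _BINS.lower_mask


@dataclass
class ClassifiedTrial:
    """Outcome of classifying one report against the true direction."""

    delta: float  # signed error, stimulus minus report, in (-180, 180]
    label: str  # "correct" | "opposite" | "general"
    response_bin: float  # center of the bin holding the report
    cardinal_score: float  # NaN on correct trials
    hemifield_score: float  # NaN on correct trials


def cardinal_score(response_bin: float) -> float:
    """Per-trial cardinal bias score (error trials only).

    +1/4 if the response bin is cardinal, else -1/12: counts normalized by
    the number of bins per category (4 cardinal vs 12 non-cardinal), so a
    uniform guesser scores 0 in expectation.
    """
    return 0.25 if _CARDINAL[bin_index(response_bin)] else -1.0 / 12.0


def hemifield_score(response_bin: float) -> float:
    """Per-trial upper-vs-lower hemifield score (error trials only).

    +1/7 for a strictly negative (upward) bin, -1/7 for a strictly positive
    (downward) one, 0 for the 0 and 180 deg boundary bins; 7 bins per
    hemifield category.
    """
    i = bin_index(response_bin)
    if _UPPER[i]:
        return 1.0 / 7.0
    if _LOWER[i]:
        return -1.0 / 7.0
    return 0.0


def classify_response(rdk_dir: float, report_dir: float) -> ClassifiedTrial:
    """Classify a single report; see module docstring for the bin rule."""
    d_rep = float(circ_diff(report_dir, rdk_dir))
    rb = float(bin_center(report_dir))
    err_bin = bin_center(d_rep)
    if err_bin == 0.0:
        label = "correct"
    elif err_bin == 180.0:
        label = "opposite"
    else:
        label = "general"
    delta = float(circ_diff(rdk_dir, report_dir))
    if label == "correct":
        cs = hs = np.nan
    else:
        cs = cardinal_score(rb)
        hs = hemifield_score(rb)
    return ClassifiedTrial(delta, label, rb, cs, hs)


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a trial table.

    Adds columns delta, label, response_bin, cardinal_score, hemifield_score
    to a copy of the input (requires rdk_dir_deg and report_dir_deg).
    """
    rdk = trials["rdk_dir_deg"].to_numpy(dtype=float)
    rep = trials["report_dir_deg"].to_numpy(dtype=float)
    err_bin = BIN_CENTERS[bin_index(circ_diff(rep, rdk))]
    label = np.where(
        err_bin == 0.0, "correct", np.where(err_bin == 180.0, "opposite", "general")
    )
    rb_idx = bin_index(rep)
    rb = BIN_CENTERS[rb_idx]
    cs = np.where(_CARDINAL[rb_idx], 0.25, -1.0 / 12.0)
    hs = np.where(_UPPER[rb_idx], 1.0 / 7.0, np.where(_LOWER[rb_idx], -1.0 / 7.0, 0.0))
    correct = label == "correct"
    out = trials.copy()
    out["delta"] = circ_diff(rdk, rep)
    out["label"] = label
    out["response_bin"] = rb
    out["cardinal_score"] = np.where(correct, np.nan, cs)
    out["hemifield_score"] = np.where(correct, np.nan, hs)
    return out


def choice_histogram(
    classified: pd.DataFrame, coherences=None
) -> AngularHistogram:
    """Histogram of response bins among error trials.

    ``coherences`` optionally restricts to a subset of coherence levels
    (e.g. pooling the two low-reliability levels 0.05 and 0.15).
    """
    err = classified[classified["label"] != "correct"]
    if coherences is not None:
        err = err[err["coherence"].isin(list(coherences))]
    if len(err) == 0:
        raise ValueError("no error trials to histogram")
    return AngularHistogram.from_angles(err["response_bin"].to_numpy())
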