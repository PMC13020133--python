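"""Inferential layer: permutation histogram tests, circular ANOVA,
serial-dependence curves, paired comparisons, correlations, and mixed-model
wrappers.

The centerpiece is a per-bin permutation test for the difference between
two sessions' normalized 16-bin direction histograms, averaged over
subjects.  The null relabels trials between the two sessions *within* each
subject while preserving the per-session trial counts; because the
statistic is a per-bin frequency, that relabeling is realized exactly (and
cheaply) by drawing the per-bin counts of one session from the
multivariate hypergeometric distribution over the pooled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .angles import (
    BIN_CENTERS,
    N_BINS,
    bin_index,
    circ_diff,
    circ_mean_deg,
    circ_std_deg,
    circ_wrap,
    resultant_length,
)

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.01


# ---------------------------------------------------------------------------
# Per-bin permutation test on histogram differences
# ---------------------------------------------------------------------------


@dataclass
class HistogramDiffResult:
    """Observed biased-minus-unbiased frequency difference and per-bin p."""

    bin_centers: np.ndarray
    observed_diff: np.ndarray  # mean over subjects of (freq_b - freq_u)
    p_per_bin: np.ndarray
    n_permutations: int
    alpha: float

    @property
    def significant_bins(self) -> np.ndarray:
        return self.bin_centers[self.p_per_bin < self.alpha]


def counts_from_angles(df: pd.DataFrame, angle_col: str, subject_col: str = "subject_id"):
    """Per-subject 16-bin counts (n_subjects, 16); subjects in sorted order."""
    subjects = np.sort(df[subject_col].unique())
    counts = np.zeros((subjects.size, N_BINS), dtype=np.int64)
    for i, s in enumerate(subjects):
        a = df.loc[df[subject_col] == s, angle_col].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        counts[i] = np.bincount(bin_index(a), minlength=N_BINS)
    return counts, subjects


def histogram_permutation_test(
    counts_biased: np.ndarray,
    counts_unbiased: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    rng: Optional[np.random.Generator] = None,
    alpha: float = DEFAULT_ALPHA,
    alternative: str = "observed",
    unit: str = "trials",
) -> HistogramDiffResult:
    """Permutation test of per-bin histogram differences between sessions.

    ``counts_*`` are (n_subjects, 16) integer bin counts.  The observed
    statistic per bin is the mean over subjects of the normalized-frequency
    difference (biased minus unbiased).  The null re-splits each subject's
    pooled trials into the two sessions at random, preserving the original
    per-session counts (``unit="trials"``); ``unit="subjects"`` instead
    swaps whole sessions within randomly chosen subjects.  p-values use the
    add-one estimator (1 + exceedances) / (n_perm + 1), one-sided in the
    direction of the observed difference by default
    (``alternative="two-sided"`` compares magnitudes).
    """
    cb = np.asarray(counts_biased, dtype=np.int64)
    cu = np.asarray(counts_unbiased, dtype=np.int64)
    if cb.ndim != 2 or cb.shape != cu.shape or cb.shape[1] != N_BINS:
        raise ValueError("expected matching (n_subjects, 16) count matrices")
    if cb.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if (cb.sum(axis=1) == 0).any() or (cu.sum(axis=1) == 0).any():
        raise ValueError("every subject needs trials in both sessions")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng() if rng is None else rng

    S = cb.shape[0]
    nb = cb.sum(axis=1).astype(float)
    nu = cu.sum(axis=1).astype(float)
    observed = (cb / nb[:, None] - cu / nu[:, None]).mean(axis=0)

    null = np.zeros((n_perm, N_BINS))
    if unit == "trials":
        pooled = cb + cu
        for s in range(S):
            draws = rng.multivariate_hypergeometric(
                pooled[s], int(nb[s]), size=n_perm
            ).astype(float)
            null += draws / nb[s] - (pooled[s] - draws) / nu[s]
        null /= S
    elif unit == "subjects":
        diffs = cb / nb[:, None] - cu / nu[:, None]
        flips = rng.integers(0, 2, size=(n_perm, S)) * 2 - 1
        null = flips @ diffs / S
    else:
        raise ValueError("unit must be 'trials' or 'subjects'")

    eps = 1e-12  # count float ties as exceedances (conservative)
    if alternative == "observed":
        upper = (null >= observed[None, :] - eps).sum(axis=0)
        lower = (null <= observed[None, :] + eps).sum(axis=0)
        exceed = np.where(observed >= 0, upper, lower)
    elif alternative == "two-sided":
        exceed = (np.abs(null) >= np.abs(observed)[None, :] - eps).sum(axis=0)
    else:
        raise ValueError("alternative must be 'observed' or 'two-sided'")
    p = (1.0 + exceed) / (n_perm + 1.0)
    return HistogramDiffResult(BIN_CENTERS.copy(), observed, p, n_perm, alpha)


# ---------------------------------------------------------------------------
# Watson-Williams circular ANOVA
# ---------------------------------------------------------------------------


@dataclass
class WatsonWilliamsResult:
    F: float
    df1: int
    df2: int
    p: float
    correction: float
    group_resultants: np.ndarray  # per-group resultant lengths (unnormalized)


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood von Mises concentration from resultant length r."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    denom = r**3 - 4 * r**2 + 3 * r
    return 1.0 / denom if denom > 0 else np.inf


def watson_williams(groups: Sequence[np.ndarray]) -> WatsonWilliamsResult:
    """Watson-Williams one-way circular ANOVA for equality of mean directions.

    Classical high-concentration F approximation with the standard
    correction factor 1 + 3/(8 kappa), kappa estimated from the
    within-group mean resultant length.  A warning is raised when the
    within-group resultant length is below 0.45 (the approximation degrades
    for dispersed data).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.size for g in groups])
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 angles")
    Ri = np.array([resultant_length(g) * g.size for g in groups])
    if np.any(Ri < 1e-12):
        raise ValueError("a group has zero resultant length")
    N = int(ns.sum())
    k = len(groups)
    R = resultant_length(np.concatenate(groups)) * N
    rw = Ri.sum() / N
    if rw < 0.45:
        warnings.warn(
            "within-group resultant length < 0.45; the Watson-Williams "
            "approximation may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    kappa = _kappa_from_r(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if 0 < kappa < np.inf else 1.0
    denom = N - Ri.sum()
    if denom <= 0:
        F = 0.0
    else:
        F = correction * ((Ri.sum() - R) * (N - k)) / (denom * (k - 1))
    F = max(float(F), 0.0)
    p = float(sps.f.sf(F, k - 1, N - k))
    return WatsonWilliamsResult(F, k - 1, N - k, p, float(correction), Ri)


# ---------------------------------------------------------------------------
# Serial dependence
# ---------------------------------------------------------------------------


@dataclass
class SerialCurve:
    """Angular error as a function of the direction change between trials."""

    bin_centers: np.ndarray  # rdk-direction-difference bins, 22.5-deg steps
    subject_means: np.ndarray  # (n_subjects, 16) circular means of delta, deg
    group_mean: np.ndarray  # circular mean over subjects per bin
    group_sem: np.ndarray  # circular sd over subjects / sqrt(n) per bin
    ww_F: float
    ww_p: float


def serial_dependence_curve(
    trials: pd.DataFrame,
    subject_col: str = "subject_id",
    order_col: str = "trial",
    dir_col: str = "rdk_dir_deg",
    delta_col: str = "delta",
) -> SerialCurve:
    """Bin the current-trial error by the direction change from trial n-1.

    Within each subject (trials in presentation order; the first trial has
    no predecessor and is dropped) the direction difference
    rdkDir(n) - rdkDir(n-1) is wrapped to (-180, 180], binned at 22.5-deg
    steps, and the circular mean of delta per bin is computed.  The group
    curve is the circular mean (+/- circular SEM) over subjects, and a
    Watson-Williams ANOVA across bins on the per-subject means tests for a
    history effect.
    """
    subjects = np.sort(trials[subject_col].unique())
    means = np.full((subjects.size, N_BINS), np.nan)
    for i, s in enumerate(subjects):
        sub = trials[trials[subject_col] == s].sort_values(order_col)
        if len(sub) < 2:
            raise ValueError("need at least 2 trials per subject")
        dirs = sub[dir_col].to_numpy(dtype=float)
        delta = sub[delta_col].to_numpy(dtype=float)
        dd = circ_diff(dirs[1:], dirs[:-1])
        idx = bin_index(dd)
        d1 = delta[1:]
        for b in range(N_BINS):
            sel = idx == b
            if sel.any():
                means[i, b] = circ_mean_deg(d1[sel])
    group_mean = np.array(
        [
            circ_mean_deg(col[np.isfinite(col)]) if np.isfinite(col).any() else np.nan
            for col in means.T
        ]
    )
    group_sem = np.array(
        [
            circ_std_deg(col[np.isfinite(col)]) / np.sqrt(np.isfinite(col).sum())
            if np.isfinite(col).sum() > 1
            else np.nan
            for col in means.T
        ]
    )
    groups = [col[np.isfinite(col)] for col in means.T]
    groups = [g for g in groups if g.size >= 2]
    ww = watson_williams(groups)
    return SerialCurve(BIN_CENTERS.copy(), means, group_mean, group_sem, ww.F, ww.p)


# ---------------------------------------------------------------------------
# Paired comparisons and correlations
# ---------------------------------------------------------------------------


@dataclass
class PairedComparison:
    t: float
    p: float
    cohens_d: float
    wilcoxon_p: float
    shapiro_p: float
    n: int
    degenerate: bool = False


class ZeroVarianceError(ValueError):
    """Paired differences have zero variance but a nonzero mean."""


def paired_comparison(values_a, values_b) -> PairedComparison:
    """Paired t-test, Wilcoxon signed-rank, Shapiro-Wilk and Cohen's d.

    d = mean(diff) / sd(diff).  Identical vectors return a degenerate
    zero-effect result (t = 0, p = 1 by convention); a constant nonzero
    shift has no defined test statistic and raises ``ZeroVarianceError``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected equal-length paired vectors")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return PairedComparison(0.0, 1.0, 0.0, 1.0, np.nan, a.size, True)
        raise ZeroVarianceError("paired differences are a nonzero constant")
    t, p = sps.ttest_rel(a, b)
    d = diff.mean() / diff.std(ddof=1)
    w_p = float(sps.wilcoxon(a, b).pvalue)
    sh_p = float(sps.shapiro(diff).pvalue)
    return PairedComparison(float(t), float(p), float(d), w_p, sh_p, a.size)


def angle_report_correlation(angles_a, angles_b):
    """Trial-by-trial Pearson correlation between two angular variables.

    Pearson correlation is not intrinsically circular; both inputs are
    wrapped to (-180, 180] and re-centered on the circular mean of the
    first variable before correlating, so that the wrap cut falls where the
    first variable has least mass.  This is a documented convention, not a
    circular-circular correlation coefficient.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.shape != b.shape or a.size < 10:
        raise ValueError("need paired angle vectors with n >= 10")
    mu = circ_mean_deg(a)
    a0 = circ_diff(a, mu)
    b0 = circ_diff(b, mu)
    if np.ptp(a0) == 0.0 or np.ptp(b0) == 0.0:
        raise ValueError("degenerate (constant) angle vector")
    r, p = sps.pearsonr(a0, b0)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Mixed-model wrappers (contract level; solvers delegated to statsmodels)
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    params: "pd.Series"
    pvalues: "pd.Series"
    converged: bool
    model: str


def fit_correctness_glmm(
    classified: pd.DataFrame,
    subject_col: str = "subject_id",
    formula: str = "correct ~ coherence + C(session)",
) -> MixedModelFit:
    """Logistic mixed model for response correctness.

    Binomial GLMM with a random intercept per subject, fit by
    ``statsmodels``' variational Bayes routine.  Returns fixed-effect
    estimates and approximate two-sided p-values from the posterior
    mean/sd ratio.  Non-convergence raises; it is never silently dropped.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if classified[subject_col].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    df = classified.copy()
    if "correct" not in df:
        df["correct"] = (df["label"] == "correct").astype(float)
    model = BinomialBayesMixedGLM.from_formula(
        formula, {"subject": f"0 + C({subject_col})"}, df
    )
    fit = model.fit_vb()
    params = pd.Series(fit.fe_mean, index=model.exog_names)
    sds = np.asarray(fit.fe_sd)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(sds)):
        raise RuntimeError("correctness GLMM failed to converge")
    z = params.to_numpy() / sds
    pvals = pd.Series(2 * sps.norm.sf(np.abs(z)), index=model.exog_names)
    return MixedModelFit(params, pvals, True, "BinomialBayesMixedGLM(VB)")


def fit_anticipation_lmm(
    data: pd.DataFrame,
    response_col: str = "anticipation_angle",
    predictor_col: str = "prev_rdk_dir",
    subject_col: str = "subject_id",
) -> MixedModelFit:
    """Linear mixed model of anticipation angle on the previous direction.

    Random intercept per subject; returns the fixed slope and its p-value.
    """
    import statsmodels.formula.api as smf

    if data[subject_col].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    df = data[[response_col, predictor_col, subject_col]].dropna()
    model = smf.mixedlm(
        f"{response_col} ~ {predictor_col}", df, groups=df[subject_col]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    if not fit.converged:
        raise RuntimeError("anticipation LMM failed to converge")
    params = fit.params[fit.model.exog_names]
    pvals = fit.pvalues[fit.model.exog_names]
    return MixedModelFit(params, pvals, bool(fit.converged), "MixedLM(REML)")
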