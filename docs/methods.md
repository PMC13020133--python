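# Methods

This note documents the models, numerical choices and limitations behind
`rdkpursuit`, in the spirit of a methods appendix. Everything stated here
is either a definition or a property the test suite itself computes.

## Angle conventions

All angles are degrees on the half-open interval (−180°, 180°], with 0° =
rightward and positive = downward/clockwise (screen coordinates). The
wrap maps +180 and −180 both to +180, which makes the representative
unique; `circ_diff(a, b)` is the signed shortest arc and inherits the
boundary convention (`circ_diff(0, 180) = circ_diff(180, 0) = +180`).
Direction space is tiled by 16 half-open bins [c − 11.25°, c + 11.25°).
Half-open bins are deliberate: closed ±11.25° ranges would double-count
boundary angles and break the exactly-one-label property of response
classification (verified exhaustively on a 1° grid). The hemifield
categories contain the seven strictly negative (upper) and seven strictly
positive (lower) bin centers; the 0° and 180° bins belong to neither and
contribute 0 to the hemifield score, the only assignment consistent with
defining the hemifields by sign.

## Session designs and trial sampling

Unbiased sessions draw 16 directions equiprobably over 480 trials; biased
sessions give one frequent direction p = 0.6 and the other fifteen 0.4/15
each over 474 trials. Because 474 × 0.6 is not an integer, directions are
sampled i.i.d. by default (reproducible under the recorded seed and
unbiased in expectation); a balanced mode with largest-remainder rounding
is available. Coherence (5/15/40%) is drawn i.i.d. uniform per trial.
One global seed is split into per-(session, subject, trial) `numpy`
seed sequences so any single trial can be regenerated in isolation.

## Dot-field stimulus

~471 dots (1.5 dots/deg² × π × 10²) move at 10 °/s at 85 Hz inside a
10°-radius aperture. Signal/noise labels are reassigned every 4 frames
(≈47 ms); the signal count is round(coherence × n_dots) in every block;
noise dots receive a fresh uniform direction each block; a dot crossing
the aperture boundary is shifted one diameter inward along its radius,
re-entering from the opposite side. The analysis chain never consumes dot
fields (it consumes gaze and reports); the simulator exists so stimulus
statistics (mean displacement direction and magnitude vs coherence) can be
validated independently.

## The synthetic observer

### Perceptual reports

A report is, with probability `lapse_rate`, uniform; otherwise with
probability `w_sensory(coherence)` a von Mises draw centered on the true
direction with concentration `kappa(coherence)`; otherwise a guess from

    g(θ) ∝ [ Σ_c w_c · vM(θ; c, κ_card) ] · [ 1 − a · vM(θ; θ_freq, κ_avoid) / max vM ]

with cardinal components c ∈ {0°, ±90°, 180°}. The avoidance factor
multiplies the guess density by 1 − a at the frequent direction and ~1 far
from it; a = 0 recovers the pure cardinal-prior guesser, and an unbiased
session has no avoidance term. Guesses are drawn by inverse-CDF sampling
on a 0.1° grid with within-cell jitter; the gridded density integrates to
1 to < 1e−6 (tested).

Defaults — κ = {3, 20, 50} and w_sensory = {0.45, 0.75, 0.95} for
coherence {5, 15, 40}%, equal cardinal weights with κ_card = 3,
a = 0.8 with κ_avoid = 8, lapse 0.02 — were chosen once to produce
realistic psychophysics: accuracy rising from roughly 15% to 80% across
the three coherence levels, clearly above the 6.25% chance floor forced by
the bin geometry, with error choices enriched at cardinal axes and
depleted near the frequent direction. They are study conditions, not
fitting knobs.

### Eye traces

Velocity (deg/s) at 500 Hz is the sum of:

* **anticipation**: a C¹ smoothstep ramp from gap onset (−300 ms) to a
  plateau of `anticipation_gain` (default 1 °/s) at −50 ms, held through
  the pursuit latency, then cosine-tapered to zero over 150 ms. Its
  direction is von Mises around the expected direction (the session's
  frequent direction, or a per-subject idiosyncratic direction when
  unbiased) with a 25° circular-sd spread.
* **visual pursuit**: zero before `pursuit_latency_ms` (default 140 ms — at
  the long end of human pursuit latencies, appropriate for low-coherence
  large-field RDKs), then gain(coh) × 10 °/s × (1 − e^(−t/τ))², τ = 40 ms.
  The squared-exponential form makes the onset C¹.
* **white Gaussian velocity noise** (default sd 0.5 °/s per sample) and
  **saccades**: Poisson-timed (default 1/s) raised-cosine speed pulses
  (default peak 200 °/s, 30 ms; amplitude = peak × duration / 2) in
  uniform random directions. A fixed saccade count can override the
  Poisson draw for detector calibration.

Position is the cumulative trapezoid integral of velocity, so the
integral-vs-position identity holds to machine precision. All velocity
transitions are C¹ by construction: the zero-phase Butterworth filter in
the analysis chain smears slope discontinuities backward and forward in
time, and C⁰ kinks at window edges would bias window means by more than
the 1e−3 relative accuracy the recovery tests demand. With C¹ profiles
(and the onset kink 20 ms clear of the [100, 120) ms window edge), the
chain recovers the generator's window-mean ground truth to <1e−3 relative
without noise.

The generator's per-trial ground truth (anticipation vector, acceleration,
steady projected velocity) is evaluated by applying the analysis windows
to the *deterministic* velocity on the sample grid — an independent route
from the analysis chain, which sees only integrated, filtered,
re-differentiated position.

## Measurement chain choices

* **Zero-phase (forward–backward) filtering**: a causal filter would delay
  the signal and shift apparent pursuit latency; zero-phase preserves
  window timing at the cost of squaring the single-pass magnitude (the
  30-Hz cutoff therefore sits at gain 0.5, which the tests check against
  the transfer-function oracle).
* **Central differences** for velocity: exact for locally quadratic
  position, one-sided at the trace endpoints.
* **Saccade threshold 30 °/s, 10-ms padding**: conventional for 10 °/s
  pursuit; both are config parameters. Masked samples become NaN; unmasked
  samples pass through bit-identically.
* **Window means ignore NaN**; a window with <50% unmasked coverage yields
  a missing metric and the trial is flagged invalid. The acceleration
  windows only require ≥1 unmasked sample each (they are 10 samples wide).
* The anticipation amplitude exclusion (outside 0.25–2.5 °/s) is applied
  *before* histogram construction, i.e. excluded trials never enter the
  anticipation-direction histograms.
* Windows are half-open [a, b) on the 2-ms grid with t = 0 at stimulus
  motion onset.

## Permutation test

The statistic per bin is the mean over subjects of (biased − unbiased)
normalized frequency; the two histograms each sum to 1, so the observed
differences sum to 0 across bins by construction. The null relabels
trials between the two sessions within each subject, preserving the
original per-session counts. Since the statistic depends on a relabeling
only through per-bin counts, the relabeled counts of one session follow a
multivariate hypergeometric distribution over the subject's pooled counts;
the implementation samples that distribution directly, which is exactly
equivalent to explicit label shuffling and orders of magnitude faster.
p-values use (1 + #exceedances)/(n_perm + 1), one-sided in the direction
of the observed difference (a two-sided option exists); float ties count
as exceedances, which is conservative. Sign-selection makes the effective
two-tailed rate ≈ 2α; with the add-one estimator and tie handling the
measured per-bin rejection rate at α = 0.01 under an exchangeable null is
≈0.017 (within the calibrated acceptance band). No multiple-testing
correction is applied across the 16 bins by default, matching the per-bin
α display convention; callers can Bonferroni-correct externally. A
subject-level session-flip null is exposed as an option.

**Avoidance recovery protocol.** When the two compared sessions use
different stimulus designs, the error-trial choice histogram at the
frequent direction is depleted by a pure selection effect: guesses near
the frequent direction are far more often *correct* (and hence removed
from the error set) when 60% of stimuli move that way. The
parameter-recovery suite therefore holds the stimulus design fixed
(uniform) across both sessions and lets the avoidance term be the only
difference, so a null observer yields a calibrated false-positive rate.
Analyses of differently-designed sessions should keep this confound in
mind when interpreting a dip at the frequent direction.

## Watson–Williams test

Classical F approximation from per-group and pooled resultant lengths
with the 1 + 3/(8κ̂) correction, κ̂ from the standard three-branch
resultant-length inversion. A RuntimeWarning is raised when the
within-group mean resultant length falls below 0.45, where the
approximation degrades. Degenerate inputs (κ̂ → ∞ when all angles
coincide) fall back to correction 1. Null rejection at 0.05 is calibrated
to 0.05 ± 0.01 (tested over 5000 replicates), and F agrees with an
independent from-the-formula reference to 1e−6.

## Serial dependence

Within subject, trials in presentation order; the first trial of each
block has no predecessor and is dropped. The direction change
rdkDir(n) − rdkDir(n−1) is wrapped and binned at 22.5° (a +20° change
falls in the +22.5° bin under the half-open rule); delta is circularly
averaged per subject × bin; the group curve is the circular mean ± circular
SEM over subjects; a Watson–Williams ANOVA across bins on the per-subject
means tests for modulation. An attraction injected as a ∓10° delta shift
for |direction change| ≤ 45° is recovered as a negative-slope S-curve with
ww_p < 0.01 (tested).

## Angle–angle correlation

Pearson correlation between two angular variables is not well defined;
the package wraps both to (−180°, 180°] and re-centers both on the
circular mean of the *first* variable, placing the cut where the first
variable has least mass. This is a documented convention (adequate for
concentrated data, e.g. steady-state pursuit direction vs report at high
coherence), not a circular–circular correlation coefficient.

## Mixed models

Contract-level wrappers delegate to `statsmodels`: a variational-Bayes
binomial GLMM (random intercept per subject) for correctness, and REML
`MixedLM` for anticipation angle on the previous trial's direction.
Non-convergence raises; it is never silently dropped. Simulated-recovery
tests confirm an unbiased coherence effect and slope at the scales used.
The anticipation-angle LMM treats angle as linear, which is only sensible
when anticipation directions are concentrated; Bayes-factor analogues are
out of scope.

## Problem sizes

Test and demonstration runs use reduced problem sizes chosen for
statistical sufficiency: permutation calibration uses 200 replicate
datasets of 21 subjects × 200 trials at 2000 permutations; avoidance
recovery 2 × 50 replicates of 21 subjects × ~150 error trials; kinematic
recovery 200 noisy traces; Watson–Williams calibration 5000 replicates.
The pipeline itself defaults to the full design (21 subjects ×
480/474/474 trials) when invoked for production runs.

## Known limitations

* The observer has no trial-history mechanism: serial dependence in its
  reports is absent by construction (the serial-dependence machinery is
  validated by injecting effects post hoc), and anticipation depends on
  the session's expected direction, not on trial n−1.
* Anticipation amplitude is constant across trials (plus noise); real
  anticipatory pursuit waxes with expectation strength over a session.
* Saccades are kinematically schematic (no main-sequence scaling, no
  catch-up logic tied to position error); blink artifacts are not modeled.
* Passing recovery tests on this generator demonstrates correctness of the
  measurement chain, not realism of human data: the generator emulates the
  statistical structure the analyses assume (mixture reports, phase-
  structured pursuit, Poisson saccades, white noise), whereas real gaze
  data have colored noise, drift, tracker artifacts and nonstationarity.
* Binocular processing is out of scope; traces represent one eye.
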