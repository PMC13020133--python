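"""Inferential layer: permutation tests, circular ANOVA, serial dependence,
paired comparisons, correlations, mixed-model wrappers."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from rdkpursuit.angles import BIN_CENTERS, N_BINS, circ_wrap, resultant_length
from rdkpursuit.stats import (
    ZeroVarianceError,
    angle_report_correlation,
    counts_from_angles,
    histogram_permutation_test,
    paired_comparison,
    serial_dependence_curve,
    watson_williams,
)

# ---------------------------------------------------------------------------
# independent Watson-Williams oracle, written directly from the standard
# formula (per-group resultants, pooled resultant, 1 + 3/(8 kappa) factor)
# ---------------------------------------------------------------------------


def _ww_oracle_F(groups):
    rads = [np.deg2rad(np.asarray(g)) for g in groups]
    ns = np.array([g.size for g in rads])
    N, k = ns.sum(), len(rads)
    Ri = np.array([np.abs(np.exp(1j * g).sum()) for g in rads])
    R = np.abs(np.exp(1j * np.concatenate(rads)).sum())
    rw = Ri.sum() / N
    if rw < 0.53:
        kappa = 2 * rw + rw**3 + 5 * rw**5 / 6
    elif rw < 0.85:
        kappa = -0.4 + 1.39 * rw + 0.43 / (1 - rw)
    else:
        kappa = 1 / (rw**3 - 4 * rw**2 + 3 * rw)
    K = 1 + 3 / (8 * kappa)
    return K * ((Ri.sum() - R) * (N - k)) / ((N - Ri.sum()) * (k - 1))


class TestPermutationTest:
    def _null_counts(self, rng, n_subj=8, n_trials=100):
        p = np.ones(16) / 16
        return (rng.multinomial(n_trials, p, size=n_subj),
                rng.multinomial(n_trials, p, size=n_subj))

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        cb = np.zeros((4, 16), dtype=int)
        cu = np.zeros((4, 16), dtype=int)
        cb[:, 0] = 100
        cu[:, 8] = 100
        res = histogram_permutation_test(cb, cu, 1000, rng)
        assert res.p_per_bin.min() == pytest.approx(1 / 1001)
        assert (res.p_per_bin >= 1 / 1001).all()

    def test_observed_diff_sums_to_zero(self, rng):
        cb, cu = self._null_counts(rng)
        res = histogram_permutation_test(cb, cu, 200, rng)
        assert res.observed_diff.sum() == pytest.approx(0.0, abs=1e-10)

    def test_reproducible_and_subject_order_invariant(self):
        rng = np.random.default_rng(0)
        cb, cu = self._null_counts(rng)
        p1 = histogram_permutation_test(cb, cu, 500, np.random.default_rng(42)).p_per_bin
        p2 = histogram_permutation_test(cb, cu, 500, np.random.default_rng(42)).p_per_bin
        np.testing.assert_array_equal(p1, p2)
        # permuting subjects leaves the observed statistic unchanged
        perm = np.random.default_rng(1).permutation(cb.shape[0])
        r1 = histogram_permutation_test(cb, cu, 200, np.random.default_rng(0))
        r2 = histogram_permutation_test(cb[perm], cu[perm], 200, np.random.default_rng(0))
        np.testing.assert_allclose(r1.observed_diff, r2.observed_diff, atol=1e-12)

    def test_null_rejection_rate_is_controlled(self, rng):
        hits = total = 0
        for _ in range(30):
            cb, cu = self._null_counts(rng, n_subj=10, n_trials=150)
            res = histogram_permutation_test(cb, cu, 500, rng)
            hits += (res.p_per_bin < 0.01).sum()
            total += N_BINS
        assert hits / total < 0.06  # coarse check; full calibration elsewhere

    def test_subject_level_flip_option(self, rng):
        cb, cu = self._null_counts(rng)
        res = histogram_permutation_test(cb, cu, 500, rng, unit="subjects")
        assert res.p_per_bin.shape == (16,)
        assert (res.p_per_bin > 0).all()

    def test_two_sided_alternative(self, rng):
        cb, cu = self._null_counts(rng)
        res = histogram_permutation_test(cb, cu, 500, rng, alternative="two-sided")
        assert (res.p_per_bin <= 1.0).all()

    def test_input_validation(self, rng):
        cb, cu = self._null_counts(rng)
        with pytest.raises(ValueError):
            histogram_permutation_test(cb, cu, 50, rng)  # too few permutations
        with pytest.raises(ValueError):
            histogram_permutation_test(cb[:1], cu[:1], 500, rng)  # one subject
        cu2 = cu.copy()
        cu2[0] = 0
        with pytest.raises(ValueError):
            histogram_permutation_test(cb, cu2, 500, rng)  # missing session

    def test_counts_from_angles_roundtrip(self, rng):
        df = pd.DataFrame(
            {"subject_id": np.repeat([0, 1], 50),
             "a": rng.choice(BIN_CENTERS, 100)}
        )
        counts, subjects = counts_from_angles(df, "a")
        assert counts.shape == (2, 16)
        assert counts.sum() == 100
        np.testing.assert_array_equal(subjects, [0, 1])


class TestWatsonWilliams:
    def test_identical_groups_give_zero_F(self):
        g = np.array([-10.0, 0.0, 10.0])
        res = watson_williams([g, g])
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)
        assert res.df1 == 1 and res.df2 == 4

    def test_separated_groups_highly_significant(self, rng):
        g1 = np.rad2deg(sps.vonmises.rvs(5, size=50, random_state=rng))
        g2 = circ_wrap(90 + np.rad2deg(sps.vonmises.rvs(5, size=50, random_state=rng)))
        assert watson_williams([g1, g2]).p < 1e-6

    def test_matches_independent_oracle(self, rng):
        for _ in range(30):
            k = rng.integers(2, 5)
            groups = [
                np.rad2deg(
                    sps.vonmises.rvs(
                        rng.uniform(2, 8),
                        loc=rng.uniform(-np.pi, np.pi),
                        size=rng.integers(8, 30),
                        random_state=rng,
                    )
                )
                for _ in range(k)
            ]
            res = watson_williams(groups)
            assert abs(res.F - _ww_oracle_F(groups)) < 1e-6

    def test_low_concentration_warns(self, rng):
        g1 = rng.uniform(-180, 180, 40)
        g2 = rng.uniform(-180, 180, 40)
        if resultant_length(np.concatenate([g1, g2])) < 0.45:
            with pytest.warns(RuntimeWarning):
                watson_williams([g1, g2])

    def test_validation(self):
        with pytest.raises(ValueError):
            watson_williams([np.array([0.0, 1.0])])
        with pytest.raises(ValueError):
            watson_williams([np.array([0.0]), np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            watson_williams([np.array([0.0, 180.0]), np.array([1.0, 2.0])])


class TestSerialDependence:
    def _simulate(self, rng, n_subj=12, n_trials=300, attract=0.0):
        rows = []
        for s in range(n_subj):
            dirs = rng.choice(BIN_CENTERS, n_trials)
            delta = np.rad2deg(sps.vonmises.rvs(8, size=n_trials, random_state=rng))
            if attract:
                dd = circ_wrap(np.diff(dirs, prepend=dirs[0]))
                shift = np.where(np.abs(dd) <= 45, -attract * np.sign(dd), 0.0)
                shift[0] = 0.0
                delta = circ_wrap(delta + shift)
            rows.append(
                pd.DataFrame(
                    {"subject_id": s, "trial": np.arange(n_trials),
                     "rdk_dir_deg": dirs, "delta": delta}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_boundary_binning(self):
        """rdkDir 350 -> 10 gives a +20 difference, assigned to the 22.5 bin."""
        df = pd.DataFrame(
            {"subject_id": 0, "trial": [0, 1, 2],
             "rdk_dir_deg": [circ_wrap(350.0), 10.0, 10.0],
             "delta": [0.0, 5.0, 5.0]}
        )
        df = pd.concat([df.assign(subject_id=i) for i in range(3)])
        curve = serial_dependence_curve(df)
        i = int(np.where(curve.bin_centers == 22.5)[0][0])
        assert curve.subject_means[0, i] == pytest.approx(5.0)

    def test_null_curve_is_flat(self, rng):
        curve = self._simulate(rng, n_subj=15, n_trials=400)
        res = serial_dependence_curve(curve)
        finite = np.isfinite(res.group_mean)
        assert np.max(np.abs(res.group_mean[finite])) < 5.0
        assert res.ww_p > 0.001  # no spurious strong effect

    def test_injected_attraction_recovered(self, rng):
        df = self._simulate(rng, n_subj=15, n_trials=400, attract=10.0)
        res = serial_dependence_curve(df)
        i_pos = int(np.where(res.bin_centers == 22.5)[0][0])
        i_neg = int(np.where(res.bin_centers == -22.5)[0][0])
        assert res.group_mean[i_pos] < 0 < res.group_mean[i_neg]
        assert res.ww_p < 0.01

    def test_too_few_trials_raises(self):
        df = pd.DataFrame(
            {"subject_id": [0], "trial": [0], "rdk_dir_deg": [0.0], "delta": [0.0]}
        )
        with pytest.raises(ValueError):
            serial_dependence_curve(df)


class TestPairedComparison:
    def test_identical_vectors_degenerate_zero(self):
        a = np.arange(10.0)
        res = paired_comparison(a, a)
        assert res.t == 0.0 and res.p == 1.0 and res.cohens_d == 0.0
        assert res.degenerate

    def test_constant_shift_raises(self):
        a = np.arange(10.0)
        with pytest.raises(ZeroVarianceError):
            paired_comparison(a, a + 1.0)

    def test_effect_size_recovery(self, rng):
        """Paired shift delta=0.5, sd=1: mean Cohen's d over replicates ~0.5."""
        ds = []
        for _ in range(300):
            b = rng.normal(0, 1, 21)
            a = b + 0.5 + rng.normal(0, 1, 21)
            ds.append(paired_comparison(a, b).cohens_d)
        # diff = 0.5 + N(0,1) noise -> population d = 0.5
        assert np.mean(ds) == pytest.approx(0.5, abs=0.08)

    def test_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        res = paired_comparison(a, b)
        t, p = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)


class TestAngleCorrelation:
    def test_perfect_agreement(self, rng):
        a = rng.uniform(-170, 170, 100)
        r, _ = angle_report_correlation(a, a)
        assert r == pytest.approx(1.0)

    def test_independent_angles_near_zero(self, rng):
        a = rng.uniform(-180, 180, 10_000)
        b = rng.uniform(-180, 180, 10_000)
        r, _ = angle_report_correlation(a, b)
        assert abs(r) < 0.03

    def test_noisy_agreement(self, rng):
        a = circ_wrap(rng.uniform(-180, 180, 1000))
        b = circ_wrap(a + np.rad2deg(sps.vonmises.rvs(4, size=1000, random_state=rng)))
        r, p = angle_report_correlation(a, b)
        assert r > 0.5 and p < 1e-6

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            angle_report_correlation(np.zeros(20), np.arange(20.0))


class TestMixedModels:
    def test_correctness_glmm_recovers_coherence_effect(self, rng):
        from rdkpursuit.stats import fit_correctness_glmm

        rows = []
        for s in range(10):
            b0 = -1 + rng.normal(0, 0.5)
            coh = rng.choice([0.05, 0.15, 0.40], size=400)
            p = 1 / (1 + np.exp(-(b0 + 3 * coh)))
            rows.append(
                pd.DataFrame(
                    {"subject_id": s, "coherence": coh, "session": "unbiased",
                     "label": np.where(rng.uniform(size=400) < p, "correct", "general")}
                )
            )
        df = pd.concat(rows, ignore_index=True)
        fit = fit_correctness_glmm(df, formula="correct ~ coherence")
        assert fit.converged
        assert 1.8 < fit.params["coherence"] < 4.2
        # logistic monotonicity: fitted accuracy increases with coherence
        assert fit.params["coherence"] > 0

    def test_glmm_needs_five_subjects(self):
        from rdkpursuit.stats import fit_correctness_glmm

        df = pd.DataFrame(
            {"subject_id": [0, 1], "coherence": [0.05, 0.4],
             "session": "unbiased", "label": ["correct", "general"]}
        )
        with pytest.raises(ValueError):
            fit_correctness_glmm(df)

    def test_anticipation_lmm_slope_recovery(self, rng):
        from rdkpursuit.stats import fit_anticipation_lmm

        rows = []
        for s in range(8):
            prev = rng.uniform(-180, 180, 250)
            ang = rng.normal(0, 1) + 0.05 * prev + rng.normal(0, 15, 250)
            rows.append(
                pd.DataFrame(
                    {"subject_id": s, "prev_rdk_dir": prev, "anticipation_angle": ang}
                )
            )
        fit = fit_anticipation_lmm(pd.concat(rows, ignore_index=True))
        assert fit.params["prev_rdk_dir"] == pytest.approx(0.05, abs=0.02)
        assert fit.pvalues["prev_rdk_dir"] < 0.01

    def test_anticipation_lmm_null_slope_not_significant(self, rng):
        from rdkpursuit.stats import fit_anticipation_lmm

        pvals = []
        for _ in range(10):
            rows = []
            for s in range(6):
                prev = rng.uniform(-180, 180, 150)
                ang = rng.normal(0, 1) + rng.normal(0, 15, 150)
                rows.append(
                    pd.DataFrame(
                        {"subject_id": s, "prev_rdk_dir": prev,
                         "anticipation_angle": ang}
                    )
                )
            try:
                pvals.append(
                    fit_anticipation_lmm(pd.concat(rows, ignore_index=True)).pvalues[
                        "prev_rdk_dir"
                    ]
                )
            except RuntimeError:
                # boundary (zero) random-intercept variance can stall REML;
                # the wrapper surfaces it instead of silently dropping it
                continue
        assert len(pvals) >= 5
        assert min(pvals) > 1e-4  # no systematic spurious effect
        assert np.mean(np.array(pvals) < 0.5) < 0.95
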