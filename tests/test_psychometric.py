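"""Staircases, psychometric fitting, sinusoid model, PSEs, rm-correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs
from scipy.stats import norm

from chromasim import psychometric as ps
from chromasim.staircase import StaircaseConfig, run_staircase, two_down_one_up_target


def simulated_2afc(mu, sigma, seed, lapse=0.0):
    rng = np.random.default_rng(seed)

    def responder(level):
        p = 0.5 + (0.5 - lapse) * norm.cdf((level - mu) / sigma)
        return rng.random() < p

    return responder


class TestStaircase:
    def test_always_correct_never_rises(self):
        cfg = StaircaseConfig(start_level=1.0, step=0.1, step_mode="additive",
                              n_trials=20, min_level=0.0)
        recs = run_staircase(cfg, lambda lv: True, rng_seed=0)
        levels = [r.level for r in recs]
        assert all(b <= a for a, b in zip(levels, levels[1:]))
        # level drops exactly every second trial
        assert levels[0] == levels[1] and levels[2] == levels[0] - 0.1

    def test_always_wrong_monotonically_rises(self):
        cfg = StaircaseConfig(start_level=0.1, step=1.3, n_trials=15, max_level=100.0)
        recs = run_staircase(cfg, lambda lv: False, rng_seed=0)
        levels = [r.level for r in recs]
        assert all(b > a for a, b in zip(levels, levels[1:]))

    def test_reproducible_given_seed_and_responder(self):
        cfg = StaircaseConfig(start_level=0.8, step=0.05, step_mode="additive",
                              n_trials=60)
        a = run_staircase(cfg, simulated_2afc(0.5, 0.1, 42), rng_seed=7)
        b = run_staircase(cfg, simulated_2afc(0.5, 0.1, 42), rng_seed=7)
        assert a == b

    def test_converges_to_analytic_70_7_percent_level(self):
        # 2-down/1-up tracks p^2 = 0.5; for this observer that level is
        # mu + sigma Phi^-1((sqrt(0.5) - 0.5) / 0.5).  A single staircase
        # tail wanders by about a step, so (as in the protocol) several runs
        # are averaged: mean of the final-10 levels across runs.
        mu, sigma, step = 0.5, 0.1, 0.05
        target = mu + sigma * norm.ppf((two_down_one_up_target() - 0.5) / 0.5)
        cfg = StaircaseConfig(start_level=0.9, step=step, step_mode="additive",
                              n_trials=120, min_level=0.0, max_level=1.5)
        tails = []
        for run in range(10):
            recs = run_staircase(cfg, simulated_2afc(mu, sigma, run), rng_seed=run,
                                 n_alternatives=2)
            tails.append(np.mean([r.level for r in recs[-10:]]))
        assert abs(np.mean(tails) - target) <= 0.5 * step

    def test_exact_trial_count_and_indices(self):
        cfg = StaircaseConfig(start_level=0.5, step=1.3, n_trials=17)
        recs = run_staircase(cfg, simulated_2afc(0.2, 0.1, 0), rng_seed=0)
        assert len(recs) == 17
        assert [r.index for r in recs] == list(range(17))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            StaircaseConfig(start_level=1.0, step=0.9)  # multiplicative < 1
        with pytest.raises(ValueError):
            StaircaseConfig(start_level=1.0, step=-0.1, step_mode="additive")


class TestPsychometricFit:
    @staticmethod
    def _dataset(mu=0.5, sigma=0.1, gamma=0.25, lapse=0.02, n=40, seed=0):
        levels = np.linspace(0.1, 1.0, 9)
        p = gamma + (1 - gamma - lapse) * norm.cdf((levels - mu) / sigma)
        k = np.random.default_rng(seed).binomial(n, p)
        return levels, np.full(9, n), k

    def test_parameter_recovery(self):
        levels, n, k = self._dataset(seed=3)
        res = ps.fit_psychometric(levels, n, k)
        assert res.mu == pytest.approx(0.5, abs=0.05)
        assert res.sigma == pytest.approx(0.1, abs=0.05)

    def test_optimum_beats_generating_parameters(self):
        # optimizer sanity: the fitted likelihood should not fall below the
        # likelihood of the true generating parameters
        wins = 0
        for seed in range(20):
            levels, n, k = self._dataset(seed=seed)
            model = ps.PsychometricModel(tuple(levels), tuple(n), tuple(k))
            res = model.fit()
            wins += res.loglike >= model.loglike(0.5, 0.1, 0.02) - 1e-9
        assert wins >= 19

    def test_symmetric_step_data_centers_mu(self):
        levels = np.array([0.2, 0.4, 0.6, 0.8])
        n = np.full(4, 50)
        k = np.array([13, 18, 45, 50])  # symmetric about 0.5 on the 0.25-1 scale
        res = ps.fit_psychometric(levels, n, k)
        assert res.mu == pytest.approx(0.5, abs=0.05)

    def test_sigma_shrinks_with_steeper_slope(self):
        _, n, k1 = self._dataset(sigma=0.2, seed=5)
        levels, _, k2 = self._dataset(sigma=0.05, seed=5)
        shallow = ps.fit_psychometric(levels, n, k1)
        steep = ps.fit_psychometric(levels, n, k2)
        assert steep.sigma < shallow.sigma

    def test_degenerate_data_rejected_with_guidance(self):
        with pytest.raises(ps.DegenerateFitError, match="threshold"):
            ps.fit_psychometric([0.1, 0.2, 0.3], [10, 10, 10], [10, 10, 10])

    def test_free_lapse_stays_bounded(self):
        levels, n, k = self._dataset(lapse=0.05, seed=2)
        res = ps.fit_psychometric(levels, n, k, lapse="free")
        assert 0.0 <= res.lapse_rate <= 0.06

    def test_summary_mentions_parameters(self):
        levels, n, k = self._dataset()
        s = ps.fit_psychometric(levels, n, k).summary()
        assert "mu" in s and "sigma" in s and "lapse" in s


class TestThresholdAt:
    def test_acuity_criterion_closed_form(self):
        # 78.1% correct on a 4AFC with no lapses sits 0.547 sigma above mu
        t = ps.threshold_at(mu=0.0, sigma=1.0, chance=0.25, lapse=0.0, criterion=0.781)
        assert t == pytest.approx(0.5476, abs=1e-3)

    def test_midpoint_criterion_returns_mu(self):
        mid = 0.25 + (1 - 0.25 - 0.02) / 2
        t = ps.threshold_at(mu=0.37, sigma=0.2, chance=0.25, lapse=0.02, criterion=mid)
        assert t == pytest.approx(0.37)

    def test_pse_criterion_with_zero_chance(self):
        assert ps.threshold_at(1.3, 0.5, 0.0, 0.0, 0.5) == pytest.approx(1.3)

    def test_strictly_increasing_in_criterion(self):
        ts = [ps.threshold_at(0.0, 1.0, 0.25, 0.02, c) for c in (0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(ts) > 0)

    def test_unachievable_criterion_rejected(self):
        with pytest.raises(ValueError):
            ps.threshold_at(0.0, 1.0, 0.25, 0.02, 0.99)
        with pytest.raises(ValueError):
            ps.threshold_at(0.0, 1.0, 0.25, 0.02, 0.25)


class TestBootstrapCI:
    def test_deterministic_responder_gives_zero_width(self):
        # step data: every resample reproduces the same counts exactly
        res = ps.fit_psychometric([0.2, 0.4, 0.6, 0.8], [30] * 4, [0, 0, 30, 30],
                                  chance=0.0, lapse=0.0)
        lo, hi = res.bootstrap_ci(0.5, n_boot=200, rng_seed=0)
        assert hi - lo < 1e-9

    def test_ci_brackets_point_estimate(self):
        levels = np.linspace(0.1, 1.0, 9)
        p = 0.25 + 0.73 * norm.cdf((levels - 0.5) / 0.1)
        k = np.random.default_rng(1).binomial(40, p)
        res = ps.fit_psychometric(levels, [40] * 9, k)
        lo, hi = res.bootstrap_ci(0.781, n_boot=200, rng_seed=2)
        assert lo < res.threshold_at(0.781) < hi

    def test_seed_reproducibility(self):
        levels = np.linspace(0.1, 1.0, 9)
        p = 0.25 + 0.73 * norm.cdf((levels - 0.5) / 0.1)
        k = np.random.default_rng(4).binomial(40, p)
        res = ps.fit_psychometric(levels, [40] * 9, k)
        assert res.bootstrap_ci(0.781, 200, rng_seed=9) == res.bootstrap_ci(0.781, 200, rng_seed=9)

    def test_small_n_boot_rejected(self):
        levels, n, k = TestPsychometricFit._dataset()
        res = ps.fit_psychometric(levels, n, k)
        with pytest.raises(ValueError):
            res.bootstrap_ci(0.781, n_boot=50)


class TestSinusoid:
    def test_exact_recovery_noise_free(self):
        x = np.array([-3.0, -2, -1, 0, 1, 2, 3])
        y = 2.0 * np.sin(2 * np.pi * (x - 1.0) / 6.0) + 5.0
        fit = ps.fit_threshold_sinusoid(x, y)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.offset == pytest.approx(5.0, abs=1e-6)
        assert fit.phase == pytest.approx(1.0, abs=1e-6)

    def test_constant_data(self):
        fit = ps.fit_threshold_sinusoid([-3, 0, 3, 1], [4.0, 4.0, 4.0, 4.0])
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.offset == pytest.approx(4.0)
        assert fit.phase == 0.0

    @settings(max_examples=25, derandomize=True)
    @given(hs.floats(-20, 20), hs.floats(0.1, 5), hs.floats(0.1, 10))
    def test_phase_canonicalized_into_half_open_period(self, p, a, b):
        x = np.linspace(-3, 3, 13)
        y = a * np.sin(2 * np.pi * (x - p) / 6.0) + b
        fit = ps.fit_threshold_sinusoid(x, y)
        assert -3.0 < fit.phase <= 3.0
        assert fit.amplitude >= 0.0
        assert np.allclose(fit.predict(x), y, atol=1e-6)

    def test_extrema_half_period_apart(self):
        fit = ps.fit_threshold_sinusoid([-3, -1.5, 0, 1.5, 3], [1, 2, 3, 2.2, 1.1])
        sep = abs(fit.argmax - fit.argmin)
        assert min(sep, 6 - sep) == pytest.approx(3.0)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            ps.fit_threshold_sinusoid([0.0, 1.0], [1.0, 2.0])


class TestPSE:
    @staticmethod
    def _constant_stimuli(pse, sigma=0.5, seed=0, flip=False, n=20):
        x = np.arange(-2.0, 2.5, 0.5)
        p = norm.cdf((x - pse) / sigma)
        if flip:
            p = 1 - p
        k = np.random.default_rng(seed).binomial(n, p)
        return x, np.full(x.size, n), k

    def test_symmetric_data_recovers_center(self):
        x, n, k = self._constant_stimuli(0.5, seed=1)
        res = ps.pse_from_constant_stimuli(x, n, k)
        assert res.pse == pytest.approx(0.5, abs=0.15)
        assert not res.extrapolated

    def test_label_swap_flips_slope_not_pse(self):
        x, n, k = self._constant_stimuli(0.3, seed=2)
        a = ps.pse_from_constant_stimuli(x, n, k)
        b = ps.pse_from_constant_stimuli(x, n, n - k)
        assert b.pse == pytest.approx(a.pse, abs=1e-3)
        assert a.slope * b.slope < 0

    def test_no_crossing_flagged_as_extrapolated(self):
        x = np.arange(-2.0, 2.5, 0.5)
        res = ps.pse_from_constant_stimuli(x, [10] * 9, [6, 7, 7, 8, 9, 9, 10, 10, 10])
        assert res.extrapolated

    def test_bootstrap_ci_contains_pse(self):
        x, n, k = self._constant_stimuli(0.0, seed=3)
        res = ps.pse_from_constant_stimuli(x, n, k, n_boot=200, rng_seed=0)
        assert res.ci90[0] <= res.pse <= res.ci90[1]


def brute_force_rm_corr(subjects, x, y):
    """Independent oracle: explicit centered sums of squares."""
    import pandas as pd

    df = pd.DataFrame({"s": subjects, "x": x, "y": y})
    xc = df.x - df.groupby("s").x.transform("mean")
    yc = df.y - df.groupby("s").y.transform("mean")
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestRmCorr:
    def test_parallel_lines_give_unit_correlation(self):
        subjects = list("aaabbbccc")
        x = [1, 2, 3] * 3
        y = [10 + 2 * v for v in (1, 2, 3)] + [0 + 2 * v for v in (1, 2, 3)] + [
            -5 + 2 * v for v in (1, 2, 3)
        ]
        res = ps.rm_corr(subjects, x, y)
        assert res.r == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        subjects = np.repeat(list("abc"), 2)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = ps.rm_corr(subjects, x, y)
        assert res.r == pytest.approx(brute_force_rm_corr(subjects, x, y), abs=1e-10)

    def test_matches_pingouin_and_ancova_regression(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"s": np.repeat(list("abcde"), 4),
             "x": rng.normal(size=20),
             "y": rng.normal(size=20)}
        )
        df["y"] += 0.5 * df.x
        mine = ps.rm_corr(df.s, df.x, df.y)
        pg = pingouin.rm_corr(data=df, x="x", y="y", subject="s")
        assert mine.r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-10)
        assert mine.dof == int(pg["dof"].iloc[0])
        assert mine.p == pytest.approx(float(pg["pval"].iloc[0]), rel=1e-8)
        # ANCOVA route: common slope with subject intercepts; r_rm shares the
        # slope's sign and its t statistic reproduces the same p value
        ols = smf.ols("y ~ x + C(s)", data=df).fit()
        assert np.sign(mine.r) == np.sign(ols.params["x"])
        assert mine.p == pytest.approx(float(ols.pvalues["x"]), rel=1e-8)

    def test_invariant_to_per_subject_offsets(self):
        rng = np.random.default_rng(7)
        subjects = np.repeat(list("abcd"), 3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = ps.rm_corr(subjects, x, y)
        offs = {"a": 5.0, "b": -3.0, "c": 100.0, "d": 0.5}
        x2 = x + np.array([offs[s] for s in subjects])
        y2 = y + np.array([2 * offs[s] for s in subjects])
        shifted = ps.rm_corr(subjects, x2, y2)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)

    def test_permuted_y_gives_uniformish_p(self):
        rng = np.random.default_rng(11)
        subjects = np.repeat([f"s{i}" for i in range(6)], 4)
        x = rng.normal(size=24)
        y = rng.normal(size=24)
        sig = 0
        for _ in range(200):
            yp = y.copy()
            for s in np.unique(subjects):
                idx = np.nonzero(subjects == s)[0]
                yp[idx] = yp[rng.permutation(idx)]
            if ps.rm_corr(subjects, x, yp).p <= 0.05:
                sig += 1
        assert sig <= 24  # ~5% expected; generous binomial bound

    def test_single_pair_per_subject_is_error_not_nan(self):
        with pytest.raises(ValueError):
            ps.rm_corr(["a", "b", "c"], [1, 2, 3], [1, 2, 3])

    def test_constant_x_within_subjects_rejected(self):
        with pytest.raises(ValueError):
            ps.rm_corr(list("aabb"), [1, 1, 2, 2], [0.1, 0.4, 0.2, 0.9])


class TestPairedT:
    def test_identical_samples(self):
        t, p = ps.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_three_pair_closed_form(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 2 sqrt(3);
        # for df = 2 the two-tailed p is 1 - t / sqrt(t^2 + 2)
        x, y = [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        t, p = ps.paired_t_test(x, y)
        t_expect = 2 * np.sqrt(3)
        assert t == pytest.approx(t_expect, abs=1e-10)
        assert p == pytest.approx(1 - t_expect / np.sqrt(t_expect**2 + 2), abs=1e-10)

    def test_sign_flip_antisymmetry(self):
        x = [1.0, 2.0, 4.0, 3.0]
        y = [0.5, 2.5, 3.0, 2.0]
        t1, p1 = ps.paired_t_test(x, y)
        t2, p2 = ps.paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_constant_nonzero_difference(self):
        with pytest.raises(ValueError):
            ps.paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
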