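"""Cosinor, IV/IS, L5/M10 window statistics and diurnal fPCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actijive.circadian import (OMEGA, cosinor_fit, diurnal_fpca, iv_is,
                                l5_m10)


class TestCosinor:
    def test_noise_free_cosine_recovered_exactly(self):
        t = np.arange(2 * 1440) / 60.0
        x = 30.0 + 20.0 * np.cos(OMEGA * (t - 14.0))
        mesor, amp, acro = cosinor_fit(t, x)
        assert mesor == pytest.approx(30.0, abs=1e-10)
        assert amp == pytest.approx(20.0, abs=1e-10)
        assert acro == pytest.approx(-2 * np.pi * 14.0 / 24.0, abs=1e-10)

    def test_two_pm_peak_matches_reference_convention(self):
        # a ~2 PM peak corresponds to an acrophase near -3.67 rad
        t = np.arange(1440) / 60.0
        _, _, acro = cosinor_fit(t, 10 + 5 * np.cos(OMEGA * (t - 14.0)))
        assert acro == pytest.approx(-3.665, abs=1e-3)
        assert -2 * np.pi < acro <= 0

    def test_constant_input_flagged(self):
        mesor, amp, acro = cosinor_fit(np.arange(1500) / 60.0, np.full(1500, 7.0))
        assert amp == 0.0 and np.isnan(acro)

    def test_noisy_recovery_within_linear_model_se(self):
        """Parameter recovery checked against the OLS standard errors of an
        independent statsmodels fit of the same harmonic design."""
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        t = np.arange(14 * 1440) / 60.0
        truth = (30.0, 20.0, 14.0)
        x = truth[0] + truth[1] * np.cos(OMEGA * (t - truth[2])) \
            + rng.normal(0, 25.0, t.size)
        mesor, amp, acro = cosinor_fit(t, x)
        X = sm.add_constant(np.column_stack([np.cos(OMEGA * t), np.sin(OMEGA * t)]))
        ols = sm.OLS(x, X).fit()
        bc, bs = truth[1] * np.cos(OMEGA * truth[2]), truth[1] * np.sin(OMEGA * truth[2])
        assert abs(mesor - truth[0]) < 3 * ols.bse[0]
        assert abs(ols.params[1] - bc) < 3 * ols.bse[1]
        assert abs(ols.params[2] - bs) < 3 * ols.bse[2]
        # and the nonlinear transforms agree with the oracle's coefficients
        assert amp == pytest.approx(np.hypot(ols.params[1], ols.params[2]), rel=1e-12)


class TestIvIs:
    def test_pure_sinusoid_iv_closed_form(self):
        t = np.arange(10_000)
        x = 50 + 20 * np.cos(2 * np.pi * t / 24.0)
        iv, _ = iv_is(x, t % 24)
        assert iv == pytest.approx(2 * (1 - np.cos(2 * np.pi / 24)), abs=1e-3)

    def test_exactly_repeated_pattern_has_is_one(self):
        day = np.array([1, 5, 9, 3, 2, 8, 7, 4] * 3, float)  # 24 h
        x = np.tile(day, 14)
        _, is_ = iv_is(x, np.tile(np.arange(24), 14))
        assert is_ == pytest.approx(1.0)

    def test_iid_noise_limits(self):
        rng = np.random.default_rng(0)
        days = 420
        x = rng.normal(0, 1, 24 * days)
        iv, is_ = iv_is(x, np.tile(np.arange(24), days))
        assert iv == pytest.approx(2.0, abs=0.1)
        assert is_ == pytest.approx(1.0 / days, rel=0.5)

    def test_constant_series_undefined(self):
        iv, is_ = iv_is(np.full(48, 3.0), np.tile(np.arange(24), 2))
        assert np.isnan(iv) and np.isnan(is_)


def brute_force_l5_m10(profile):
    """Exhaustive wrap-around window scan (the independent oracle)."""
    p = np.asarray(profile, float)
    best = {}
    for width, mode in ((600, "M10"), (300, "L5")):
        means = np.array([np.take(p, np.arange(s, s + width), mode="wrap").mean()
                          for s in range(1440)])
        idx = int(np.argmax(means) if mode == "M10" else np.argmin(means))
        best[mode] = (means[idx], ((idx + width / 2) / 60.0) % 24.0)
    return best


class TestL5M10:
    def test_rectangular_profile_geometry(self):
        p = np.zeros(1440)
        p[8 * 60:18 * 60] = 100.0
        out = l5_m10(p)
        assert out["M10"] == pytest.approx(100.0)
        assert out["M10Time"] == pytest.approx(13.0)
        assert out["L5"] == pytest.approx(0.0)
        assert out["RA"] == pytest.approx(1.0)

    def test_zero_l5_with_positive_m10_gives_ra_one(self):
        p = np.zeros(1440)
        p[:700] = 50.0
        assert l5_m10(p)["RA"] == pytest.approx(1.0)

    def test_all_zero_profile_ra_undefined(self):
        assert np.isnan(l5_m10(np.zeros(1440))["RA"])

    def test_ties_resolve_to_earliest_window(self):
        out = l5_m10(np.full(1440, 5.0))  # every window ties
        assert out["M10Time"] == pytest.approx((0 + 300) / 60.0)
        assert out["L5Time"] == pytest.approx((0 + 150) / 60.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.gamma(1.0, 30.0, 1440)
        out = l5_m10(p)
        oracle = brute_force_l5_m10(p)
        assert out["M10"] == pytest.approx(oracle["M10"][0], rel=1e-12)
        assert out["M10Time"] == pytest.approx(oracle["M10"][1])
        assert out["L5"] == pytest.approx(oracle["L5"][0], rel=1e-12)
        assert out["L5Time"] == pytest.approx(oracle["L5"][1])


class TestFpca:
    def _profiles(self, n, rng, height=None, shift=None):
        t = np.arange(1440) / 60.0
        P = np.empty((n, 1440))
        for i in range(n):
            if height is not None:
                P[i] = (3.0 + 1.5 * np.cos(OMEGA * (t - 14.0))) * (1 + 0.2 * height[i])
            else:
                P[i] = 3.0 + 1.5 * np.cos(OMEGA * (t - 14.0 - shift[i]))
            P[i] += rng.normal(0, 0.01, 1440)
        return P

    def test_identical_profiles_have_zero_scores(self):
        P = np.tile(np.linspace(0, 5, 1440), (8, 1))
        scores, comps, shares = diurnal_fpca(P, k=2)
        assert np.allclose(scores, 0.0, atol=1e-9)

    def test_height_factor_separates_groups_with_sign_rule(self):
        rng = np.random.default_rng(2)
        height = np.array([1.0] * 20 + [-1.0] * 20)
        P = self._profiles(40, rng, height=height)
        scores, comps, shares = diurnal_fpca(P, k=4)
        # fPC1 carries the planted height contrast, higher profiles positive
        assert np.corrcoef(scores[:, 0], height)[0, 1] > 0.99
        assert comps[600:840, 0].sum() > 0  # midday loading positive

    def test_timing_shift_loads_on_leading_components(self):
        rng = np.random.default_rng(3)
        shift = rng.normal(0, 1.0, 40)
        P = self._profiles(40, rng, shift=shift)
        scores, _, _ = diurnal_fpca(P, k=4)
        r = max(abs(np.corrcoef(scores[:, j], shift)[0, 1]) for j in (0, 1))
        assert r > 0.8

    def test_scores_centered_and_orthogonal(self):
        rng = np.random.default_rng(5)
        P = rng.normal(0, 1, (12, 1440))
        scores, comps, shares = diurnal_fpca(P, k=4, smooth_width=1)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        gram = scores.T @ scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        assert np.allclose(np.linalg.norm(comps, axis=0), 1.0)

    def test_rank_deficient_input_rejected(self):
        P = np.tile(np.linspace(0, 5, 1440), (6, 1))
        P[0] += 1.0  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            diurnal_fpca(P, k=4)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="k\\+1"):
            diurnal_fpca(np.random.default_rng(0).normal(size=(4, 1440)), k=4)
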