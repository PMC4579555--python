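"""FSC computation and fitting, shell averaging, SAXS profile operations."""

import numpy as np
import pytest

import pentastate as ps
from pentastate.crystsym import ReflectionSet
from pentastate.synthdata import (analytic_fsc_half_crossing, make_falloff_half_maps,
                                  make_fsc_pair)


def _noise_map(seed, n=64, voxel=3.5):
    rng = np.random.default_rng(seed)
    return ps.DensityMap(rng.normal(size=(n, n, n)), voxel)


class TestComputeFsc:
    def test_self_fsc_is_one(self):
        m = _noise_map(0, n=32)
        fsc = ps.compute_fsc(m, m, n_shells=12)
        assert np.abs(fsc.values - 1.0).max() < 1e-9

    def test_symmetry(self):
        a, b = _noise_map(1, 32), _noise_map(2, 32)
        f1 = ps.compute_fsc(a, b, n_shells=12)
        f2 = ps.compute_fsc(b, a, n_shells=12)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_independent_noise_decorrelated(self):
        a, b = _noise_map(3), _noise_map(4)
        fsc = ps.compute_fsc(a, b, n_shells=20)
        smag_counts = np.histogram(
            np.sqrt(sum(g ** 2 for g in np.meshgrid(
                *[np.fft.fftfreq(64, d=3.5)] * 3, indexing="ij"))).ravel(),
            bins=np.linspace(0, 1 / 7.0, 21))[0]
        big = smag_counts[np.searchsorted(np.linspace(0, 1 / 7.0, 21), fsc.s) - 1] >= 500
        assert np.abs(fsc.values[big]).max() < 0.1

    def test_grid_mismatch_error(self):
        with pytest.raises(ValueError):
            ps.compute_fsc(_noise_map(0, 32), _noise_map(0, 16), n_shells=8)


class TestLogisticFit:
    def test_recovers_generator_parameters(self):
        a_true, b_true = 200.0, 8.0
        s = np.linspace(0.005, 0.075, 30)
        vals = 1.0 / (1.0 + np.exp(a_true * s - b_true))
        fit = ps.fit_fsc_logistic(ps.ShellProfile(s=s, values=vals))
        assert abs(fit.a - a_true) / a_true < 1e-6
        assert abs(fit.b - b_true) / b_true < 1e-6
        assert fit.resolution == pytest.approx(25.0, rel=1e-6)

    def test_fitted_curve_at_half_crossing(self):
        s = np.linspace(0.005, 0.075, 30)
        vals = 1.0 / (1.0 + np.exp(150 * s - 6))
        fit = ps.fit_fsc_logistic(ps.ShellProfile(s=s, values=vals))
        assert fit(fit.s_half) == 0.5

    def test_no_crossing_error(self):
        s = np.linspace(0.01, 0.05, 10)
        with pytest.raises(ValueError, match="crossing"):
            ps.fit_fsc_logistic(ps.ShellProfile(s=s, values=np.ones(10)))


class TestThresholdCrossing:
    def test_exact_hit(self):
        p = ps.ShellProfile(s=[0.01, 0.02, 0.03, 0.04], values=[0.9, 0.7, 0.5, 0.3])
        assert ps.threshold_crossing(p) == pytest.approx(0.03)

    def test_linear_interpolation(self):
        p = ps.ShellProfile(s=[0.01, 0.02], values=[0.8, 0.2])
        assert ps.threshold_crossing(p) == pytest.approx(0.015)

    def test_monotone_increasing_error(self):
        p = ps.ShellProfile(s=[0.01, 0.02], values=[0.2, 0.8])
        with pytest.raises(ValueError):
            ps.threshold_crossing(p)


class TestSphericalAverage:
    def _refl(self, hkl, I, sigma=None, cell=(100.0, 100.0, 100.0, 90.0, 90.0, 90.0)):
        return ReflectionSet(hkl=np.array(hkl), intensity=np.array(I, dtype=float),
                             sigma=None if sigma is None else np.array(sigma, float),
                             cell=cell)

    def test_constant_intensity(self):
        rng = np.random.default_rng(0)
        hkl = rng.integers(-8, 9, (200, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        prof = ps.spherical_average(self._refl(hkl, np.full(len(hkl), 7.0)), n_bins=20)
        assert np.abs(prof.values - 7.0).max() < 1e-12

    def test_single_reflection_s_value(self):
        prof = ps.spherical_average(self._refl([[0, 0, 5]], [3.0]), n_bins=150)
        assert len(prof) == 1
        # cubic cell a = 100 Å: S(0,0,5) = 5/100 = 0.05 (d = 20 Å)
        assert prof.s[0] == pytest.approx(0.05, abs=1e-6)
        assert prof.values[0] == 3.0

    def test_conserves_weighted_mean(self):
        rng = np.random.default_rng(1)
        hkl = rng.integers(-6, 7, (150, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        I = rng.random(len(hkl)) * 10
        rs = self._refl(hkl, I)
        prof = ps.spherical_average(rs, n_bins=15)
        cell = rs.gemmi_cell
        s = np.sqrt([cell.calculate_1_d2(h) for h in hkl.tolist()])
        counts = np.histogram(s, bins=np.linspace(s.min(), s.max() * (1 + 1e-12), 16))[0]
        assert np.sum(prof.values * counts[counts > 0]) == pytest.approx(I.sum(), rel=1e-9)

    def test_inverse_variance_weighting(self):
        rs = self._refl([[1, 0, 0], [1, 0, 0]], [10.0, 20.0], sigma=[1.0, 2.0])
        prof = ps.spherical_average(rs, n_bins=5)
        expected = (10 / 1 + 20 / 4) / (1 / 1 + 1 / 4)
        assert prof.values[0] == pytest.approx(expected)


class TestSubtractMerge:
    def test_subtract_self_gives_zero(self):
        p = ps.ShellProfile(s=[0.01, 0.02, 0.03], values=[5.0, 4.0, 3.0])
        out = ps.subtract_buffer(p, p)
        assert np.all(out.values == 0)

    def test_errors_add_in_quadrature(self):
        a = ps.ShellProfile(s=[0.01], values=[1.0], errors=[3.0])
        b = ps.ShellProfile(s=[0.01], values=[0.5], errors=[4.0])
        assert ps.subtract_buffer(a, b).errors[0] == pytest.approx(5.0)

    def test_mismatched_grids_error(self):
        a = ps.ShellProfile(s=[0.01, 0.02], values=[1.0, 1.0])
        b = ps.ShellProfile(s=[0.015, 0.025], values=[1.0, 1.0])
        with pytest.raises(ValueError):
            ps.subtract_buffer(a, b)

    def test_merge_identity_split(self):
        s = np.linspace(0.01, 0.1, 40)
        I = np.exp(-100 * s)
        low = ps.ShellProfile(s=s[:25], values=I[:25])
        high = ps.ShellProfile(s=s[20:], values=I[20:])
        merged, scale = ps.merge_profiles(low, high)
        assert scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(merged.s, s)
        np.testing.assert_allclose(merged.values, I, rtol=1e-12)

    def test_merge_recovers_scale(self):
        s = np.linspace(0.01, 0.1, 40)
        I = np.exp(-80 * s)
        low = ps.ShellProfile(s=s[:25], values=I[:25])
        high = ps.ShellProfile(s=s[20:], values=5.0 * I[20:])
        _, scale = ps.merge_profiles(low, high)
        assert scale == pytest.approx(0.2, abs=1e-9)

    def test_merge_idempotent(self):
        s = np.linspace(0.01, 0.1, 40)
        I = np.exp(-80 * s)
        low = ps.ShellProfile(s=s[:25], values=I[:25])
        high = ps.ShellProfile(s=s[20:], values=I[20:])
        merged, _ = ps.merge_profiles(low, high)
        again, scale = ps.merge_profiles(merged, high)
        assert scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(again.values, merged.values, atol=1e-9)

    def test_insufficient_overlap_error(self):
        low = ps.ShellProfile(s=[0.01, 0.02], values=[1.0, 1.0])
        high = ps.ShellProfile(s=[0.02, 0.03], values=[1.0, 1.0])
        with pytest.raises(ValueError, match="overlap"):
            ps.merge_profiles(low, high)


class TestGuinier:
    def test_exact_guinier_curve(self):
        rg_true, i0_true = 53.2, 100.0
        q = np.linspace(0.006, 0.08, 60)
        I = i0_true * np.exp(-q ** 2 * rg_true ** 2 / 3.0)
        fit = ps.guinier_fit(ps.ShellProfile(s=q / (2 * np.pi), values=I))
        assert fit.rg == pytest.approx(rg_true, rel=1e-6)
        assert fit.i0 == pytest.approx(i0_true, rel=1e-6)

    def test_uniform_sphere(self):
        # Rg of a uniform sphere is sqrt(3/5)·R; the Guinier truncation bias
        # scales as (q_max·Rg)² so the analytic check uses a tight window
        R = 68.7
        q = np.linspace(0.002, 0.03, 200)
        qr = q * R
        I = (3 * (np.sin(qr) - qr * np.cos(qr)) / qr ** 3) ** 2
        fit = ps.guinier_fit(ps.ShellProfile(s=q / (2 * np.pi), values=I), qrg_limit=0.75)
        assert abs(fit.rg - np.sqrt(3 / 5) * R) / (np.sqrt(3 / 5) * R) < 0.01

    def test_flat_profile_error(self):
        q = np.linspace(0.01, 0.05, 20)
        with pytest.raises(ValueError):
            ps.guinier_fit(ps.ShellProfile(s=q, values=np.ones(20)))

    def test_q_range_respects_limit(self):
        q = np.linspace(0.006, 0.2, 300)
        I = 50 * np.exp(-q ** 2 * 30.0 ** 2 / 3.0)
        fit = ps.guinier_fit(ps.ShellProfile(s=q / (2 * np.pi), values=I), qrg_limit=1.3)
        assert fit.q_range_used[1] * fit.rg <= 1.3 + 1e-9


class TestHalfMapResolution:
    def test_fsc_decreases_and_resolution_matches_analytic(self):
        a, b, s_half = make_falloff_half_maps(seed=11)
        fsc = ps.compute_fsc(a, b, n_shells=30)
        smooth = np.convolve(fsc.values, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(smooth) < 0.05)  # monotone after smoothing
        fit = ps.fit_fsc_logistic(fsc)
        assert abs(fit.s_half - s_half) / s_half < 0.1

    def test_zero_noise_pair_is_perfect(self):
        sig = _noise_map(5, n=32)
        a, b = make_fsc_pair(sig, noise_sd=0.0, seed=0)
        fsc = ps.compute_fsc(a, b, n_shells=10)
        assert np.abs(fsc.values - 1.0).max() < 1e-9
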