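"""Registration, CoR estimation, reprojection alignment and ring removal."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from phasetomo.align import (
    RegistrationError,
    RingFilterParams,
    bin_image,
    find_cor_opposing,
    find_cor_sinogram,
    register_translation,
    remove_rings_additive,
    remove_rings_wavelet,
    reprojection_align,
)
from phasetomo.tomo import TomoGeometry, forward_project

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def textured_disk(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    mask = (x - c) ** 2 + (y - c) ** 2 < radius**2
    return gaussian_filter(rng.random((n, n)), 2) * mask


def ball_volume(n, seed=0):
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[:n, :n, :n]
    vol = np.zeros((n, n, n))
    for _ in range(6):
        p = rng.uniform(0.25 * n, 0.75 * n, 3)
        r = rng.uniform(n / 20, n / 9)
        vol += ((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2 < r * r) \
            * rng.uniform(0.5, 1.0)
    return vol


class TestRegisterTranslation:
    def test_integer_cyclic_shift(self, rng):
        a = rng.random((64, 64))
        b = np.roll(a, (3, -5), axis=(0, 1))
        res = register_translation(a, b)
        # b(x) = a(x - (3,-5)) so a(x) = b(x - (-3,5))
        assert res.shift == (-3.0, 5.0)

    def test_self_registration_is_zero(self, rng):
        a = rng.random((32, 32))
        assert register_translation(a, a).shift == (0.0, 0.0)

    def test_subpixel_shift_recovered(self, rng):
        a = gaussian_filter(rng.random((64, 64)), 2)
        b = np.fft.ifftn(fourier_shift(np.fft.fftn(a), (2.25, -0.75))).real
        res = register_translation(a, b, upsample=100)
        assert abs(res.shift[0] + 2.25) < 0.01
        assert abs(res.shift[1] - 0.75) < 0.01

    def test_flat_image_rejected(self):
        with pytest.raises(RegistrationError):
            register_translation(np.ones((16, 16)), np.ones((16, 16)))

    def test_antisymmetry(self, rng):
        a = gaussian_filter(rng.random((64, 64)), 2)
        b = np.fft.ifftn(fourier_shift(np.fft.fftn(a), (1.4, -2.6))).real
        s_ab = register_translation(a, b).shift
        s_ba = register_translation(b, a).shift
        assert abs(s_ab[0] + s_ba[0]) < 0.01
        assert abs(s_ab[1] + s_ba[1]) < 0.01


class TestCorOpposing:
    def test_centered_phantom_gives_zero(self):
        img = textured_disk(128, 40)
        g = TomoGeometry(np.array([0.0, np.pi]))
        p = forward_project(img, g)
        assert abs(find_cor_opposing(p[0], p[1])) < 0.05

    def test_known_offset_recovered(self):
        img = textured_disk(128, 40)
        g = TomoGeometry(np.array([0.0, np.pi]), cor_offset=7.3)
        p = forward_project(img, g)
        assert find_cor_opposing(p[0], p[1]) == pytest.approx(7.3, abs=0.1)

    def test_fixed_point_after_compensation(self):
        """Applying the estimated offset and re-estimating gives ~0."""
        img = textured_disk(128, 40)
        g = TomoGeometry(np.array([0.0, np.pi]), cor_offset=4.6)
        p = forward_project(img, g)
        cor = find_cor_opposing(p[0], p[1])
        g2 = TomoGeometry(g.angles, cor_offset=4.6 - cor)
        p2 = forward_project(img, g2)
        assert abs(find_cor_opposing(p2[0], p2[1])) < 0.05


class TestCorSinogram:
    def test_jitter_free_offset_recovered(self):
        img = textured_disk(128, 40)
        angles = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        g = TomoGeometry(angles, cor_offset=4.0)
        sino = forward_project(img, g)
        cor, tilt = find_cor_sinogram(sino, angles)
        assert cor == pytest.approx(4.0, abs=0.1)
        assert tilt == 0.0

    def test_more_robust_than_single_pair_under_jitter(self, rng):
        """Averaging over all angles beats one opposing pair when the
        trajectory jitters."""
        img = textured_disk(128, 40)
        angles = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        jitter = np.zeros((360, 2))
        jitter[:, 1] = rng.uniform(-2, 2, 360)
        g = TomoGeometry(angles, shifts=jitter, cor_offset=4.0)
        sino = forward_project(img, g)
        cor_sino, _ = find_cor_sinogram(sino, angles)
        cor_pair = find_cor_opposing(sino[0], sino[180])
        assert abs(cor_sino - 4.0) < abs(cor_pair - 4.0)

    def test_axis_tilt_recovered_from_rows(self):
        """Per-row CoRs of a tilted axis give the tilt slope within 20%."""
        vol = ball_volume(64, seed=3)
        angles = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        g = TomoGeometry(angles, tilt=0.01)
        proj = forward_project(vol, g)
        rows = [20, 32, 44]
        sinos = np.stack([proj[:, r, :] for r in rows])
        cors = [find_cor_sinogram(s, angles)[0] for s in sinos]
        slope = np.polyfit(np.asarray(rows) - 31.5, cors, 1)[0]
        assert slope == pytest.approx(0.01, rel=0.2)

    def test_span_below_pi_rejected(self):
        with pytest.raises(ValueError):
            find_cor_sinogram(np.zeros((90, 32)),
                              np.linspace(0, np.pi / 2, 90))


class TestReprojectionAlign:
    def test_aligned_data_is_fixed_point(self):
        vol = ball_volume(64, seed=1)
        angles = np.linspace(0, np.pi, 90, endpoint=False)
        g = TomoGeometry(angles)
        proj = forward_project(vol, g)
        g_est, history = reprojection_align(proj, g, iterations=5, binning=2)
        assert len(history) == 1  # stop at iteration 1: max update < 0.1 px
        assert np.abs(g_est.shifts).max() < 0.1

    def test_injected_jitter_recovered(self, rng):
        """Uniform ±10 px per-projection jitter reduced to < 0.5 px RMS
        (modulo the global-translation gauge of the trajectory)."""
        vol = ball_volume(96, seed=2)
        angles = np.linspace(0, np.pi, 120, endpoint=False)
        true_shifts = rng.uniform(-10, 10, (120, 2))
        g_true = TomoGeometry(angles, shifts=true_shifts.copy())
        proj = forward_project(vol, g_true)
        g_est, history = reprojection_align(
            proj, TomoGeometry(angles), iterations=50, binning=4, upsample=50,
            stop_update=0.05,
        )
        resid = g_est.shifts - true_shifts
        resid[:, 0] -= resid[:, 0].mean()
        basis = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        resid[:, 1] -= basis @ np.linalg.lstsq(basis, resid[:, 1], rcond=None)[0]
        rms = np.sqrt(np.mean(resid**2))
        assert rms < 0.5
        # error shrinks monotonically (allowing plateaus) early on
        def gauge_rms(shifts):
            r = shifts - true_shifts
            r = r.copy()
            r[:, 0] -= r[:, 0].mean()
            r[:, 1] -= basis @ np.linalg.lstsq(basis, r[:, 1], rcond=None)[0]
            return np.sqrt(np.mean(r**2))

        trace = [gauge_rms(h) for h in history[:10]]
        assert all(b <= a + 0.05 for a, b in zip(trace, trace[1:]))

    def test_binning_blockmean(self):
        img = np.arange(16.0).reshape(4, 4)
        out = bin_image(img, 2)
        assert out.shape == (2, 2)
        assert out[0, 0] == pytest.approx(img[:2, :2].mean())


class TestRingRemoval:
    @pytest.fixture
    def smooth_sino(self, rng):
        base = np.outer(1.0 + 0.1 * np.sin(np.linspace(0, np.pi, 256)),
                        np.linspace(1.0, 2.0, 256))
        return base + 0.01 * gaussian_filter(rng.random((256, 256)), 2)

    def test_additive_column_means_equal_smoothed(self, smooth_sino):
        striped = smooth_sino.copy()
        striped[:, 100] += 0.5
        out = remove_rings_additive(striped, smooth_width=31)
        from scipy.ndimage import uniform_filter1d

        # the correction maps the column means onto their moving average
        expected = uniform_filter1d(striped.mean(axis=0), 31, mode="nearest")
        assert np.allclose(out.mean(axis=0), expected, atol=1e-9)

    def test_additive_suppresses_isolated_stripe(self, smooth_sino):
        striped = smooth_sino.copy()
        striped[:, 100] += 0.5
        out = remove_rings_additive(striped, smooth_width=31)
        resid = np.abs((out - smooth_sino)[:, 100]).mean()
        # suppression down to the moving-average leakage level (~a/width)
        assert resid <= 1.5 * 0.5 / 31

    def test_additive_zero_input(self):
        assert np.allclose(remove_rings_additive(np.zeros((64, 64))), 0.0)

    def test_additive_parameter_validation(self):
        with pytest.raises(ValueError):
            remove_rings_additive(np.zeros((32, 32)), smooth_width=4)

    def test_wavelet_suppresses_stripe_5x(self, smooth_sino):
        striped = smooth_sino.copy()
        striped[:, 100] += 0.5
        out = remove_rings_wavelet(striped, RingFilterParams(levels=4, sigma=1.0))
        resid = np.abs((out - smooth_sino)[:, 100]).mean()
        assert resid < 0.2 * 0.5

    def test_wavelet_distortion_below_2_percent(self, smooth_sino):
        out = remove_rings_wavelet(smooth_sino, RingFilterParams(levels=4, sigma=1.0))
        change = np.sqrt(np.mean((out - smooth_sino) ** 2))
        assert change < 0.02 * np.ptp(smooth_sino)

    def test_wavelet_sigma_zero_limit_damps_only_dc(self):
        """g(k) = 1 - exp(-k²/2σ²) → 1 for k ≠ 0 as σ → 0: only the exact
        angle-constant component of the stripe band is removed."""
        params = RingFilterParams(levels=1, sigma=1e-6)
        k = np.arange(1, 10)
        damp = 1.0 - np.exp(-(k**2) / (2 * params.sigma**2))
        assert np.allclose(damp, 1.0)

    def test_wavelet_depth_validation(self):
        with pytest.raises(ValueError):
            remove_rings_wavelet(np.zeros((16, 16)), RingFilterParams(levels=6))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            RingFilterParams(levels=0)
        with pytest.raises(ValueError):
            RingFilterParams(sigma=0.0)
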