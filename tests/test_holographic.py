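"""Holographic-regime retrieval: CTF, constrained CTF, Tikhonov(-TV), AP."""

import numpy as np
import pytest

from phasetomo.holographic import (
    Constraints,
    HologramStack,
    RegularizationProfile,
    _tikhonov_problem,
    alternating_projections,
    ctf_constrained,
    ctf_factor,
    ctf_retrieve,
    disk_support,
    tikhonov_retrieve,
    tikhonov_tv,
    two_level_alpha,
)
from phasetomo.optimize import check_grad
from phasetomo.sim import simulate_hologram
from phasetomo.wave import chirp, fresnel_propagate
from tests.conftest import rel_l2, smooth_phase

# reference multi-distance conditions: B = 0.035, two rescaled Fresnel
# numbers, two-level regularization weights 2e-5 / 3e-5
B = 0.035
F_PAIR = [2.44e-4, 1.98e-4]
PROFILE = RegularizationProfile(alpha_low=2e-5, alpha_high=3e-5)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def make_stack(phi, fresnel=F_PAIR, b_ratio=B, photons=None, seed=0):
    rng = np.random.default_rng(seed)
    imgs = [simulate_hologram(phi, f, b_ratio, photons, rng) for f in fresnel]
    return HologramStack(np.array(imgs), list(fresnel))


class TestCtfFactor:
    def test_dc_equals_b(self):
        s = ctf_factor((16, 16), 0.1, 0.25)
        assert s[0, 0] == pytest.approx(0.25)

    def test_known_chi_values(self):
        # on a custom grid: chi = pi/2 -> s = 1 (any B contributes 0); chi = pi -> s = -B
        chi = chirp((64, 64), 0.01)
        s = ctf_factor((64, 64), 0.01, 0.3)
        near_half = np.argmin(np.abs(chi - np.pi / 2))
        assert np.allclose(s.ravel()[near_half],
                           np.sin(chi.ravel()[near_half]) + 0.3 * np.cos(chi.ravel()[near_half]))
        assert np.allclose(np.sin(np.pi / 2) + 0.3 * np.cos(np.pi / 2), 1.0)
        assert np.sin(np.pi) + 0.3 * np.cos(np.pi) == pytest.approx(-0.3)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            ctf_factor((8, 8), 0.1, -0.1)


class TestTwoLevelAlpha:
    def test_limits(self):
        alpha = two_level_alpha((128, 128), 0.05, PROFILE)
        chi = chirp((128, 128), 0.05)
        assert alpha[0, 0] == pytest.approx(PROFILE.alpha_low, rel=1e-3)
        assert alpha[chi > np.pi] == pytest.approx(PROFILE.alpha_high, rel=1e-2)

    def test_monotone_in_chi(self):
        alpha = two_level_alpha((64, 64), 0.03, PROFILE)
        chi = chirp((64, 64), 0.03)
        order = np.argsort(chi.ravel())
        assert np.all(np.diff(alpha.ravel()[order]) >= -1e-12)

    def test_equal_levels_constant(self):
        prof = RegularizationProfile(1e-4, 1e-4)
        alpha = two_level_alpha((32, 32), 0.1, prof)
        assert np.allclose(alpha, 1e-4)


class TestCtfRetrieve:
    def test_unit_holograms_give_zero_phase(self):
        h = HologramStack(np.ones((2, 32, 32)), F_PAIR)
        assert np.allclose(ctf_retrieve(h, B, PROFILE), 0.0, atol=1e-12)

    def test_weak_object_two_distance_recovery(self):
        """Reference conditions: two distances, max |phi| = 0.1 -> < 2% error."""
        phi = smooth_phase(256, sigma=6, peak=0.1)
        h = make_stack(phi)
        rec = ctf_retrieve(h, B, PROFILE)
        assert rel_l2(rec, phi) < 0.02

    def test_second_distance_fills_ctf_zeros(self):
        """CTF zeros of a single distance dominate its error; adding the
        second distance cuts the error at least 2-fold."""
        phi = smooth_phase(256, sigma=6, peak=0.1, seed=3)
        h2 = make_stack(phi)
        h1 = HologramStack(h2.images[:1], [F_PAIR[0]])
        e1 = rel_l2(ctf_retrieve(h1, B, PROFILE), phi)
        e2 = rel_l2(ctf_retrieve(h2, B, PROFILE), phi)
        assert e1 / e2 >= 2.0

    def test_linearization_consistency(self):
        """|P exp((B+i)phi)|^2 - 1 matches IDFT[2 s(nu) DFT(phi)] for weak
        phases — ties the CTF sign/scale convention to the propagator."""
        phi = smooth_phase(128, sigma=3, peak=1e-3, seed=8)
        f = 5e-3
        intensity = np.abs(fresnel_propagate(np.exp((B + 1j) * phi), f)) ** 2
        linear = np.fft.ifft2(2 * ctf_factor(phi.shape, f, B) * np.fft.fft2(phi)).real
        assert np.linalg.norm((intensity - 1) - linear) / np.linalg.norm(linear) < 1e-2


class TestCtfConstrained:
    def test_trivial_constraints_match_unconstrained(self):
        phi = smooth_phase(64, sigma=4, peak=0.1)
        h = make_stack(phi)
        rec_c, _ = ctf_constrained(h, B, PROFILE, Constraints())
        assert np.allclose(rec_c, ctf_retrieve(h, B, PROFILE), atol=1e-8)

    def test_nonpositivity_improves_error_and_holds_exactly(self):
        phi = smooth_phase(64, sigma=4, peak=0.1, seed=2)
        h = make_stack(phi, photons=1e4)
        unc = ctf_retrieve(h, B, PROFILE)
        con, rep = ctf_constrained(h, B, PROFILE, Constraints(nonpositive=True),
                                   max_iter=200)
        assert con.max() <= 0.0
        assert rel_l2(con, phi) <= rel_l2(unc, phi)

    def test_support_is_enforced_exactly(self):
        phi = smooth_phase(64, sigma=4, peak=0.1, seed=2)
        support = disk_support((64, 64), 20.0)
        h = make_stack(phi * support)
        rec, _ = ctf_constrained(h, B, PROFILE,
                                 Constraints(nonpositive=True, support=support))
        assert np.all(rec[~support] == 0.0)
        assert rec.max() <= 0.0


class TestTikhonov:
    def test_unit_holograms_zero_init_is_stationary(self):
        h = HologramStack(np.ones((2, 32, 32)), F_PAIR)
        rec, rep = tikhonov_retrieve(h, B, PROFILE, max_iter=10, x0=np.zeros((32, 32)))
        assert np.allclose(rec, 0.0, atol=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        """Hand-derived gradient of the amplitude-residual functional."""
        phi0 = rng.standard_normal((8, 8)) * 0.3
        h = make_stack(phi0, fresnel=[0.02, 0.03])
        alpha = two_level_alpha((8, 8), h.fresnel[0], PROFILE)
        problem = _tikhonov_problem(h, B, alpha, Constraints())
        x = rng.standard_normal((8, 8)) * 0.2
        assert check_grad(problem.smooth_value, problem.smooth_grad, x) < 1e-5

    def test_tv_gradient_matches_finite_differences(self, rng):
        phi0 = rng.standard_normal((8, 8)) * 0.3
        h = make_stack(phi0, fresnel=[0.02, 0.03])
        alpha = two_level_alpha((8, 8), h.fresnel[0], PROFILE)
        problem = _tikhonov_problem(h, B, alpha, Constraints(), tv_weight=0.1,
                                    tv_eps=1e-2)
        x = rng.standard_normal((8, 8)) * 0.2
        assert check_grad(problem.smooth_value, problem.smooth_grad, x) < 1e-5

    def test_strong_phase_beats_ctf(self):
        """max |phi| = 1.5: the nonlinear solver must beat the linear CTF."""
        phi = smooth_phase(128, sigma=6, peak=1.5, seed=4)
        h = make_stack(phi)
        e_ctf = rel_l2(ctf_retrieve(h, B, PROFILE), phi)
        rec, _ = tikhonov_retrieve(h, B, PROFILE, Constraints(nonpositive=True),
                                   max_iter=100)
        assert rel_l2(rec, phi) < e_ctf

    def test_constraints_hold_exactly(self):
        phi = smooth_phase(32, sigma=3, peak=0.5, seed=4)
        support = disk_support((32, 32), 12.0)
        h = make_stack(phi * support)
        rec, _ = tikhonov_retrieve(h, B, PROFILE,
                                   Constraints(nonpositive=True, support=support),
                                   max_iter=30)
        assert rec.max() <= 0.0
        assert np.all(rec[~support] == 0.0)


class TestTikhonovTV:
    def test_zero_weight_reduces_to_tikhonov(self):
        phi = smooth_phase(32, sigma=3, peak=0.3, seed=5)
        h = make_stack(phi)
        a, _ = tikhonov_retrieve(h, B, PROFILE, max_iter=15)
        b_, _ = tikhonov_tv(h, B, PROFILE, tv_weight=0.0, max_iter=15)
        assert np.allclose(a, b_, atol=1e-10)

    def test_tv_denoises_piecewise_constant_phantom(self):
        """Noisy (10^3 photons) piecewise-constant object: the TV solution has
        markedly lower total variation at a comparable data residual."""
        n = 64
        y, x = np.mgrid[:n, :n]
        phi = -0.3 * (((x - 32) ** 2 + (y - 32) ** 2) < 15**2).astype(float)
        h = make_stack(phi, fresnel=[0.02, 0.03], photons=1e3)

        def total_variation(img):
            gx = np.roll(img, -1, 1) - img
            gy = np.roll(img, -1, 0) - img
            return float(np.sum(np.hypot(gx, gy)))

        def data_residual(img):
            val = 0.0
            for im, f in zip(h.images, h.fresnel):
                psi = fresnel_propagate(np.exp((B + 1j) * img), f)
                val += float(np.sum((np.abs(psi) - np.sqrt(im)) ** 2))
            return val

        rec0, _ = tikhonov_retrieve(h, B, PROFILE, Constraints(nonpositive=True),
                                    max_iter=60)
        rec1, _ = tikhonov_tv(h, B, PROFILE, Constraints(nonpositive=True),
                              tv_weight=5e-3, max_iter=60)
        assert total_variation(rec1) < total_variation(rec0)
        assert data_residual(rec1) < 1.5 * data_residual(rec0)

    def test_invalid_parameters_rejected(self):
        h = HologramStack(np.ones((1, 16, 16)), [0.1])
        with pytest.raises(ValueError):
            tikhonov_tv(h, B, tv_weight=-1.0)
        with pytest.raises(ValueError):
            tikhonov_tv(h, B, tv_eps=0.0)


class TestAlternatingProjections:
    def test_unit_holograms_zero_fixed_point(self):
        h = HologramStack(np.ones((2, 32, 32)), F_PAIR)
        rec, residuals = alternating_projections(h, B, max_iter=5)
        assert np.allclose(rec, 0.0, atol=1e-10)
        assert residuals[-1] < 1e-10

    def test_noiseless_weak_residual_reduction(self):
        """Magnitude residual after 200 iterations < 10% of its start."""
        phi = smooth_phase(64, sigma=4, peak=0.1, seed=3)
        h = make_stack(phi, fresnel=[0.01, 0.015])
        _, residuals = alternating_projections(h, B, max_iter=200)
        assert residuals[-1] < 0.1 * residuals[0]

    def test_measurement_step_matches_moduli_exactly(self):
        """After modulus replacement each plane's amplitude equals sqrt(I)."""
        phi = smooth_phase(32, sigma=3, peak=0.2, seed=6)
        h = make_stack(phi, fresnel=[0.02])
        amp = np.sqrt(h.images[0])
        psi = fresnel_propagate(np.exp((B + 1j) * phi), h.fresnel[0])
        replaced = amp * psi / np.abs(psi)
        assert np.allclose(np.abs(replaced), amp, atol=1e-12)


def test_translation_equivariance_of_retrievals():
    """Cyclic shifts of all holograms cyclically shift the retrieved phase."""
    phi = smooth_phase(64, sigma=4, peak=0.1, seed=9)
    h = make_stack(phi)
    shift = (9, -13)
    shifted = HologramStack(np.roll(h.images, shift, axis=(1, 2)), h.fresnel)
    rec = ctf_retrieve(h, B, PROFILE)
    rec_s = ctf_retrieve(shifted, B, PROFILE)
    assert np.allclose(rec_s, np.roll(rec, shift, axis=(0, 1)), atol=1e-10)
    tik, _ = tikhonov_retrieve(h, B, PROFILE, max_iter=10)
    tik_s, _ = tikhonov_retrieve(shifted, B, PROFILE, max_iter=10)
    assert np.allclose(tik_s, np.roll(tik, shift, axis=(0, 1)), atol=1e-8)


def test_hologram_stack_validation():
    with pytest.raises(ValueError):
        HologramStack(np.ones((2, 16, 16)), [0.1])  # wrong fresnel count
    with pytest.raises(ValueError):
        HologramStack(np.zeros((1, 16, 16)), [0.1])  # nonpositive intensities


def test_constraint_projection_is_idempotent(rng):
    c = Constraints(nonpositive=True, support=disk_support((32, 32), 10.0),
                    vmin=-2.0)
    x = rng.standard_normal((32, 32))
    p1 = c.project(x)
    assert np.array_equal(c.project(p1), p1)
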