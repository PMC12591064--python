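"""Single-distance phase retrieval in the direct-contrast regime.

At Fresnel numbers of order one a hologram shows edge enhancement rather
than extended fringes, and single-distance closed-form Fourier filters
suffice.  All methods assume the homogeneous ("single-material") object
model: transmission T(x) = exp((B + i)·φ(x)) with B = β/δ ≥ 0 and phase
φ ≤ 0 for matter denser than vacuum, so the attenuation is locked to the
phase via μ = −2Bφ.

Implemented filters (frequency ν in cycles/pixel, χ(ν) = π(νx²/fx + νy²/fy)):

* Paganin:              φ = ln( F⁻¹[ F(I) / (1 + χ/B) ] ) / (2B)
* generalized Paganin:  χ replaced by its discrete-Laplacian counterpart
                        χ_d(ν) = [(1 − cos 2πνx)/fx + (1 − cos 2πνy)/fy]/(2π),
                        which matches χ to O(ν⁴) but damps less near Nyquist
* modified Bronnikov:   φ̂ = F(I − 1) / (2χ + α)     (weak pure-phase limit)
* Bronnikov-aided correction: divide I by the phase-contrast factor
                        1 + γ·F⁻¹[2χ·F(φ_MB)] to recover an absorption image
"""

from __future__ import annotations

import warnings

import numpy as np

from .wave import _as_pair, chirp, frequency_grid

__all__ = [
    "paganin",
    "generalized_paganin",
    "modified_bronnikov",
    "bronnikov_aided_correction",
    "discrete_chirp",
]


def _check_intensity(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    if I.ndim != 2:
        raise ValueError(f"expected a 2-D intensity image, got ndim={I.ndim}")
    if not np.all(np.isfinite(I)):
        raise ValueError("intensity image contains non-finite values")
    if np.any(I <= 0):
        raise ValueError(
            "intensity image has non-positive pixels; run faulty-pixel repair "
            "and flat-field correction first"
        )
    return I


def discrete_chirp(shape: tuple[int, int], f) -> np.ndarray:
    """Discrete-Laplacian chirp χ_d(ν), the generalized-Paganin kernel.

    χ_d(ν) = [(1 − cos 2πνx)/fx + (1 − cos 2πνy)/fy] / (2π).  Taylor
    expansion of 1 − cos 2πν = 2π²ν² − O(ν⁴) shows χ_d → χ as ν → 0 and
    χ_d < χ elsewhere (weaker high-frequency damping, the point of the
    generalized filter).
    """
    fx, fy = _as_pair(f)
    nu_y, nu_x = frequency_grid(shape)
    return (
        (1.0 - np.cos(2.0 * np.pi * nu_x)) / fx
        + (1.0 - np.cos(2.0 * np.pi * nu_y)) / fy
    ) / (2.0 * np.pi)


def _paganin_core(I: np.ndarray, chi: np.ndarray, b_ratio: float) -> np.ndarray:
    filt = 1.0 / (1.0 + chi / b_ratio)
    smoothed = np.fft.ifft2(np.fft.fft2(I) * filt).real
    # the filtered intensity is a low-passed exp(2Bφ) ≤ max(I); clip guards
    # against tiny negative overshoots of the Fourier filter
    smoothed = np.maximum(smoothed, 1e-12)
    return np.log(smoothed) / (2.0 * b_ratio)


def paganin(I: np.ndarray, f, b_ratio: float) -> np.ndarray:
    """Paganin single-material phase retrieval.

    Parameters
    ----------
    I : flat-field-normalized intensity image (strictly positive).
    f : per-pixel Fresnel number (scalar or ``(fx, fy)``).
    b_ratio : β/δ ratio B > 0 of the homogeneous object.

    Returns the phase map φ (radians, φ ≤ 0 for absorbing matter).
    """
    I = _check_intensity(I)
    if not b_ratio > 0:
        raise ValueError(f"beta/delta ratio must be positive, got {b_ratio}")
    return _paganin_core(I, chirp(I.shape, f), b_ratio)


def generalized_paganin(I: np.ndarray, f, b_ratio: float) -> np.ndarray:
    """Paganin filter with the discrete-Laplacian chirp (sharper at Nyquist)."""
    I = _check_intensity(I)
    if not b_ratio > 0:
        raise ValueError(f"beta/delta ratio must be positive, got {b_ratio}")
    return _paganin_core(I, discrete_chirp(I.shape, f), b_ratio)


def modified_bronnikov(I: np.ndarray, f, alpha: float = 1e-3) -> np.ndarray:
    """Modified Bronnikov retrieval for weak pure-phase objects.

    φ̂(ν) = F(I − 1)(ν) / (2χ(ν) + α); ``alpha`` (dimensionless, on the χ
    scale) regularizes the DC singularity of the pure-phase contrast
    transfer 2·sin χ ≈ 2χ.
    """
    I = _check_intensity(I)
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    chi = chirp(I.shape, f)
    phi_hat = np.fft.fft2(I - 1.0) / (2.0 * chi + alpha)
    return np.fft.ifft2(phi_hat).real


def bronnikov_aided_correction(
    I: np.ndarray,
    f,
    alpha: float = 1e-3,
    gamma: float = 1.0,
    clip: float = 0.1,
) -> np.ndarray:
    """Bronnikov-aided correction: strip propagation fringes from I.

    Retrieves a modified-Bronnikov phase estimate, builds the phase-contrast
    factor c = F⁻¹[2χ·F(φ_MB)] and returns A = I / (1 + γ·c), an
    attenuation-only image.  γ ∈ [0, 1] scales the correction strength; the
    denominator is clipped at ``clip`` to avoid blow-ups where the linear
    model overshoots.
    """
    I = _check_intensity(I)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if gamma == 0.0:
        return I.copy()
    phi = modified_bronnikov(I, f, alpha)
    chi = chirp(I.shape, f)
    c = np.fft.ifft2(2.0 * chi * np.fft.fft2(phi)).real
    denom = 1.0 + gamma * c
    n_clipped = int(np.count_nonzero(denom < clip))
    if n_clipped:
        warnings.warn(
            f"BAC denominator clipped at {clip} in {n_clipped} pixels",
            RuntimeWarning,
            stacklevel=2,
        )
        denom = np.maximum(denom, clip)
    return I / denom
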