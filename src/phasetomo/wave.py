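"""Discrete Fresnel free-space propagation.

The propagator is a unitary Fourier multiplier acting on a sampled complex
wavefront.  With frequencies ν in cycles/pixel and per-axis Fresnel numbers
(fx, fy) referenced to one pixel, the forward kernel is

    H(ν) = exp(−i χ(ν)),      χ(ν) = π (νx²/fx + νy²/fy),

and backward propagation uses the complex conjugate.  χ is the phase-chirp
argument that also appears in every transfer-function retrieval filter, so
it is defined once here and imported everywhere else — a single source of
truth for the frequency grid and the sign convention.

The sign of the exponent is a package-wide convention: it is what makes a
denser-than-vacuum object (phase φ ≤ 0) produce the contrast factor
sin χ + (β/δ) cos χ used by the linearized retrieval methods.  All retrieval
code is validated against simulations run through this propagator, never
against absolute sign claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import FresnelPair

__all__ = [
    "frequency_grid",
    "chirp",
    "PropagationKernel",
    "fresnel_propagate",
]


def _as_pair(f) -> FresnelPair:
    if np.isscalar(f):
        return FresnelPair.isotropic(float(f)).validate()
    return FresnelPair(*f).validate()


def frequency_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """DFT frequency axes in cycles/pixel, zero frequency first.

    Returns ``(nu_y, nu_x)`` broadcastable to ``shape`` (rows = y/vertical,
    columns = x/horizontal), each covering [−1/2, 1/2) in standard DFT
    ordering.
    """
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise ValueError(f"shape must be at least 2x2, got {shape}")
    nu_y = np.fft.fftfreq(ny)[:, None]
    nu_x = np.fft.fftfreq(nx)[None, :]
    return nu_y, nu_x


def chirp(shape: tuple[int, int], f) -> np.ndarray:
    """Chirp argument χ(ν) = π(νx²/fx + νy²/fy) on the DFT grid."""
    fx, fy = _as_pair(f)
    nu_y, nu_x = frequency_grid(shape)
    return np.pi * (nu_x**2 / fx + nu_y**2 / fy)


@dataclass(frozen=True)
class PropagationKernel:
    """Precomputed unitary Fresnel multiplier for one shape and distance."""

    f: FresnelPair
    shape: tuple[int, int]
    values: np.ndarray  # complex, |H| = 1, H[0, 0] = 1

    @classmethod
    def create(cls, shape: tuple[int, int], f) -> "PropagationKernel":
        f = _as_pair(f)
        chi = chirp(shape, f)
        # adjacent-frequency phase step > π means the discrete kernel is
        # aliased w.r.t. the continuous one; the discrete operator itself
        # stays unitary, so only warn
        ny, nx = shape
        step = np.pi * max(1.0 / (f.fx * nx), 1.0 / (f.fy * ny))
        if step > np.pi:
            warnings.warn(
                "Fresnel kernel is aliased at the highest frequencies "
                f"(max phase step {step:.2f} rad > pi); results are exact for "
                "the discrete periodic model only",
                RuntimeWarning,
                stacklevel=2,
            )
        return cls(f=f, shape=tuple(shape), values=np.exp(-1j * chi))


def fresnel_propagate(
    field: np.ndarray,
    f,
    direction: str = "forward",
    pad_factor: int = 1,
) -> np.ndarray:
    """Propagate a complex field by the discrete Fresnel propagator.

    Parameters
    ----------
    field : 2-D complex (or real) array, rows = y, columns = x.
    f : Fresnel number, scalar or ``(fx, fy)`` pair, referenced to one pixel.
    direction : ``"forward"`` (downstream) or ``"backward"`` (conjugate
        kernel; exact inverse of forward).
    pad_factor : symmetric zero-order padding factor (1 = none).  Padding
        moves the periodic wrap-around away from the frame for simulations
        of non-periodic scenes; the pad is cropped off again.

    The operator is unitary: energy Σ|ψ|² is conserved exactly, and
    forward followed by backward with the same ``f`` is the identity.
    """
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError(f"expected a 2-D field, got ndim={field.ndim}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError("pad_factor must be a positive integer")

    ny, nx = field.shape
    if pad_factor > 1:
        py = (pad_factor - 1) * ny // 2
        px = (pad_factor - 1) * nx // 2
        work = np.pad(field, ((py, py), (px, px)), mode="edge")
    else:
        py = px = 0
        work = field

    kern = PropagationKernel.create(work.shape, f).values
    if direction == "backward":
        kern = np.conj(kern)
    out = np.fft.ifft2(np.fft.fft2(work) * kern)
    if pad_factor > 1:
        out = out[py : py + ny, px : px + nx]
    if np.isrealobj(field):
        return out  # input promoted to complex; caller decides what to keep
    return out
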