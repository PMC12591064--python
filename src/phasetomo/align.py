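"""Trajectory alignment and sinogram stripe removal.

Real scans deviate from the ideal trajectory: the rotation axis is not
where the nominal geometry says (center-of-rotation error, small tilts),
and the sample drifts between projections.  This module estimates those
deviations — subpixel image registration, CoR from opposing projections or
sinogram halves, and iterative reprojection alignment — and writes them
into the :class:`~phasetomo.tomo.TomoGeometry` so reconstruction can
compensate them exactly instead of resampling images.

Angle-independent detector-column errors show up as stripes in sinograms
and as concentric rings in slices; additive (column-mean) and wavelet-FFT
stripe filters are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter, uniform_filter1d
from skimage.registration import phase_cross_correlation

from .tomo import ParallelProjector, TomoGeometry, fbp, forward_project

__all__ = [
    "RegistrationResult",
    "RegistrationError",
    "RingFilterParams",
    "register_translation",
    "find_cor_opposing",
    "find_cor_sinogram",
    "reprojection_align",
    "remove_rings_additive",
    "remove_rings_wavelet",
    "bin_image",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegistrationResult:
    """Subpixel shift (dv, du) mapping the moving image onto the reference:
    reference(x) ≈ moving(x − shift)."""

    shift: tuple[float, float]
    peak: float


@dataclass(frozen=True)
class RingFilterParams:
    """Wavelet-FFT stripe filter settings: decomposition depth ``levels``,
    Gaussian damping width ``sigma`` (in band-index units along the angle
    axis) and the wavelet family."""

    levels: int = 4
    sigma: float = 1.0
    wavelet: str = "db5"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def register_translation(a: np.ndarray, b: np.ndarray, upsample: int = 100) -> RegistrationResult:
    """Subpixel translation of ``b`` relative to ``a`` by upsampled DFT
    cross-correlation (integer peak, then local refinement by factor
    ``upsample``)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"images must share a shape, got {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise RegistrationError("cannot register a flat (zero-variance) image")
    shift, error, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample, normalization=None
    )
    return RegistrationResult(shift=(float(shift[0]), float(shift[1])), peak=1.0 - float(error))


def find_cor_opposing(p0: np.ndarray, p180: np.ndarray, upsample: int = 100) -> float:
    """Center-of-rotation offset from two projections separated by π.

    Mirroring the θ+π projection about the pixel-center column (N−1)/2
    turns the axis offset c into a relative shift of 2c, so
    ``cor = horizontal shift / 2`` (subpixel).
    """
    p0 = np.atleast_2d(np.asarray(p0, float))
    p180 = np.atleast_2d(np.asarray(p180, float))
    mirrored = p180[..., ::-1]
    res = register_translation(p0, mirrored, upsample=upsample)
    return res.shift[-1] / 2.0


def find_cor_sinogram(
    sinogram: np.ndarray, angles: np.ndarray, upsample: int = 100
) -> tuple[float, float]:
    """CoR (and axis tilt) from opposite segments of a sinogram.

    For scans spanning more than π the rows at θ and θ+π are mirror pairs;
    registering the two half-sinograms averages the CoR estimate over all
    angles, which is far more robust to per-projection jitter than a single
    opposing pair.  A 3-D input (rows, angles, columns) is processed per
    detector row and a least-squares line over the per-row CoRs gives the
    axis tilt (pixels of CoR per row ≈ radians for small tilt).

    Returns ``(cor_offset, tilt_slope)``; the slope is 0 for 2-D input.
    """
    angles = np.asarray(angles, float)
    span = angles.max() - angles.min()
    if span <= np.pi:
        raise ValueError(f"angular span must exceed pi, got {span:.3f}")
    sinogram = np.asarray(sinogram, float)
    if sinogram.ndim == 2:
        sinogram = sinogram[None]
    dtheta = np.median(np.diff(angles))
    k = int(round(np.pi / dtheta))
    cors = []
    for row in sinogram:
        s1 = row[: len(angles) - k]
        s2 = row[k:, ::-1]
        res = register_translation(s1, s2, upsample=upsample)
        cors.append(res.shift[-1] / 2.0)
    cors = np.asarray(cors)
    if cors.size == 1:
        return float(cors[0]), 0.0
    rows = np.arange(cors.size) - (cors.size - 1) / 2.0
    slope, intercept = np.polyfit(rows, cors, 1)
    return float(intercept), float(slope)


def bin_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean binning of the trailing two axes (crops any remainder)."""
    if factor == 1:
        return img
    ny, nx = img.shape[-2:]
    ny2, nx2 = ny // factor * factor, nx // factor * factor
    view = img[..., :ny2, :nx2]
    shape = view.shape[:-2] + (ny2 // factor, factor, nx2 // factor, factor)
    return view.reshape(shape).mean(axis=(-3, -1))


def _highpass(img: np.ndarray, sigma: float) -> np.ndarray:
    return img - gaussian_filter(img, sigma, mode="nearest")


def reprojection_align(
    projections: np.ndarray,
    g: TomoGeometry,
    iterations: int = 50,
    binning: int = 8,
    highpass_sigma: float | None = None,
    damping: float = 1.0,
    stop_update: float = 0.1,
    upsample: int = 20,
) -> tuple[TomoGeometry, np.ndarray]:
    """Iterative reprojection alignment of per-projection shifts.

    Each iteration reconstructs the volume under the current geometry,
    re-projects it, registers every reprojection against the corresponding
    measured image and updates that projection's shift by
    ``damping × detected shift``.  The work is done on ``binning``-fold
    block-binned, Gaussian-high-pass-filtered copies (σ defaults to
    40/binning px); detected shifts are scaled back by the binning factor.
    Stops early when the largest update falls below ``stop_update`` px.

    Returns the geometry with updated shifts and the per-iteration shift
    history, shape (iterations_run, n_proj, 2).
    """
    if iterations < 1 or binning < 1:
        raise ValueError("iterations and binning must be >= 1")
    if highpass_sigma is None:
        highpass_sigma = 40.0 / binning
    p = np.asarray(projections, float)
    is_2d = p.ndim == 2  # (angle, u) sinogram: vertical shifts meaningless
    if is_2d:
        p = p[:, None, :].repeat(2, axis=1)
    small = bin_image(p, binning)
    meas = np.stack([_highpass(im, highpass_sigma) for im in small])
    n_small = small.shape[-1]
    if small.shape[-2] != n_small:
        raise ValueError("projections must be square after binning")
    projector = ParallelProjector(n_small, g.angles)

    shifts = g.shifts.copy()
    history = []
    for _ in range(iterations):
        g_small = g.replace(
            shifts=shifts / binning, cor_offset=g.cor_offset / binning, tilt=g.tilt
        )
        vol = fbp(small, g_small, projector=projector)
        reproj = forward_project(vol, g_small, projector=projector)
        max_update = 0.0
        for i in range(g.n_proj):
            try:
                res = register_translation(meas[i], _highpass(reproj[i], highpass_sigma),
                                           upsample=upsample)
            except RegistrationError:
                warnings.warn(f"registration failed for projection {i}; update skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            # measured(x) ≈ reproj(x − shift) and reproj is rendered at the
            # current estimate, so the detected shift IS the residual error
            update = damping * binning * np.asarray(res.shift)
            shifts[i] += update
            max_update = max(max_update, float(np.abs(update).max()))
        history.append(shifts.copy())
        if max_update < stop_update:
            break
    return g.replace(shifts=shifts), np.asarray(history)


def remove_rings_additive(sinogram: np.ndarray, smooth_width: int = 31) -> np.ndarray:
    """Additive stripe removal: subtract the deviation of each column's
    angular mean from its moving average (width ``smooth_width``)."""
    if smooth_width < 3 or smooth_width % 2 == 0:
        raise ValueError("smooth_width must be odd and >= 3")
    sino = np.asarray(sinogram, float)
    col_mean = sino.mean(axis=-2, keepdims=True)
    smoothed = uniform_filter1d(col_mean, smooth_width, axis=-1, mode="nearest")
    return sino - (col_mean - smoothed)


def remove_rings_wavelet(
    sinogram: np.ndarray, params: RingFilterParams | None = None
) -> np.ndarray:
    """Wavelet-FFT stripe removal (combined wavelet / Fourier filtering).

    The sinogram (angle × column) is decomposed ``levels`` deep; in each
    level's band of vertical structures (detail coefficients varying along
    the column axis but smooth along the angle axis — where stripes
    concentrate) the DFT along the angle axis is damped by
    ``1 − exp(−k²/(2σ²))`` with k the integer frequency index of that band,
    suppressing angle-independent components while leaving genuine image
    features (which rotate, hence spread over k) nearly untouched.
    """
    params = params or RingFilterParams()
    sino = np.asarray(sinogram, float)
    if sino.ndim != 2:
        raise ValueError("expected a 2-D (angle, column) sinogram")
    ny, nx = sino.shape
    max_lev = pywt.dwtn_max_level((ny, nx), params.wavelet)
    if params.levels > max_lev:
        raise ValueError(
            f"sinogram {sino.shape} supports at most {max_lev} levels of "
            f"'{params.wavelet}', got {params.levels}"
        )
    coeffs = pywt.wavedec2(sino, params.wavelet, level=params.levels, mode="symmetric")
    new_coeffs = [coeffs[0]]
    for ch, cv, cd in coeffs[1:]:
        # cv: vertical-orientation detail band (stripes live here — pywt's
        # (LH) band: high-pass along columns, low-pass along angles)
        spec = np.fft.fft(cv, axis=0)
        k = np.fft.fftfreq(cv.shape[0]) * cv.shape[0]
        damp = 1.0 - np.exp(-(k**2) / (2.0 * params.sigma**2))
        spec *= damp[:, None]
        new_coeffs.append((ch, np.fft.ifft(spec, axis=0).real, cd))
    out = pywt.waverec2(new_coeffs, params.wavelet, mode="symmetric")
    return out[:ny, :nx]
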