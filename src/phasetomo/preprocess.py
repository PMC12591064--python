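"""Raw-frame conditioning: dark subtraction, empty-beam division, faulty
pixel repair and low-frequency background removal.

Raw frames R are modelled as R = dark + flat · signal; the chain
``(R − dark) / flat`` recovers the normalized hologram.  Because the
illumination drifts over a scan, the flat can be interpolated between
empty-beam images taken before and after the scan, or synthesized per
frame from a principal-component basis of the empty stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter, median_filter
from scipy.sparse.linalg import spsolve

__all__ = [
    "FlatFieldSet",
    "interpolate_flatfield",
    "pca_flatfield",
    "repair_faulty_pixels",
    "remove_background",
    "normalize",
]


@dataclass
class FlatFieldSet:
    """Darks plus empty-beam stacks bracketing a scan over [0, theta_max]."""

    darks: np.ndarray
    empties_before: np.ndarray
    empties_after: np.ndarray
    theta_max: float

    def __post_init__(self) -> None:
        self.darks = np.atleast_3d(np.asarray(self.darks, float))
        self.empties_before = np.atleast_3d(np.asarray(self.empties_before, float))
        self.empties_after = np.atleast_3d(np.asarray(self.empties_after, float))
        shapes = {a.shape[1:] for a in (self.darks, self.empties_before, self.empties_after)}
        if len(shapes) != 1:
            raise ValueError(f"dark/empty stacks have inconsistent detector shapes: {shapes}")
        if not self.theta_max > 0:
            raise ValueError("theta_max must be positive")

    @property
    def dark(self) -> np.ndarray:
        return self.darks.mean(axis=0)


def interpolate_flatfield(ffs: FlatFieldSet, theta: float) -> np.ndarray:
    """Flat for angle θ: convex combination of the mean before/after empties,

        e_θ = (1 − θ/θmax)·mean(before) + (θ/θmax)·mean(after).
    """
    if not 0.0 <= theta <= ffs.theta_max:
        raise ValueError(f"theta={theta} outside [0, {ffs.theta_max}]")
    w = theta / ffs.theta_max
    return (1.0 - w) * ffs.empties_before.mean(axis=0) + w * ffs.empties_after.mean(axis=0)


def pca_flatfield(
    empties: np.ndarray,
    raw: np.ndarray,
    fit_region: Optional[np.ndarray] = None,
    n_components: int = 2,
) -> np.ndarray:
    """Synthesize a per-frame flat from a principal-component basis.

    The centered empty stack is decomposed by SVD; the mean flat plus the
    leading ``n_components`` eigen-images form the basis.  Coefficients are
    fitted by least squares on ``fit_region`` (an object-free border mask;
    default: the whole frame), so illumination states not present in any
    single empty image can still be matched.

    ``n_components = 0`` reduces to classic division by the mean flat.
    """
    empties = np.atleast_3d(np.asarray(empties, float))
    raw = np.asarray(raw, float)
    n_emp = empties.shape[0]
    if n_components > max(n_emp - 1, 0):
        raise ValueError(
            f"n_components={n_components} needs at least {n_components + 1} empty images, got {n_emp}"
        )
    mean_flat = empties.mean(axis=0)
    if n_components == 0:
        return np.maximum(mean_flat, 1e-6)
    centered = (empties - mean_flat).reshape(n_emp, -1)
    # rows of vt are the eigen-flats (principal illumination modes)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    modes = vt[:n_components].reshape(n_components, *raw.shape)
    region = np.ones(raw.shape, bool) if fit_region is None else np.asarray(fit_region, bool)
    a = modes[:, region].T
    b = (raw - mean_flat)[region]
    coeff, *_ = np.linalg.lstsq(a, b, rcond=None)
    flat = mean_flat + np.tensordot(coeff, modes, axes=1)
    return np.maximum(flat, 1e-6)


def repair_faulty_pixels(
    image: np.ndarray, k: float = 6.0, size: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Detect and repair outlier (hot/dead) pixels.

    A pixel is flagged when its deviation from the local ``size×size``
    median exceeds ``k`` robust standard deviations (1.4826·MAD of the
    residual over the frame); flagged pixels are replaced by that median.
    Works on single images or stacks (frame-wise); returns
    ``(repaired, flagged_mask)``.  Idempotent on its own output.
    """
    image = np.asarray(image, float)
    if image.ndim == 3:
        out = np.empty_like(image)
        mask = np.empty(image.shape, bool)
        for i, frame in enumerate(image):
            out[i], mask[i] = repair_faulty_pixels(frame, k=k, size=size)
        return out, mask
    med = median_filter(image, size=size, mode="reflect")
    resid = image - med
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        flagged = resid != 0
    else:
        flagged = np.abs(resid) > k * sigma
    # the filter window is ill-defined on the 1-px border; never flag there
    flagged[0, :] = flagged[-1, :] = False
    flagged[:, 0] = flagged[:, -1] = False
    repaired = np.where(flagged, med, image)
    return repaired, flagged


def _biharmonic_inpaint(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace ``values`` inside ``mask`` by the least-curvature (biharmonic)
    extension of the outside data: minimize Σ(Δu)² with u fixed outside."""
    ny, nx = values.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    # 5-point Laplacian; missing neighbours at the frame edge are dropped
    count = np.zeros((ny, nx))
    data = []
    rows = []
    cols = []
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ys = slice(max(dy, 0), ny + min(dy, 0))
        xs = slice(max(dx, 0), nx + min(dx, 0))
        ys_n = slice(max(-dy, 0), ny + min(-dy, 0))
        xs_n = slice(max(-dx, 0), nx + min(-dx, 0))
        rows.append(idx[ys, xs].ravel())
        cols.append(idx[ys_n, xs_n].ravel())
        data.append(np.ones(idx[ys, xs].size))
        count[ys, xs] += 1.0
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    data.append(-count.ravel())
    lap = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    bih = (lap.T @ lap).tocsr()
    inside = mask.ravel()
    a_ii = bih[inside][:, inside]
    a_ib = bih[inside][:, ~inside]
    rhs = -a_ib @ values.ravel()[~inside]
    u = values.ravel().copy()
    u[inside] = spsolve(a_ii.tocsc(), rhs)
    return u.reshape(ny, nx)


def remove_background(
    hologram: np.ndarray,
    object_mask: Optional[np.ndarray] = None,
    boundary_sigma: float = 5.0,
) -> np.ndarray:
    """Suppress residual low-frequency background by least-curvature inpainting.

    The background estimate equals a Gaussian-smoothed (σ = ``boundary_sigma``)
    copy of the hologram outside the object support and its biharmonic
    (least-curvature) continuation inside; the hologram is divided by it.
    With an empty mask this degenerates to division by the smoothed
    hologram, i.e. a gentle high-pass.
    """
    hologram = np.asarray(hologram, float)
    smooth = gaussian_filter(hologram, boundary_sigma, mode="nearest")
    if object_mask is None or not np.any(object_mask):
        return hologram / np.maximum(smooth, 1e-6)
    object_mask = np.asarray(object_mask, bool)
    if object_mask.shape != hologram.shape:
        raise ValueError("object_mask shape must match the hologram")
    if object_mask[0, :].any() or object_mask[-1, :].any() \
            or object_mask[:, 0].any() or object_mask[:, -1].any():
        raise ValueError("object_mask must lie strictly inside the frame")
    if object_mask.all():
        raise ValueError("object_mask covers the full frame; no background to fit")
    background = _biharmonic_inpaint(smooth, object_mask)
    return hologram / np.maximum(background, 1e-6)


def normalize(
    raw: np.ndarray,
    dark: np.ndarray,
    flat: np.ndarray,
) -> np.ndarray:
    """Dark-subtract and flat-divide a raw frame: (raw − dark)/(flat − dark)."""
    flat_c = np.asarray(flat, float) - dark
    flat_c = np.maximum(flat_c, 1e-6 * max(float(np.median(np.abs(flat_c))), 1e-30))
    return (np.asarray(raw, float) - dark) / flat_c
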