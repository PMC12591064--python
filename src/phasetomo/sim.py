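"""Synthetic data generation: digital phantoms and hologram simulation.

Everything the rest of the toolbox needs for testing and demonstration is
generated here from first principles: ellipsoid/ball phantoms, projection
to phase maps, Fresnel propagation to per-distance holograms with Poisson
noise, and per-projection trajectory jitter — with the injected ground
truth (phase maps, shifts, CoR) returned alongside, so retrieval,
alignment and reconstruction can be scored against known answers without
any external data.

Phantoms are rasterized by supersampled area sampling (each voxel stores
the volume fraction covered), which makes values resolution-independent
and keeps projections consistent under grid refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tomo import TomoGeometry, forward_project
from .wave import _as_pair, fresnel_propagate

__all__ = [
    "Phantom",
    "SimulationRecipe",
    "shepp_logan_3d",
    "ball_phantom",
    "disk_projection",
    "simulate_hologram",
    "simulate_holograms",
    "SimulatedScan",
]

# 3-D Shepp–Logan ellipsoid table (Kak–Slaney style, contrast-enhanced
# values): (x0, y0, z0, a, b, c, rotation about z in deg, additive value),
# coordinates in units of the half-width.
_SHEPP_LOGAN_3D = [
    (0.0, 0.0, 0.0, 0.69, 0.92, 0.81, 0.0, 1.0),
    (0.0, -0.0184, 0.0, 0.6624, 0.874, 0.78, 0.0, -0.8),
    (0.22, 0.0, 0.0, 0.11, 0.31, 0.22, -18.0, -0.2),
    (-0.22, 0.0, 0.0, 0.16, 0.41, 0.28, 18.0, -0.2),
    (0.0, 0.35, -0.15, 0.21, 0.25, 0.41, 0.0, 0.1),
    (0.0, 0.1, 0.25, 0.046, 0.046, 0.05, 0.0, 0.1),
    (0.0, -0.1, 0.25, 0.046, 0.046, 0.05, 0.0, 0.1),
    (-0.08, -0.605, 0.0, 0.046, 0.023, 0.05, 0.0, 0.1),
    (0.0, -0.605, 0.0, 0.023, 0.023, 0.02, 0.0, 0.1),
    (0.06, -0.605, 0.0, 0.023, 0.046, 0.02, 0.0, 0.1),
]


@dataclass
class Phantom:
    """Digital phantom: a non-negative refractive-decrement proxy volume."""

    delta_volume: np.ndarray  # (z, y, x), values in [0, 1] for the stock phantoms
    b_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        self.delta_volume = np.asarray(self.delta_volume, float)
        if np.any(self.delta_volume < 0):
            raise ValueError("phantom values must be non-negative")


@dataclass
class SimulationRecipe:
    """Conditions of a simulated holographic scan.

    ``fresnel`` lists one Fresnel number (pair) per defocus distance;
    ``phi_max`` sets the peak phase shift |φ| the projections are scaled
    to; ``photon_count`` is the Poisson scale per pixel (None = noiseless);
    ``jitter_amplitude`` bounds the uniform per-projection shifts.
    """

    fresnel: Sequence = (2.44e-4, 1.98e-4)
    b_ratio: float = 0.035
    phi_max: float = 0.1
    photon_count: Optional[float] = 1e4
    jitter_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.fresnel = [_as_pair(f) for f in self.fresnel]
        if self.photon_count is not None and not self.photon_count > 0:
            raise ValueError("photon_count must be positive or None")
        if self.jitter_amplitude < 0:
            raise ValueError("jitter_amplitude must be non-negative")
        if not self.phi_max >= 0:
            raise ValueError("phi_max must be non-negative")


def _supersampled_ellipsoids(n: int, table, supersample: int = 2) -> np.ndarray:
    s = supersample
    m = n * s
    ax = (np.arange(m) + 0.5) / m * 2.0 - 1.0
    # (z, y, x) with y increasing upward in the table's convention
    y = -ax[None, :, None]
    x = ax[None, None, :]
    out = np.empty((n, n, n))
    # rasterize in z-slabs to keep the supersampled memory footprint small
    for iz in range(n):
        z = ax[iz * s:(iz + 1) * s][:, None, None]
        slab = np.zeros((s, m, m), dtype=np.float32)
        for x0, y0, z0, a, b, c, ang, val in table:
            if np.min(np.abs(z - z0)) > c:
                continue
            t = np.deg2rad(ang)
            xr = (x - x0) * np.cos(t) + (y - y0) * np.sin(t)
            yr = -(x - x0) * np.sin(t) + (y - y0) * np.cos(t)
            slab += np.float32(val) * (
                (xr / a) ** 2 + (yr / b) ** 2 + ((z - z0) / c) ** 2 <= 1.0
            )
        out[iz] = slab.reshape(s, n, s, n, s).mean(axis=(0, 2, 4))
    return np.clip(out, 0.0, None)


def shepp_logan_3d(n: int, supersample: int = 2) -> Phantom:
    """Contrast-enhanced 3-D Shepp–Logan head phantom, values in [0, 1].

    Rasterized by ``supersample``-fold area sampling so edge voxels carry
    partial-volume values and the model is resolution-independent.
    """
    if n < 16:
        raise ValueError("n must be at least 16")
    return Phantom(_supersampled_ellipsoids(n, _SHEPP_LOGAN_3D, supersample))


def ball_phantom(n: int, radius: float, value: float = 1.0, center=None,
                 supersample: int = 2) -> Phantom:
    """Uniform ball; its projection has the closed form value·2√(R²−r²)."""
    if radius == 0:
        return Phantom(np.zeros((n, n, n)))
    m = n * supersample
    c = np.asarray(center if center is not None else ((n - 1) / 2.0,) * 3, float)
    ax = (np.arange(m) + 0.5) / supersample - 0.5  # voxel-centre coordinates
    z = ax[:, None, None]
    y = ax[None, :, None]
    x = ax[None, None, :]
    inside = (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= radius**2
    vol = value * inside.astype(np.float32)
    s = supersample
    vol = vol.reshape(n, s, n, s, n, s).mean(axis=(1, 3, 5))
    return Phantom(vol.astype(float))


def disk_projection(n: int, radius: float, value: float = 1.0, center=None,
                    supersample: int = 4) -> np.ndarray:
    """Analytic parallel projection of a uniform ball: value·2√(R²−r²)."""
    c = np.asarray(center if center is not None else ((n - 1) / 2.0,) * 2, float)
    s = supersample
    ax = (np.arange(n * s) + 0.5) / s - 0.5
    y = ax[:, None]
    x = ax[None, :]
    r2 = (y - c[0]) ** 2 + (x - c[1]) ** 2
    proj = value * 2.0 * np.sqrt(np.maximum(radius**2 - r2, 0.0))
    return proj.reshape(n, s, n, s).mean(axis=(1, 3))


def simulate_hologram(
    phi: np.ndarray,
    fresnel,
    b_ratio: float = 0.0,
    photon_count: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    pad_factor: int = 1,
) -> np.ndarray:
    """Hologram of one phase map at one distance.

    Forward chain: transmission exp((B+i)φ) → Fresnel propagation →
    squared modulus → optional Poisson noise at ``photon_count`` photons
    per pixel (renormalized back to mean level 1).
    """
    phi = np.asarray(phi, float)
    psi = fresnel_propagate(np.exp((b_ratio + 1j) * phi), fresnel, "forward",
                            pad_factor=pad_factor)
    intensity = np.abs(psi) ** 2
    if photon_count is not None:
        rng = rng or np.random.default_rng(0)
        intensity = rng.poisson(np.maximum(intensity, 0.0) * photon_count) / photon_count
        intensity = np.maximum(intensity, 1.0 / photon_count)  # keep > 0
    return intensity


@dataclass
class SimulatedScan:
    """Output bundle of :func:`simulate_holograms` with the ground truth."""

    holograms: np.ndarray  # (D, n_proj, ny, nx)
    phase: np.ndarray  # (n_proj, ny, nx) jitter-free ground-truth phase maps
    shifts: np.ndarray  # (n_proj, 2) injected jitter (dv, du)
    geometry: TomoGeometry  # trajectory the holograms were recorded on
    recipe: SimulationRecipe = field(repr=False, default=None)


def simulate_holograms(
    phantom,
    recipe: SimulationRecipe,
    g: TomoGeometry,
) -> SimulatedScan:
    """Simulate a holographic tomography scan of a phantom.

    The δ-volume is projected along the trajectory (including injected
    jitter), scaled so the peak |φ| equals ``recipe.phi_max`` and given the
    non-positive sign convention; each projection's transmission is
    propagated to every distance.  All randomness (jitter, Poisson noise)
    derives from ``recipe.seed``; equal seeds give bit-identical scans.
    """
    rng = np.random.default_rng(recipe.seed)
    vol = phantom.delta_volume if isinstance(phantom, Phantom) else np.asarray(phantom, float)

    if recipe.jitter_amplitude > 0:
        jitter = rng.uniform(-recipe.jitter_amplitude, recipe.jitter_amplitude,
                             (g.n_proj, 2))
    else:
        jitter = np.zeros((g.n_proj, 2))
    g_true = g.replace(shifts=g.shifts + jitter)

    if vol.ndim == 3:
        proj_ideal = forward_project(vol, g)  # jitter-free truth
        proj_jit = forward_project(vol, g_true)
    else:  # pre-projected phase maps (n_proj, ny, nx)
        proj_ideal = proj_jit = np.asarray(vol, float)

    peak = np.abs(proj_ideal).max()
    scale = recipe.phi_max / peak if peak > 0 else 0.0
    phase_true = -scale * proj_ideal
    phase_jit = -scale * proj_jit

    d = len(recipe.fresnel)
    holos = np.empty((d, g.n_proj) + phase_jit.shape[-2:])
    for j, f in enumerate(recipe.fresnel):
        for i in range(g.n_proj):
            holos[j, i] = simulate_hologram(
                phase_jit[i], f, recipe.b_ratio, recipe.photon_count, rng
            )
    return SimulatedScan(
        holograms=holos, phase=phase_true, shifts=jitter, geometry=g_true, recipe=recipe
    )
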