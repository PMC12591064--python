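"""Cone-beam acquisition geometry and derived scalar quantities.

Near-field imaging with a divergent (point-source) beam at source–sample
distance ``z01`` and source–detector distance ``z02`` is equivalent, by the
Fresnel scaling theorem, to a parallel-beam setup with demagnified pixel
``Δx/M`` and effective propagation distance ``z01·z12/z02``, where
``M = z02/z01`` and ``z12 = z02 − z01``.  All downstream modules work in
that effective parallel geometry and express frequencies in cycles per
pixel, so the only physical quantity they need is the dimensionless Fresnel
number ``F = Δx_eff² / (z_eff · λ)`` per image (and per axis, when the
magnification is anisotropic).

Constructors accept the units experimentalists quote (mm, µm, keV) and
convert once; everything returned is SI (metres) or dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "HC_KEV_M",
    "ConeBeamGeometry",
    "FresnelPair",
    "wavelength",
    "magnification",
    "effective_pixel",
    "effective_distance",
    "fresnel_number",
    "rescale_fresnel",
]

#: hc in keV·m (12.3984193 keV·Å), the conversion between photon energy and
#: wavelength: λ = HC_KEV_M / E.
HC_KEV_M: float = 12.3984193e-10


def wavelength(energy_kev: float) -> float:
    """X-ray wavelength in metres for a photon energy in keV."""
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_M / energy_kev


class FresnelPair(NamedTuple):
    """Per-axis Fresnel numbers (horizontal ``fx``, vertical ``fy``).

    Astigmatic setups (e.g. anisotropic magnification) have ``fx != fy``;
    the isotropic case simply repeats the value.
    """

    fx: float
    fy: float

    @classmethod
    def isotropic(cls, f: float) -> "FresnelPair":
        return cls(float(f), float(f))

    def validate(self) -> "FresnelPair":
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"Fresnel numbers must be positive, got {self}")
        return self


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Physical cone-beam geometry.

    Parameters
    ----------
    z01_mm : source→sample distance in mm.
    z02_mm : source→detector distance in mm.
    det_pixel_um : physical detector pixel size in µm.
    energy_kev : photon energy in keV.
    """

    z01_mm: float
    z02_mm: float
    det_pixel_um: float
    energy_kev: float

    def __post_init__(self) -> None:
        if not 0 < self.z01_mm < self.z02_mm:
            raise ValueError(
                f"need 0 < z01 < z02, got z01={self.z01_mm} mm, z02={self.z02_mm} mm"
            )
        if not self.det_pixel_um > 0:
            raise ValueError(f"detector pixel must be positive, got {self.det_pixel_um}")
        if not self.energy_kev > 0:
            raise ValueError(f"photon energy must be positive, got {self.energy_kev}")

    # -- SI accessors -----------------------------------------------------
    @property
    def z01(self) -> float:
        """Source→sample distance in m."""
        return self.z01_mm * 1e-3

    @property
    def z02(self) -> float:
        """Source→detector distance in m."""
        return self.z02_mm * 1e-3

    @property
    def z12(self) -> float:
        """Sample→detector distance in m."""
        return self.z02 - self.z01

    @property
    def det_pixel(self) -> float:
        """Physical detector pixel in m."""
        return self.det_pixel_um * 1e-6

    @property
    def wavelength(self) -> float:
        return wavelength(self.energy_kev)

    # -- derived quantities ----------------------------------------------
    @property
    def magnification(self) -> float:
        return magnification(self)

    @property
    def effective_pixel(self) -> float:
        return effective_pixel(self)

    @property
    def effective_distance(self) -> float:
        return effective_distance(self)

    @property
    def fresnel_number(self) -> float:
        """Fresnel number w.r.t. the effective pixel size (isotropic)."""
        return fresnel_number(self.effective_pixel, self.effective_distance, self.wavelength)

    def fresnel_pair(self) -> FresnelPair:
        return FresnelPair.isotropic(self.fresnel_number)


def magnification(g: ConeBeamGeometry) -> float:
    """Geometric magnification M = z02/z01 (> 1 for z01 < z02)."""
    return g.z02 / g.z01


def effective_pixel(g: ConeBeamGeometry) -> float:
    """Demagnified (effective) pixel size Δx/M in m."""
    return g.det_pixel / magnification(g)


def effective_distance(g: ConeBeamGeometry) -> float:
    """Effective parallel-beam propagation distance z01·z12/z02 in m."""
    return g.z01 * g.z12 / g.z02


def fresnel_number(pixel: float, distance: float, lam: float) -> float:
    """Dimensionless Fresnel number F = pixel² / (distance · λ).

    The reference length scale is one (effective) pixel, so retrieval
    filters can express all spatial frequencies in cycles/pixel.
    """
    if not (pixel > 0 and distance > 0 and lam > 0):
        raise ValueError(
            f"pixel, distance and wavelength must be positive, got "
            f"({pixel}, {distance}, {lam})"
        )
    return pixel * pixel / (distance * lam)


def rescale_fresnel(f: FresnelPair, pixel_old: float, pixel_new: float) -> FresnelPair:
    """Fresnel numbers after resampling an image to a new pixel size.

    Rescaling a hologram recorded with pixel ``pixel_old`` onto a grid with
    pixel ``pixel_new`` (e.g. to bring multi-distance stacks onto the common
    effective pixel of the first distance) multiplies each per-axis Fresnel
    number by ``(pixel_new / pixel_old)²`` — F is quadratic in the reference
    length while distance and wavelength are untouched.
    """
    f = FresnelPair(*f).validate()
    if not (pixel_old > 0 and pixel_new > 0):
        raise ValueError("pixel sizes must be positive")
    s = (pixel_new / pixel_old) ** 2
    return FresnelPair(f.fx * s, f.fy * s)
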