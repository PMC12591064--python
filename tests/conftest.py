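import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from phasetomo.geometry import ConeBeamGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry_first():
    """First defocus distance of the reference nano-holotomography setup."""
    return ConeBeamGeometry(z01_mm=13.53, z02_mm=5110.0, det_pixel_um=6.5, energy_kev=13.8)


@pytest.fixture
def geometry_second():
    """Second defocus distance (same source-detector distance)."""
    return ConeBeamGeometry(z01_mm=16.73, z02_mm=5110.0, det_pixel_um=6.5, energy_kev=13.8)


def smooth_phase(n: int, sigma: float, peak: float, seed: int = 0) -> np.ndarray:
    """Smooth non-positive test phase map with max |phi| = peak."""
    r = np.random.default_rng(seed)
    x = gaussian_filter(r.standard_normal((n, n)), sigma)
    return -peak * (x - x.min()) / (x.max() - x.min())


@pytest.fixture
def smooth_phi():
    return smooth_phase


def rel_l2(a: np.ndarray, b: np.ndarray) -> float:
    """Relative L2 error of a against reference b."""
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
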