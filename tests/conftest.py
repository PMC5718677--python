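import math

import numpy as np
import pytest

import petthresh as pt
from petthresh.phantom import ImageVolume


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless IEC-like acquisition at prepared ratio 8.1, 8 mm smoothing."""
    spec = pt.default_iec_spec(8.1, smoothing_fwhm=8.0, noise_sd_fraction=0.0, seed=0)
    volume, truth = pt.simulate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise acquisition at prepared ratio 8.1."""
    spec = pt.default_iec_spec(8.1, smoothing_fwhm=8.0, seed=0)
    volume, truth = pt.simulate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def background_pattern(noiseless_phantom):
    spec, volume, truth = noiseless_phantom
    return pt.nema_background_pattern(volume, truth, truth.central_slice(0))


@pytest.fixture(scope="session")
def published():
    return pt.published_models()


def gaussian_blob_volume(
    sigma_mm: float = 4.0,
    peak: float = 100.0,
    size: int = 81,
    spacing: float = 1.0,
    n_slices: int = 3,
    background: float = 0.0,
) -> ImageVolume:
    """Analytic 2D Gaussian blob replicated over a few slices (1 mm grid)."""
    c = (size * spacing) / 2.0
    x = (np.arange(size) + 0.5) * spacing
    g = np.exp(-((x - c) ** 2) / (2.0 * sigma_mm**2))
    sl = background + peak * np.outer(g, g)
    values = np.repeat(sl[:, :, None], n_slices, axis=2)
    return ImageVolume(values, (spacing, spacing, 2.0))


def binary_disk_volume(
    radius_mm: float = 10.0,
    value: float = 10.0,
    size: int = 61,
    spacing: float = 1.0,
    n_slices: int = 1,
) -> ImageVolume:
    c = (size * spacing) / 2.0
    x = (np.arange(size) + 0.5) * spacing
    d2 = (x[:, None] - c) ** 2 + (x[None, :] - c) ** 2
    sl = np.where(d2 <= radius_mm**2, value, 0.0)
    values = np.repeat(sl[:, :, None], n_slices, axis=2)
    return ImageVolume(values, (spacing, spacing, 2.0))


def center_roi(volume: ImageVolume, diameter: float, slice_index: int = 0) -> pt.SliceROI:
    ext_x = volume.shape[0] * volume.voxel_spacing[0]
    ext_y = volume.shape[1] * volume.voxel_spacing[1]
    return pt.SliceROI((ext_x / 2.0, ext_y / 2.0), diameter, slice_index)


def gaussian_iso_area_mm2(sigma_mm: float, ts_percent: float) -> float:
    """Closed-form iso-contour area of a Gaussian blob: pi * r^2 with
    r^2 = 2 sigma^2 ln(100/ts)."""
    return math.pi * 2.0 * sigma_mm**2 * math.log(100.0 / ts_percent)
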