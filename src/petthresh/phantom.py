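"""Digital sphere-in-background phantom simulation.

Emulates a modified IEC body phantom imaged on a clinical PET scanner:
fillable spheres of known internal diameter in a warm background, rendered
on a voxel grid with analytic partial-volume handling, then degraded by a
Gaussian point-spread/smoothing kernel and additive noise standing in for
the reconstructed-image noise of an iterative (OSEM) reconstruction.

Axis convention: arrays are indexed ``values[ix, iy, iz]`` with axial slices
along the last axis; world coordinates follow the voxel-center convention
``origin + (index + 0.5) * spacing`` (all mm).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

__all__ = [
    "Sphere",
    "PhantomSpec",
    "ImageVolume",
    "GroundTruth",
    "GeometryError",
    "default_iec_spec",
    "render_activity_map",
    "simulate_reconstruction",
    "simulate_phantom",
    "generate_threshold_dataset",
]


class GeometryError(ValueError):
    """Sphere/grid geometry violates the phantom's construction rules."""


@dataclass(frozen=True)
class Sphere:
    """A fillable sphere: center in mm (world), internal diameter in mm,
    and the activity concentration of its fill (kBq/ml)."""

    center: tuple[float, float, float]
    internal_diameter: float
    activity: float

    @property
    def radius(self) -> float:
        return self.internal_diameter / 2.0

    @property
    def true_volume_ml(self) -> float:
        """Sphere volume in ml (mm^3 / 1000)."""
        return math.pi / 6.0 * self.internal_diameter**3 / 1000.0


@dataclass(frozen=True)
class ImageVolume:
    """3D activity map with voxel spacing metadata (mm)."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("ImageVolume values must be finite")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz

    def slice_z_mm(self, slice_index: int) -> float:
        """World z coordinate of an axial slice's plane (voxel centers)."""
        return self.origin[2] + (slice_index + 0.5) * self.voxel_spacing[2]

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_spacing[axis]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one simulated acquisition.

    ``system_psf`` is (transverse FWHM, axial FWHM) in mm; ``smoothing_fwhm``
    is the post-reconstruction Gaussian filter width, combined with the PSF
    in quadrature per axis.  ``iteration_label`` carries the EM-equivalent
    iteration count of the emulated reconstruction; it is metadata unless
    ``noise_iteration_slope`` is nonzero, in which case the noise standard
    deviation is scaled by ``1 + slope * (iterations / 16 - 1)`` so that
    higher iteration numbers yield noisier images.
    """

    background_activity: float = 5.4
    spheres: tuple[Sphere, ...] = ()
    voxel_spacing: tuple[float, float, float] = (2.6, 2.6, 2.0)
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    system_psf: tuple[float, float] = (4.6, 5.1)
    smoothing_fwhm: float = 8.0
    iteration_label: int = 16
    noise_sd_fraction: float = 0.05
    noise_iteration_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_activity <= 0:
            raise ValueError("background_activity must be > 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if self.smoothing_fwhm < 0 or any(f < 0 for f in self.system_psf):
            raise ValueError("FWHM values must be non-negative")
        for sph in self.spheres:
            if sph.internal_diameter <= 0:
                raise GeometryError("sphere diameters must be > 0")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    def noise_sd(self) -> float:
        """Absolute noise sd: fraction of background, optionally scaled by
        the EM-equivalent iteration count (16 iterations = unit factor)."""
        factor = 1.0 + self.noise_iteration_slope * (self.iteration_label / 16.0 - 1.0)
        return self.noise_sd_fraction * self.background_activity * max(factor, 0.0)

    def validate_geometry(self) -> None:
        extent = self.extent_mm
        for sph in self.spheres:
            for ax in range(3):
                if sph.center[ax] - sph.radius < 0 or sph.center[ax] + sph.radius > extent[ax]:
                    raise GeometryError(
                        f"sphere d={sph.internal_diameter} mm at {sph.center} "
                        f"extends outside the grid (extent {extent})"
                    )
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                gap = math.dist(a.center, b.center)
                if gap < a.radius + b.radius:
                    raise GeometryError(
                        f"spheres d={a.internal_diameter} and d={b.internal_diameter} overlap"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry of the rendered phantom.

    ``slice_areas_mm2[i]`` holds the analytic cross-sectional area of sphere
    ``i`` on every axial slice (pi * (r^2 - dz^2) at slice-center offset dz);
    ``label_mask`` labels voxels by the sphere containing their center
    (0 = background, i+1 = sphere i).
    """

    spheres: tuple[Sphere, ...]
    slice_areas_mm2: np.ndarray  # (n_spheres, n_slices)
    label_mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def central_slice(self, sphere_index: int) -> int:
        """Index of the axial slice whose plane is nearest the sphere center."""
        sph = self.spheres[sphere_index]
        nz = self.label_mask.shape[2]
        z_centers = self.origin[2] + (np.arange(nz) + 0.5) * self.voxel_spacing[2]
        return int(np.argmin(np.abs(z_centers - sph.center[2])))

    def central_area_mm2(self, sphere_index: int) -> float:
        """Largest (equatorial) cross-section: pi * (d/2)^2."""
        return math.pi * self.spheres[sphere_index].radius ** 2

    def slice_area_mm2(self, sphere_index: int, slice_index: int) -> float:
        return float(self.slice_areas_mm2[sphere_index, slice_index])


# ---------------------------------------------------------------------------
# default phantom geometry


#: Internal diameters (mm) of the six fillable IEC spheres.
IEC_SPHERE_DIAMETERS = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
#: Internal diameters (mm) of the supplemental micro-sphere set.
MICRO_SPHERE_DIAMETERS = (4.1, 4.7, 6.5, 8.1)


def default_iec_spec(
    tb_ratio: float = 8.1,
    *,
    smoothing_fwhm: float = 8.0,
    iteration_label: int = 16,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
    sphere_diameters: tuple[float, ...] = IEC_SPHERE_DIAMETERS,
    include_micro_spheres: bool = False,
    ring_radius: float = 45.0,
) -> PhantomSpec:
    """IEC-like phantom: spheres on a ring in the central axial plane.

    ``tb_ratio`` is the prepared source-to-background activity ratio; the
    background is filled at 5.4 kBq/ml.  Spheres sit on a ``ring_radius`` mm
    circle about the grid center, evenly spaced in angle, in the central
    axial plane.  The optional micro-sphere set goes on an inner 20 mm ring
    rotated to sit between the main spheres.
    """
    background = 5.4
    spec = PhantomSpec(
        background_activity=background,
        smoothing_fwhm=smoothing_fwhm,
        iteration_label=iteration_label,
        noise_sd_fraction=noise_sd_fraction,
        seed=seed,
    )
    cx, cy, cz = (e / 2.0 for e in spec.extent_mm)
    spheres = []
    n = len(sphere_diameters)
    for k, d in enumerate(sphere_diameters):
        ang = 2.0 * math.pi * k / n
        spheres.append(
            Sphere(
                center=(cx + ring_radius * math.cos(ang), cy + ring_radius * math.sin(ang), cz),
                internal_diameter=d,
                activity=tb_ratio * background,
            )
        )
    if include_micro_spheres:
        m = len(MICRO_SPHERE_DIAMETERS)
        for k, d in enumerate(MICRO_SPHERE_DIAMETERS):
            ang = 2.0 * math.pi * (k + 0.5) / m
            spheres.append(
                Sphere(
                    center=(cx + 20.0 * math.cos(ang), cy + 20.0 * math.sin(ang), cz),
                    internal_diameter=d,
                    activity=tb_ratio * background,
                )
            )
    spec = dataclasses.replace(spec, spheres=tuple(spheres))
    spec.validate_geometry()
    return spec


# ---------------------------------------------------------------------------
# rendering


def _sphere_slice_areas(spec: PhantomSpec) -> np.ndarray:
    nz = spec.grid_shape[2]
    z_centers = (np.arange(nz) + 0.5) * spec.voxel_spacing[2]
    areas = np.zeros((len(spec.spheres), nz))
    for i, sph in enumerate(spec.spheres):
        dz = z_centers - sph.center[2]
        r2 = sph.radius**2 - dz**2
        areas[i] = np.where(r2 > 0, math.pi * r2, 0.0)
    return areas


def render_activity_map(
    spec: PhantomSpec, *, supersampling: int = 8, with_truth: bool = True
) -> tuple[ImageVolume, GroundTruth] | ImageVolume:
    """Render the noiseless, unblurred activity map.

    Interior voxels carry the source activity exactly; voxels straddling a
    sphere surface carry the volume-weighted mixture of sphere and
    background activity, estimated by ``supersampling``^3 subvoxel sampling.
    Returns ``(ImageVolume, GroundTruth)`` unless ``with_truth=False``.
    """
    spec.validate_geometry()
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    nx, ny, nz = spec.grid_shape
    spacing = np.asarray(spec.voxel_spacing)
    values = np.full(spec.grid_shape, spec.background_activity, dtype=float)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    half_diag = float(np.linalg.norm(spacing / 2.0))

    # subvoxel center offsets within one voxel, in mm
    s = supersampling
    off = (np.arange(s) + 0.5) / s  # fractions of a voxel
    sub = np.stack(np.meshgrid(off, off, off, indexing="ij"), axis=-1).reshape(-1, 3)
    sub_mm = sub * spacing  # (s^3, 3)

    centers = [
        (np.arange(n) + 0.5) * sp + o
        for n, sp, o in zip(spec.grid_shape, spec.voxel_spacing, (0.0, 0.0, 0.0))
    ]

    for si, sph in enumerate(spec.spheres):
        r = sph.radius
        lo = [
            max(0, int((sph.center[ax] - r) / spec.voxel_spacing[ax]) - 1) for ax in range(3)
        ]
        hi = [
            min(spec.grid_shape[ax], int((sph.center[ax] + r) / spec.voxel_spacing[ax]) + 2)
            for ax in range(3)
        ]
        cx = [centers[ax][lo[ax] : hi[ax]] - sph.center[ax] for ax in range(3)]
        d2 = (
            cx[0][:, None, None] ** 2 + cx[1][None, :, None] ** 2 + cx[2][None, None, :] ** 2
        )
        dist = np.sqrt(d2)
        inside = dist <= r - half_diag
        boundary = (dist > r - half_diag) & (dist < r + half_diag)
        block = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        block[inside] = sph.activity
        # supersample boundary voxels only
        bidx = np.argwhere(boundary)
        if bidx.size:
            corners = (bidx + lo) * spacing  # voxel lower corners in mm
            pts = corners[:, None, :] + sub_mm[None, :, :]  # (nb, s^3, 3)
            pd2 = np.sum((pts - np.asarray(sph.center)) ** 2, axis=-1)
            frac = np.mean(pd2 <= r * r, axis=1)
            block[tuple(bidx.T)] = spec.background_activity + frac * (
                sph.activity - spec.background_activity
            )
        center_inside = dist <= r
        labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][center_inside] = si + 1

    volume = ImageVolume(values, spec.voxel_spacing)
    if not with_truth:
        return volume
    truth = GroundTruth(
        spheres=spec.spheres,
        slice_areas_mm2=_sphere_slice_areas(spec),
        label_mask=labels,
        voxel_spacing=spec.voxel_spacing,
    )
    return volume, truth


def simulate_reconstruction(volume: ImageVolume, spec: PhantomSpec) -> ImageVolume:
    """Degrade a rendered map the way reconstruction + post-filtering would.

    The map is convolved with an anisotropic Gaussian: in-plane the FWHM
    combines the transverse system PSF with the post-reconstruction
    smoothing in quadrature; axially the resolution is set by the axial
    system PSF alone (the smoothing filter acts transaxially, so axial
    contrast gradients — which slice-specific thresholding exploits —
    remain governed by the scanner's axial resolution).  Zero-mean Gaussian
    noise of sd ``spec.noise_sd()`` is then added (seeded) and negative
    values are clamped to zero: reconstructed activity is non-negative.
    """
    if spec.smoothing_fwhm < 0 or any(f < 0 for f in spec.system_psf):
        raise ValueError("FWHM values must be non-negative")
    tr, ax = spec.system_psf
    fwhm = np.array(
        [
            math.hypot(tr, spec.smoothing_fwhm),
            math.hypot(tr, spec.smoothing_fwhm),
            ax,
        ]
    )
    sigma_vox = fwhm * FWHM_TO_SIGMA / np.asarray(volume.voxel_spacing)
    values = ndimage.gaussian_filter(volume.values, sigma=sigma_vox, mode="nearest")
    sd = spec.noise_sd()
    if sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    return ImageVolume(values, volume.voxel_spacing, volume.origin)


def simulate_phantom(
    spec: PhantomSpec, *, supersampling: int = 8
) -> tuple[ImageVolume, GroundTruth]:
    """Render and reconstruct in one step."""
    rendered, truth = render_activity_map(spec, supersampling=supersampling)
    return simulate_reconstruction(rendered, spec), truth


def ground_truth_for(
    spheres: tuple[Sphere, ...],
    voxel_spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> GroundTruth:
    """Reconstruct the analytic ground truth for a sphere set on a grid
    (used when a truth sidecar is loaded from disk)."""
    spec = PhantomSpec(
        spheres=tuple(spheres), voxel_spacing=voxel_spacing, grid_shape=grid_shape
    )
    labels = np.zeros(grid_shape, dtype=np.int16)
    centers = [
        origin[ax] + (np.arange(grid_shape[ax]) + 0.5) * voxel_spacing[ax] for ax in range(3)
    ]
    for si, sph in enumerate(spheres):
        d2 = (
            (centers[0][:, None, None] - sph.center[0]) ** 2
            + (centers[1][None, :, None] - sph.center[1]) ** 2
            + (centers[2][None, None, :] - sph.center[2]) ** 2
        )
        labels[d2 <= sph.radius**2] = si + 1
    return GroundTruth(
        spheres=tuple(spheres),
        slice_areas_mm2=_sphere_slice_areas(spec),
        label_mask=labels,
        voxel_spacing=voxel_spacing,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# synthetic calibration tables


def generate_threshold_dataset(model_coeffs, design_grid, noise_sd: float, seed: int):
    """Synthesize calibration records from a known threshold model.

    ``design_grid`` is an iterable of ``(area_mm2, tb, fwhm_mm)`` triples (or
    mappings with those keys); each record's threshold is the model
    prediction at that design point plus zero-mean Gaussian noise of sd
    ``noise_sd``.  Used for parameter-recovery experiments where the true
    coefficients are known.  Returns a list of ``ThresholdRecord``.
    """
    from .calibration import ThresholdRecord
    from .regression import ThresholdModel

    if isinstance(model_coeffs, ThresholdModel):
        model = model_coeffs
    else:
        coeffs = dict(model_coeffs)
        form = "small_area" if "area" in coeffs else "large_area"
        model = ThresholdModel(form=form, coefficients=coeffs)

    points = []
    for entry in design_grid:
        if isinstance(entry, dict):
            points.append((entry.get("area_mm2"), entry["tb"], entry.get("fwhm_mm", 0.0)))
        else:
            points.append(tuple(entry))
    if not points:
        raise ValueError("design grid is empty")

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(points)) if noise_sd > 0 else np.zeros(len(points))
    records = []
    for (area, tb, fwhm), eps in zip(points, noise):
        ts = model.predict(area=area, tb=tb, fwhm=fwhm, clip=False)[0] + float(eps)
        records.append(
            ThresholdRecord(
                sphere_id_mm=float("nan"),
                area_mm2=float(area) if area is not None else float("nan"),
                tb=float(tb),
                ts_percent=float(ts),
                iterations=0,
                fwhm_mm=float(fwhm),
                role="synthetic",
            )
        )
    return records
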