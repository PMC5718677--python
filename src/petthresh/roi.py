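"""Circular-ROI placement and target-to-background (TB) measurement.

The TB ratio of a target is the maximum voxel intensity inside a circular
ROI encircling its cross-section, divided by the mean intensity over a set
of background ROIs placed well away from the phantom edge and from every
hot sphere (NEMA-style pattern: 12 ROIs of 37 mm on the central slice,
replicated at +-10 and +-20 mm for 60 in total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .phantom import GeometryError, GroundTruth, ImageVolume

__all__ = [
    "SliceROI",
    "ROISet",
    "MeasurementError",
    "PlacementError",
    "roi_mask",
    "measure_tb",
    "nema_background_pattern",
]


class MeasurementError(ValueError):
    """ROI statistics cannot be formed (empty mask, non-positive background)."""


class PlacementError(ValueError):
    """Background-ROI placement constraints cannot be satisfied."""


@dataclass(frozen=True)
class SliceROI:
    """Circular in-plane ROI: center (x, y) in mm, diameter in mm, on one
    axial slice."""

    center: tuple[float, float]
    diameter: float
    slice_index: int
    role: str = "target"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class ROISet:
    """A collection of ROIs with role tags (``target`` / ``background``)."""

    rois: tuple[SliceROI, ...]

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def with_role(self, role: str) -> "ROISet":
        return ROISet(tuple(r for r in self.rois if r.role == role))

    def concentric(self, diameter: float) -> "ROISet":
        """Same centers and slices, different ROI diameter (the smaller
        background ROIs are derived concentric with the 37 mm set)."""
        return ROISet(tuple(replace(r, diameter=diameter) for r in self.rois))

    def validate_nonoverlap(self) -> None:
        by_slice: dict[int, list[SliceROI]] = {}
        for r in self.rois:
            if r.role == "background":
                by_slice.setdefault(r.slice_index, []).append(r)
        for rois in by_slice.values():
            for i, a in enumerate(rois):
                for b in rois[i + 1 :]:
                    if math.dist(a.center, b.center) < a.radius + b.radius - 1e-9:
                        raise PlacementError("background ROIs overlap")


def roi_mask(volume: ImageVolume, roi: SliceROI) -> np.ndarray:
    """Boolean in-plane mask of voxels whose centers fall inside the ROI.

    Membership is by voxel-center inclusion: center within ``diameter/2`` of
    the ROI center, on the ROI's slice.  Returns a 2D array of the slice
    shape.  Raises :class:`GeometryError` if the ROI lies outside the
    volume.
    """
    nx, ny, nz = volume.shape
    if not 0 <= roi.slice_index < nz:
        raise GeometryError(f"slice {roi.slice_index} outside volume (nz={nz})")
    ext_x = nx * volume.voxel_spacing[0]
    ext_y = ny * volume.voxel_spacing[1]
    cx, cy = roi.center
    if not (volume.origin[0] <= cx <= volume.origin[0] + ext_x) or not (
        volume.origin[1] <= cy <= volume.origin[1] + ext_y
    ):
        raise GeometryError(f"ROI center {roi.center} outside volume extent")
    xs = volume.axis_centers_mm(0)
    ys = volume.axis_centers_mm(1)
    d2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
    return d2 <= roi.radius**2


def measure_tb(
    volume: ImageVolume, target_roi: SliceROI, background_rois: ROISet
) -> float:
    """TB ratio: max intensity in the target ROI over mean background.

    The numerator is the single hottest voxel inside the target ROI on its
    slice; the denominator is the mean over the union of all background ROI
    voxels (which may span several slices).
    """
    tmask = roi_mask(volume, target_roi)
    if not tmask.any():
        raise GeometryError("target ROI contains no voxel centers")
    target_max = float(volume.values[:, :, target_roi.slice_index][tmask].max())

    bg_values = []
    for roi in background_rois:
        if roi.role not in ("background", "target"):
            continue
        m = roi_mask(volume, roi)
        if not m.any():
            raise GeometryError("background ROI contains no voxel centers")
        bg_values.append(volume.values[:, :, roi.slice_index][m])
    if not bg_values:
        raise MeasurementError("no background ROIs supplied")
    bg_mean = float(np.concatenate(bg_values).mean())
    if bg_mean <= 0:
        raise MeasurementError(f"background mean {bg_mean} is not positive")
    return target_max / bg_mean


BACKGROUND_ROI_DIAMETER = 37.0
EDGE_CLEARANCE_MM = 15.0
SPHERE_CLEARANCE_MM = 15.0
N_RING_ROIS = 12
SLICE_OFFSETS_MM = (-20.0, -10.0, 0.0, 10.0, 20.0)


def nema_background_pattern(
    volume: ImageVolume,
    phantom_truth: GroundTruth,
    central_slice: int,
    *,
    roi_diameter: float = BACKGROUND_ROI_DIAMETER,
) -> ROISet:
    """Automatic NEMA-style background ROI pattern.

    Places 12 non-overlapping ROIs of ``roi_diameter`` on the central slice
    by a deterministic angular sweep along the ring lying 15 mm + ROI radius
    inside the in-plane volume edge, greedily rejecting positions whose ROI
    boundary comes within 15 mm of any sphere surface (in-plane), then
    replicates the accepted pattern at -20, -10, +10 and +20 mm axially for
    a total of 60 ROIs.
    """
    nx, ny, nz = volume.shape
    ext_x = nx * volume.voxel_spacing[0]
    ext_y = ny * volume.voxel_spacing[1]
    cx = volume.origin[0] + ext_x / 2.0
    cy = volume.origin[1] + ext_y / 2.0
    radius = roi_diameter / 2.0
    ring = min(ext_x, ext_y) / 2.0 - EDGE_CLEARANCE_MM - radius
    if ring <= 0:
        raise PlacementError("volume too small for the edge-clearance ring")

    spheres_xy = [
        ((s.center[0], s.center[1]), s.radius) for s in phantom_truth.spheres
    ]

    def clear_of_spheres(px: float, py: float) -> bool:
        for (sx, sy), sr in spheres_xy:
            if math.dist((px, py), (sx, sy)) < sr + radius + SPHERE_CLEARANCE_MM - 1e-9:
                return False
        return True

    accepted: list[tuple[float, float]] = []
    for step in range(720):  # 0.5 degree sweep
        ang = 2.0 * math.pi * step / 720.0
        px = cx + ring * math.cos(ang)
        py = cy + ring * math.sin(ang)
        if not clear_of_spheres(px, py):
            continue
        if any(math.dist((px, py), q) < roi_diameter + 1e-9 for q in accepted):
            continue
        accepted.append((px, py))
        if len(accepted) == N_RING_ROIS:
            break
    if len(accepted) < N_RING_ROIS:
        raise PlacementError(
            f"only {len(accepted)} of {N_RING_ROIS} background ROIs fit the constraints"
        )

    sz = volume.voxel_spacing[2]
    rois = []
    for off in SLICE_OFFSETS_MM:
        k = central_slice + round(off / sz)
        if not 0 <= k < nz:
            raise PlacementError(f"offset slice at {off:+g} mm falls outside the volume")
        for px, py in accepted:
            rois.append(SliceROI((px, py), roi_diameter, k, role="background"))
    roi_set = ROISet(tuple(rois))
    roi_set.validate_nonoverlap()
    return roi_set
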