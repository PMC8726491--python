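"""HU-histogram analysis (HUHA) of circular neck ROIs and femur VOIs.

HUHA expresses, as percentages of the region, the voxels below 0 HU
(HUHA_Fat, fatty marrow) and at or above 126 HU (HUHA_Bone); the remainder is
the mid band. The largest circular ROI is grown around the neck's 3D central
point until it touches the outer cortical boundary, so cortical pixels lie
inside the ROI. Pixel/voxel membership is decided by the center-in-region
rule and HU values enter the statistics raw (no binning beyond the two band
edges).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .reformation import ReformattedPlane
from .segmentation import ProximalFemurVOI
from .volume_io import CTVolume

FAT_EDGE_HU = 0.0  # HUHA_Fat: strictly below
BONE_EDGE_HU = 126.0  # HUHA_Bone: inclusive at the edge

PREFIX_2D = "2D_coronal"
PREFIX_3D = "3D_Femur"


@dataclass(frozen=True)
class HUHAResult:
    """Band percentages (exact rational counts converted to float) and mean HU."""

    huha_fat: float
    huha_bone: float
    huha_mid: float
    mean_hu: float
    n: int
    n_fat: int
    n_bone: int
    n_mid: int


@dataclass(frozen=True)
class CircularROI:
    center: tuple[float, float]  # (u, v) mm offsets on the plane
    radius: float
    pixel_count: int
    area_mm2: float


@dataclass(frozen=True)
class MeasurementRecord:
    subject_id: str
    prefix: str  # PREFIX_2D or PREFIX_3D
    result: HUHAResult
    size: float  # area_mm2 for 2D, volume_ml for 3D
    size_unit: str


def huha_summary(values) -> HUHAResult:
    """Band fractions and mean over a sequence of HU values.

    Percentages are formed from exact voxel counts, so the fat/mid/bone
    triplet sums to 100 up to a single float conversion per band.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty HU sequence")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite HU values")
    n = int(v.size)
    n_fat = int(np.sum(v < FAT_EDGE_HU))
    n_bone = int(np.sum(v >= BONE_EDGE_HU))
    n_mid = n - n_fat - n_bone
    return HUHAResult(
        huha_fat=float(Fraction(100 * n_fat, n)),
        huha_bone=float(Fraction(100 * n_bone, n)),
        huha_mid=float(Fraction(100 * n_mid, n)),
        mean_hu=float(np.mean(v)),
        n=n,
        n_fat=n_fat,
        n_bone=n_bone,
        n_mid=n_mid,
    )


def _pixel_grids(plane: ReformattedPlane) -> tuple[np.ndarray, np.ndarray]:
    u, v = plane.pixel_offsets()
    return np.meshgrid(u, v, indexing="ij")


def largest_inscribed_circle(
    plane: ReformattedPlane, center: tuple[float, float] = (0.0, 0.0)
) -> CircularROI:
    """Largest circle around ``center`` that stays inside the femur cross-section.

    The radius is the distance from the center to the nearest non-femur (or
    invalid) pixel center, so the circle touches, without crossing, the outer
    cortical boundary. ROI pixels are those whose centers lie strictly within
    the radius.
    """
    uu, vv = _pixel_grids(plane)
    du, dv = plane.pixel_spacing
    cu, cv = float(center[0]), float(center[1])
    iu = int(round(cu / du + (plane.shape[0] - 1) / 2.0))
    iv = int(round(cv / dv + (plane.shape[1] - 1) / 2.0))
    if not (0 <= iu < plane.shape[0] and 0 <= iv < plane.shape[1]):
        raise ValueError("ROI center outside the plane")
    inside = plane.bone_mask & plane.valid
    if not inside[iu, iv]:
        raise ValueError("ROI center does not lie on the femur cross-section")
    background = ~inside
    d2 = (uu - cu) ** 2 + (vv - cv) ** 2
    if np.any(background):
        radius = float(np.sqrt(d2[background].min()))
    else:  # femur fills the plane: cap at the nearest plane edge
        u, v = plane.pixel_offsets()
        radius = float(min(cu - u[0], u[-1] - cu, cv - v[0], v[-1] - cv))
    member = d2 <= (radius - 1e-9) ** 2
    count = int(np.sum(member))
    if count == 0:
        raise ValueError("degenerate ROI: no pixel centers inside the radius")
    return CircularROI(
        center=(cu, cv), radius=radius, pixel_count=count, area_mm2=count * du * dv
    )


def roi_member_pixels(plane: ReformattedPlane, roi: CircularROI) -> np.ndarray:
    uu, vv = _pixel_grids(plane)
    d2 = (uu - roi.center[0]) ** 2 + (vv - roi.center[1]) ** 2
    return d2 <= (roi.radius - 1e-9) ** 2


def measure_roi(
    plane: ReformattedPlane, roi: CircularROI, subject_id: str = ""
) -> MeasurementRecord:
    """HUHA and mean-HU over the 2D_coronal circular ROI."""
    member = roi_member_pixels(plane, roi)
    if not np.any(member):
        raise ValueError("empty ROI")
    if np.any(member & ~plane.valid):
        raise ValueError("ROI overlaps samples outside the volume")
    res = huha_summary(plane.values[member])
    return MeasurementRecord(
        subject_id=subject_id,
        prefix=PREFIX_2D,
        result=res,
        size=roi.area_mm2,
        size_unit="mm2",
    )


def measure_voi(
    volume: CTVolume, voi: ProximalFemurVOI, subject_id: str = ""
) -> MeasurementRecord:
    """HUHA and mean-HU over all HU values inside the 3D_Femur VOI."""
    voi.mask.check_aligned(volume)
    if voi.voxel_count == 0:
        raise ValueError("empty VOI")
    res = huha_summary(volume.values[voi.mask.values])
    return MeasurementRecord(
        subject_id=subject_id,
        prefix=PREFIX_3D,
        result=res,
        size=voi.volume_ml,
        size_unit="ml",
    )
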