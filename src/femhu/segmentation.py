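"""Proximal-femur VOI extraction: 3D region growing, interior filling, and
exclusion of everything inferior to the lesser-trochanter plane.

The region-growing band defaults to [126, 3071] HU, the bone band used by the
HU-histogram analysis: it captures the cortical shell and the trabecular
lattice, after which :func:`fill_interior` adds the enclosed marrow so the
VOI histogram includes the fatty compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume_io import CTVolume, MaskVolume


class SeedOutOfRangeError(ValueError):
    """The region-growing seed voxel is outside the configured HU band."""


class CutPlaneNotFoundError(RuntimeError):
    """No medial prominence found; supply an explicit cut-plane override."""


@dataclass(frozen=True)
class RegionGrowConfig:
    seed_point: tuple[int, int, int]
    hu_low: float = 126.0
    hu_high: float = 3071.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.hu_low > self.hu_high:
            raise ValueError("hu_low must not exceed hu_high")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class ProximalFemurVOI:
    """The 3D_Femur volume of interest: femur at/above the lesser-trochanter plane."""

    mask: MaskVolume
    cut_plane_z: int
    voxel_count: int
    volume_ml: float


def region_grow(volume: CTVolume, config: RegionGrowConfig) -> MaskVolume:
    """Maximal connected in-band component containing the seed voxel.

    Deterministic: equivalent to a breadth-first flood fill over the
    thresholded grid under the configured connectivity.
    """
    seed = tuple(int(i) for i in config.seed_point)
    shape = volume.values.shape
    if any(i < 0 or i >= n for i, n in zip(seed, shape)):
        raise ValueError(f"seed point {seed} outside grid {shape}")
    hu = float(volume.values[seed])
    if not (config.hu_low <= hu <= config.hu_high):
        raise SeedOutOfRangeError(
            f"seed voxel HU {hu:.1f} outside band [{config.hu_low}, {config.hu_high}]"
        )
    band = (volume.values >= config.hu_low) & (volume.values <= config.hu_high)
    structure = (
        np.ones((3, 3, 3), dtype=bool)
        if config.connectivity == 26
        else ndi.generate_binary_structure(3, 1)
    )
    labeled, _ = ndi.label(band, structure=structure)
    return MaskVolume.like(volume, labeled == labeled[seed])


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    r = np.asarray(spacing, float)
    half = np.maximum(1, np.floor(radius_mm / r).astype(int))
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, r)], indexing="ij")
    return sum(g * g for g in grids) <= radius_mm**2


def fill_interior(mask: MaskVolume, closing_radius_mm: float = 0.0) -> MaskVolume:
    """Add all cavities not connected to the grid boundary (3D hole filling).

    An optional morphological closing of radius ``closing_radius_mm`` seals
    small perforations in the shell before filling. The result is always a
    superset of the input, and the operation is idempotent.
    """
    if not np.any(mask.values):
        raise ValueError("empty mask")
    work = mask.values
    if closing_radius_mm > 0:
        work = ndi.binary_closing(work, structure=_ball_structure(closing_radius_mm, mask.spacing))
    filled = ndi.binary_fill_holes(work)
    return MaskVolume(mask.values | filled, mask.spacing, mask.origin, mask.direction)


def detect_cut_plane(
    mask: MaskVolume,
    axis: int = 2,
    medial_axis: int = 0,
    medial_sign: float = -1.0,
    prominence_mm: float = 2.0,
    baseline_slices: int = 10,
    override: int | None = None,
) -> int:
    """Locate the inferior margin of the lesser trochanter along the slice axis.

    Scans slices from inferior (index 0) to superior and returns the first
    slice whose medial reach exceeds the shaft baseline (median medial reach
    of the most inferior slices) by ``prominence_mm``. ``medial_sign`` is -1
    for a left femur in LPS (medial = -x). An ``override`` value bypasses
    detection entirely, emulating the manual placement of the cut line.
    """
    if override is not None:
        return int(override)
    vals = mask.values
    if not np.any(vals):
        raise ValueError("empty mask")
    if axis != 2:
        vals = np.moveaxis(vals, axis, 2)
    n_slices = vals.shape[2]
    spacing_m = mask.spacing[medial_axis]
    reach = np.full(n_slices, np.nan)
    occupied = np.any(vals, axis=(0, 1))
    for k in np.nonzero(occupied)[0]:
        occ_m = np.any(vals[..., k], axis=1 if medial_axis == 0 else 0)
        idx_m = np.nonzero(occ_m)[0]
        reach[k] = (idx_m * spacing_m * medial_sign).max()
    present = np.nonzero(occupied)[0]
    base_idx = present[: max(1, baseline_slices)]
    baseline = float(np.nanmedian(reach[base_idx]))
    for k in present:
        if reach[k] > baseline + prominence_mm:
            return int(k)
    raise CutPlaneNotFoundError(
        "no medial prominence exceeds the shaft baseline by "
        f"{prominence_mm} mm; supply an explicit cut-plane override"
    )


def crop_to_voi(mask: MaskVolume, cut_plane_z: int, axis: int = 2) -> ProximalFemurVOI:
    """Remove all voxels inferior to the cut plane (the plane itself is kept)."""
    n = mask.values.shape[axis]
    if not 0 <= cut_plane_z < n:
        raise ValueError(f"cut plane {cut_plane_z} outside grid axis of length {n}")
    out = mask.values.copy()
    sl = [slice(None)] * 3
    sl[axis] = slice(0, cut_plane_z)
    out[tuple(sl)] = False
    count = int(np.sum(out))
    if count == 0:
        raise ValueError("VOI is empty after cropping at the cut plane")
    voi_mask = MaskVolume(out, mask.spacing, mask.origin, mask.direction)
    return ProximalFemurVOI(
        mask=voi_mask,
        cut_plane_z=int(cut_plane_z),
        voxel_count=count,
        volume_ml=count * voi_mask.voxel_volume_mm3 / 1000.0,
    )
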