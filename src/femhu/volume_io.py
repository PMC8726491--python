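"""CT volume and mask containers with Hounsfield-unit semantics, plus NIfTI/DICOM I/O.

Internal anatomical convention is LPS millimetres (the DICOM patient frame);
NIfTI's RAS affine is converted at the read/write boundary. Voxel indexing is
0-based and the coordinate belongs to the voxel *center*, which matches the
interpolation arithmetic in :mod:`femhu.reformation`.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

# RAS <-> LPS: flip the first two spatial axes.
_RAS_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class VolumeFormatError(ValueError):
    """A volume on disk violates the expected format (the message names the attribute)."""


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValueError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
        raise ValueError("direction matrix is not orthonormal")
    return d


@dataclass
class CTVolume:
    """A 3D grid of HU values with voxel spacing/origin/orientation metadata.

    ``values`` is indexed ``[i, j, k]``; the physical (LPS, mm) position of a
    voxel is ``origin + direction @ (index * spacing)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = _as_direction(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> LPS mm affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_mm(self, index) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = (self.affine[:3, :3] @ idx.T).T + np.asarray(self.origin)
        return pts[0] if np.asarray(index).ndim == 1 else pts

    def mm_to_index(self, point) -> np.ndarray:
        pt = np.atleast_2d(np.asarray(point, dtype=float)) - np.asarray(self.origin)
        inv = np.linalg.inv(self.affine[:3, :3])
        idx = (inv @ pt.T).T
        return idx[0] if np.asarray(point).ndim == 1 else idx

    def validate_hu(self) -> None:
        lo, hi = float(np.min(self.values)), float(np.max(self.values))
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU outside [{HU_MIN}, {HU_MAX}]: observed [{lo}, {hi}]")


@dataclass
class MaskVolume:
    """Binary labeling aligned voxel-for-voxel to a parent :class:`CTVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = _as_direction(self.direction)

    @classmethod
    def like(cls, parent: CTVolume, values: np.ndarray) -> "MaskVolume":
        if values.shape != parent.values.shape:
            raise ValueError("mask shape does not match parent volume")
        return cls(values, parent.spacing, parent.origin, parent.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def check_aligned(self, vol: CTVolume) -> None:
        if self.values.shape != vol.values.shape:
            raise ValueError("mask/volume shape mismatch")
        if not np.allclose(self.spacing, vol.spacing):
            raise ValueError("mask/volume spacing mismatch")

    # Reuse the volume coordinate math.
    index_to_mm = CTVolume.index_to_mm
    mm_to_index = CTVolume.mm_to_index
    affine = CTVolume.affine


def _lps_affine_to_nifti(affine_lps: np.ndarray) -> np.ndarray:
    return _RAS_LPS @ affine_lps


def _nifti_affine_to_lps(affine_ras: np.ndarray) -> np.ndarray:
    return _RAS_LPS @ affine_ras


def write_volume(volume: CTVolume | MaskVolume, path: str | os.PathLike) -> None:
    """Write a volume (float32) or mask (uint8) as NIfTI-1."""
    is_mask = isinstance(volume, MaskVolume)
    data = volume.values.astype(np.uint8 if is_mask else np.float32)
    affine_ras = _lps_affine_to_nifti(np.asarray(volume.affine))
    img = nib.Nifti1Image(data, affine_ras)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _read_nifti(path: str | os.PathLike) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D NIfTI, got shape {data.shape}")
    affine_lps = _nifti_affine_to_lps(img.affine)
    m = affine_lps[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"non-positive voxel spacing in affine: {spacing}")
    direction = m / spacing
    return CTVolume(data, tuple(spacing), tuple(affine_lps[:3, 3]), direction)


def read_mask(path: str | os.PathLike, like: CTVolume | None = None) -> MaskVolume:
    vol = _read_nifti(path)
    mask = MaskVolume(vol.values > 0.5, vol.spacing, vol.origin, vol.direction)
    if like is not None:
        mask.check_aligned(like)
    return mask


def _read_dicom_series(path: str | os.PathLike) -> CTVolume:
    import pydicom

    files = sorted(Path(path).iterdir())
    slices = []
    for f in files:
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no DICOM image slices found in {path}")

    first = slices[0]
    if getattr(first, "Modality", None) != "CT":
        raise VolumeFormatError(f"Modality is {getattr(first, 'Modality', None)!r}, expected 'CT'")
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    ps = np.asarray(first.PixelSpacing, dtype=float)  # (row, col)
    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop, atol=1e-5):
            raise VolumeFormatError("inconsistent ImageOrientationPatient across series")
        if not np.allclose(np.asarray(ds.PixelSpacing, float), ps, atol=1e-5):
            raise VolumeFormatError("inconsistent PixelSpacing across series")
        if ds.pixel_array.shape != first.pixel_array.shape:
            raise VolumeFormatError("inconsistent Rows/Columns across series")

    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    positions = [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in slices]
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = np.asarray(positions)[order]

    if len(slices) > 1:
        dz = np.diff(positions)
        if np.any(dz <= 0):
            raise VolumeFormatError("duplicate ImagePositionPatient slice locations")
        if not np.allclose(dz, dz[0], atol=max(1e-3, 1e-3 * dz[0])):
            k = int(np.argmax(np.abs(dz - np.median(dz))))
            raise VolumeFormatError(
                f"non-uniform slice spacing (gap between slices {k} and {k + 1}: "
                f"{dz[k]:.4f} mm vs {np.median(dz):.4f} mm); a slice may be missing"
            )
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    # pixel_array is (rows, cols); internal axes are (x=col, y=row, z=slice)
    data = np.stack([p.T for p in planes], axis=-1)

    direction = np.column_stack([row_dir, col_dir, normal])
    spacing = (float(ps[1]), float(ps[0]), slice_spacing)
    origin = tuple(np.asarray(slices[0].ImagePositionPatient, dtype=float))
    return CTVolume(data, spacing, origin, direction)


def read_volume(path: str | os.PathLike, format: str = "nifti") -> CTVolume:
    """Read a CT volume from NIfTI or a DICOM series directory (HU rescale applied)."""
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")
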