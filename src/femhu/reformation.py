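"""Femoral-neck frame estimation and true-coronal multiplanar reformation.

The "3D central point" of the neck is operationalized as the centroid of the
minimal femur cross-section along the head-to-trochanter direction, and the
true-coronal plane is the oblique plane that contains the neck axis (not the
scanner coronal). HU values are sampled with trilinear interpolation, masks
with nearest-neighbor, so no interpolation overshoot can leak across the HU
histogram band edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._utils import bbox_edt
from .volume_io import CTVolume, MaskVolume


class NeckNotFoundError(RuntimeError):
    """The mask has no neck-like structure to fit a frame to."""


@dataclass
class NeckFrame:
    """Orthonormal frame of the femoral neck (mm, LPS).

    ``in_plane_u`` (the neck axis) and ``in_plane_v`` span the true-coronal
    plane; their cross product is the plane normal.
    """

    neck_center: np.ndarray
    neck_axis: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("neck_center", "neck_axis", "in_plane_u", "in_plane_v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        basis = np.stack([self.neck_axis, self.in_plane_u, self.in_plane_v])
        norms = np.linalg.norm(basis, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"frame vectors must be unit length, norms {norms}")
        if abs(float(self.in_plane_u @ self.in_plane_v)) > 1e-9:
            raise ValueError("in-plane vectors must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.in_plane_u, self.in_plane_v)


@dataclass
class ReformattedPlane:
    """A resampled oblique plane with its femur cross-section mask.

    Pixel (i, j) sits at ``frame.neck_center + u[i]*in_plane_u + v[j]*in_plane_v``
    where u, v are centered mm offsets. ``valid`` marks pixels sampled inside
    the volume; invalid pixels are excluded from all downstream statistics.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    frame: NeckFrame
    bone_mask: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv = self.values.shape
        du, dv = self.pixel_spacing
        u = (np.arange(nu) - (nu - 1) / 2.0) * du
        v = (np.arange(nv) - (nv - 1) / 2.0) * dv
        return u, v


def estimate_head_center(mask: MaskVolume) -> np.ndarray:
    """Center of the maximal inscribed sphere of the head component (mm).

    If the mask has several connected components the one admitting the largest
    inscribed sphere is used (with a warning); ties break toward the more
    superior component.
    """
    if not np.any(mask.values):
        raise ValueError("empty mask")
    labeled, n_comp = ndi.label(mask.values, structure=np.ones((3, 3, 3), bool))
    dist = bbox_edt(mask.values, mask.spacing)
    if n_comp > 1:
        warnings.warn(f"mask has {n_comp} components; using the one with the largest inscribed sphere")
        best, best_key = None, None
        for c in range(1, n_comp + 1):
            sel = labeled == c
            r = float(dist[sel].max())
            z_top = float(np.nonzero(sel)[2].max()) if r > 0 else -1.0
            key = (r, z_top)
            if best_key is None or key > best_key:
                best, best_key = c, key
        dist = np.where(labeled == best, dist, 0.0)
    idx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    if dist[idx] <= 0:
        raise ValueError("degenerate mask: no interior voxel")
    return mask.index_to_mm(np.asarray(idx, dtype=float))


def _window_stats(t: np.ndarray, pts: np.ndarray, centers: np.ndarray, half: float):
    """Counts and centroids of points in sliding windows |t - c| <= half."""
    order = np.argsort(t)
    ts = t[order]
    ps = pts[order]
    cum = np.vstack([np.zeros(3), np.cumsum(ps, axis=0)])
    lo = np.searchsorted(ts, centers - half, side="left")
    hi = np.searchsorted(ts, centers + half, side="right")
    counts = hi - lo
    sums = cum[hi] - cum[lo]
    with np.errstate(invalid="ignore"):
        centroids = sums / np.maximum(counts, 1)[:, None]
    return counts, centroids


def estimate_neck_frame(
    mask: MaskVolume,
    head_center: np.ndarray,
    window_mm: float = 3.0,
    step_mm: float = 1.0,
    n_iter: int = 3,
    ap_axis: int = 1,
) -> NeckFrame:
    """Fit the neck axis and central point from the femur mask.

    The initial axis points from the head center toward the centroid of the
    peri-capital shell (neck and trochanter mass). It is then refined
    iteratively: sliding windows along the axis locate the waist (the minimal
    cross-section), and a principal-component line fit through the centroids
    of the near-minimal windows re-estimates the axis -- for a tubular neck
    every planar slab centroid lies exactly on the axis, which makes the fit
    robust to the window placement. The neck center is the centroid of the
    minimal window.
    """
    pts = np.argwhere(mask.values).astype(float)
    if pts.shape[0] == 0:
        raise ValueError("empty mask")
    pts_mm = pts * np.asarray(mask.spacing)
    hc = np.asarray(head_center, dtype=float)

    head_idx = np.round(np.asarray(mask.mm_to_index(hc))).astype(int)
    head_idx = np.clip(head_idx, 0, np.asarray(mask.values.shape) - 1)
    dist = bbox_edt(mask.values, mask.spacing)
    r_head = float(dist[tuple(head_idx)])
    if r_head <= 0:
        raise ValueError("head center does not lie inside the mask")

    d_all = np.linalg.norm(pts_mm - hc, axis=1)
    far = pts_mm[d_all > 1.35 * r_head]
    if far.shape[0] < 10:
        raise NeckNotFoundError("no structure beyond the head: cannot orient a neck axis")
    # Initial direction from the peri-capital shell (neck and trochanter mass);
    # the full distal femur would bias the direction toward the shaft.
    shell = pts_mm[(d_all > 1.35 * r_head) & (d_all < 2.6 * r_head)]
    if shell.shape[0] < 10:
        shell = far
    d0 = shell.mean(axis=0) - hc
    d0 /= np.linalg.norm(d0)

    reach = float(np.percentile((far - hc) @ d0, 90))
    t_lo = 0.8 * r_head
    t_hi = max(1.05 * r_head + window_mm, min(2.4 * r_head, 0.9 * reach))

    # restrict to a tube around the initial axis for speed
    rel = pts_mm - hc
    t0 = rel @ d0
    perp = rel - np.outer(t0, d0)
    keep = (t0 > t_lo - 6.0) & (t0 < t_hi + 6.0) & (np.linalg.norm(perp, axis=1) < 2.0 * r_head)
    sub = rel[keep]
    if sub.shape[0] < 10:
        raise NeckNotFoundError("no voxels in the candidate neck region")

    centers = np.arange(t_lo, t_hi + 1e-9, step_mm)
    if len(centers) < 3:
        raise NeckNotFoundError("neck search interval degenerate")
    half = window_mm / 2.0

    axis = d0
    neck_center_rel = None
    for _ in range(n_iter):
        t = sub @ axis
        counts, centroids = _window_stats(t, sub, centers, half)
        if not counts.any():
            raise NeckNotFoundError("empty neck search interval")
        k = int(np.argmin(np.where(counts > 0, counts, np.iinfo(np.int64).max)))
        # near-minimal windows delimit the tubular neck segment
        near = counts <= 1.35 * counts[k]
        near &= counts > 0
        # contiguous run containing k
        i0 = k
        while i0 > 0 and near[i0 - 1]:
            i0 -= 1
        i1 = k
        while i1 < len(centers) - 1 and near[i1 + 1]:
            i1 += 1
        run = centroids[i0 : i1 + 1]
        # the 3D central point: middle of the tubular segment, on the axis
        neck_center_rel = run.mean(axis=0)
        if len(run) >= 3:
            c_mean = run.mean(axis=0)
            u, s, vt = np.linalg.svd(run - c_mean, full_matrices=False)
            new_axis = vt[0]
            if new_axis @ axis < 0:
                new_axis = -new_axis
            axis = new_axis / np.linalg.norm(new_axis)
    neck_center = hc + neck_center_rel

    ap = np.zeros(3)
    ap[ap_axis] = 1.0
    n = ap - (ap @ axis) * axis
    if np.linalg.norm(n) < 1e-6:  # axis parallel to AP: fall back to x
        n = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    n /= np.linalg.norm(n)
    v = np.cross(n, axis)
    v /= np.linalg.norm(v)
    return NeckFrame(neck_center=neck_center, neck_axis=axis, in_plane_u=axis, in_plane_v=v)


def reformat_plane(
    volume: CTVolume,
    frame: NeckFrame,
    extent: tuple[float, float] = (80.0, 80.0),
    pixel_spacing: tuple[float, float] = (0.67, 0.67),
    mask: MaskVolume | None = None,
    center: np.ndarray | None = None,
) -> ReformattedPlane:
    """Resample the true-coronal plane of the neck by trilinear interpolation.

    ``center`` overrides the plane center (defaults to the frame's neck
    center). Samples falling outside the volume are marked invalid.
    """
    c = np.asarray(frame.neck_center if center is None else center, dtype=float)
    nu = max(2, int(round(extent[0] / pixel_spacing[0])))
    nv = max(2, int(round(extent[1] / pixel_spacing[1])))
    u = (np.arange(nu) - (nu - 1) / 2.0) * pixel_spacing[0]
    v = (np.arange(nv) - (nv - 1) / 2.0) * pixel_spacing[1]
    pts = (
        c[None, None, :]
        + u[:, None, None] * frame.in_plane_u[None, None, :]
        + v[None, :, None] * frame.in_plane_v[None, None, :]
    )
    idx = volume.mm_to_index(pts.reshape(-1, 3)).reshape(nu, nv, 3)
    coords = np.moveaxis(idx, -1, 0)
    vals = ndi.map_coordinates(
        volume.values.astype(np.float64), coords, order=1, mode="constant", cval=np.nan
    )
    valid = np.isfinite(vals)
    if not np.any(valid):
        raise ValueError("plane lies wholly outside the volume")
    if mask is not None:
        bone = ndi.map_coordinates(
            mask.values.astype(np.uint8), coords, order=0, mode="constant", cval=0
        ).astype(bool)
    else:
        bone = np.zeros((nu, nv), dtype=bool)
    frame_out = NeckFrame(c, frame.neck_axis, frame.in_plane_u, frame.in_plane_v)
    return ReformattedPlane(
        values=vals,
        pixel_spacing=(float(pixel_spacing[0]), float(pixel_spacing[1])),
        frame=frame_out,
        bone_mask=bone & valid,
        valid=valid,
    )
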