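"""Synthetic proximal-femur CT phantom cohort.

The generator emulates the statistical structure of an opportunistic-screening
study population of 430 women (96 osteoporotic by DXA femoral-neck T-score
<= -2.5, 334 non-osteoporotic) and renders, per subject, a left proximal femur
as a union of analytic solids (spherical head, frustum-like neck capsule at a
configurable neck-shaft angle, cylindrical shaft, ellipsoidal greater/lesser
trochanter bosses) on a 0.67 x 0.67 x 1 mm voxel grid.

The interior of the femur is a per-voxel categorical mixture of trabecular
bone, red marrow and marrow fat. Mixture probabilities are monotone functions
of the subject's bone mineral density: lower BMD means more marrow fat and
fewer trabecular-bone voxels, so the volume's HU histogram responds to BMD the
way osteoporotic bone does on CT. Labels are assigned by thresholding a single
per-voxel uniform field, which makes every HU-histogram fraction analytically
predictable and strictly monotone in BMD for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import truncnorm

from ._utils import bbox_edt
from .volume_io import CTVolume, MaskVolume

OSTEOPOROSIS = "osteoporosis"
NON_OSTEOPOROSIS = "non-osteoporosis"
T_SCORE_CUT = -2.5

# Composition label codes used in GroundTruth.labels
LABEL_BG = 0
LABEL_CORTICAL = 1
LABEL_TRABECULAR = 2
LABEL_RED_MARROW = 3
LABEL_FAT = 4


def t_score_from_bmd(bmd: float, ref_mean: float = 0.94, ref_sd: float = 0.12) -> float:
    """Densitometric T-score: (BMD - young-adult reference mean) / reference SD.

    The reference constants default to a plausible young-adult femoral-neck
    population (mean 0.94 g/cm^2, SD 0.12 g/cm^2); they are configuration, not
    measured values.
    """
    if ref_sd <= 0:
        raise ValueError(f"ref_sd must be positive, got {ref_sd}")
    return (bmd - ref_mean) / ref_sd


@dataclass(frozen=True)
class CouplingConfig:
    """Monotone maps from BMD to interior tissue composition.

    Over ``bmd_range`` the marrow-fat voxel probability falls linearly from
    ``fat_fraction_range[0]`` to ``fat_fraction_range[1]`` and the
    trabecular-bone voxel probability rises linearly across
    ``bone_fraction_range``; outside the range values are clipped. The HU
    constants let the expected interior HU be computed in closed form. The
    strength of the coupling is a modeling choice, not an observed quantity.
    """

    bmd_range: tuple[float, float] = (0.40, 1.20)
    fat_fraction_range: tuple[float, float] = (0.55, 0.05)  # at (bmd_lo, bmd_hi)
    bone_fraction_range: tuple[float, float] = (0.05, 0.50)
    hu_fat: float = -80.0
    hu_red_marrow: float = 40.0
    hu_trabecular: float = 400.0

    def __post_init__(self) -> None:
        if self.bmd_range[0] >= self.bmd_range[1]:
            raise ValueError("bmd_range must be increasing")
        if self.fat_fraction_range[0] <= self.fat_fraction_range[1]:
            raise ValueError("fat fraction must strictly decrease with BMD")
        if self.bone_fraction_range[0] >= self.bone_fraction_range[1]:
            raise ValueError("trabecular fraction must strictly increase with BMD")
        for f in (*self.fat_fraction_range, *self.bone_fraction_range):
            if not 0.0 <= f <= 1.0:
                raise ValueError("composition fractions must lie in [0, 1]")

    def _rel(self, bmd: float) -> float:
        lo, hi = self.bmd_range
        return min(1.0, max(0.0, (bmd - lo) / (hi - lo)))

    def fractions(self, bmd: float) -> tuple[float, float, float]:
        """(fat, red-marrow, trabecular) voxel probabilities at this BMD."""
        r = self._rel(bmd)
        f0, f1 = self.fat_fraction_range
        b0, b1 = self.bone_fraction_range
        q_fat = f0 + (f1 - f0) * r
        q_bone = b0 + (b1 - b0) * r
        return q_fat, 1.0 - q_fat - q_bone, q_bone

    def interior_mean_hu(self, bmd: float) -> float:
        q_f, q_r, q_b = self.fractions(bmd)
        return q_f * self.hu_fat + q_r * self.hu_red_marrow + q_b * self.hu_trabecular


def bmd_to_tissue_params(bmd: float, coupling: CouplingConfig | None = None) -> tuple[float, float]:
    """Map BMD to (marrow_fat_fraction, trabecular_hu_mean) via a monotone coupling."""
    if bmd <= 0:
        raise ValueError(f"bmd must be positive, got {bmd}")
    coupling = coupling or CouplingConfig()
    q_fat, _, _ = coupling.fractions(bmd)
    return q_fat, coupling.interior_mean_hu(bmd)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    age: float
    bmd: float
    t_score: float
    group: str
    marrow_fat_fraction: float
    trabecular_hu_mean: float

    def __post_init__(self) -> None:
        if self.bmd <= 0:
            raise ValueError("bmd must be positive")
        if not 0.0 <= self.marrow_fat_fraction <= 1.0:
            raise ValueError("marrow_fat_fraction must lie in [0, 1]")
        expected = OSTEOPOROSIS if self.t_score <= T_SCORE_CUT else NON_OSTEOPOROSIS
        if self.group != expected:
            raise ValueError(
                f"group {self.group!r} contradicts t_score {self.t_score} "
                f"(cut at {T_SCORE_CUT})"
            )


@dataclass(frozen=True)
class GroupParams:
    """Group-wise Gaussian moments for age / T-score / BMD."""

    age_mean: float
    age_sd: float
    t_mean: float
    t_sd: float
    bmd_mean: float
    bmd_sd: float

    def __post_init__(self) -> None:
        for sd in (self.age_sd, self.t_sd, self.bmd_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class CohortParams:
    osteoporosis: GroupParams = GroupParams(78.5, 8.7, -3.1, 0.5, 0.57, 0.06)
    non_osteoporosis: GroupParams = GroupParams(61.7, 10.2, -1.6, 0.8, 0.84, 0.12)
    age_min: float = 50.0  # study inclusion: women aged >= 50


DEFAULT_COHORT_PARAMS = CohortParams()


def _trunc_draw(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a = (lo - mean) / sd if np.isfinite(lo) else -np.inf
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    n_osteo: int,
    n_non: int,
    params: CohortParams = DEFAULT_COHORT_PARAMS,
    seed: int = 0,
    coupling: CouplingConfig | None = None,
) -> list[SubjectProfile]:
    """Draw a seeded cohort with exact group counts.

    T-scores are truncated-Gaussian draws constrained to the group's side of
    -2.5, so no subject's label can contradict its T-score; BMD is truncated
    to be positive and age to the study's inclusion minimum.
    """
    if n_osteo < 0 or n_non < 0:
        raise ValueError("group counts must be non-negative")
    coupling = coupling or CouplingConfig()
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    specs = [
        (OSTEOPOROSIS, n_osteo, params.osteoporosis, -np.inf, T_SCORE_CUT),
        (NON_OSTEOPOROSIS, n_non, params.non_osteoporosis, T_SCORE_CUT, np.inf),
    ]
    idx = 0
    for group, n, gp, t_lo, t_hi in specs:
        ages = _trunc_draw(rng, gp.age_mean, gp.age_sd, params.age_min, np.inf, n)
        ts = _trunc_draw(rng, gp.t_mean, gp.t_sd, t_lo, t_hi, n)
        bmds = _trunc_draw(rng, gp.bmd_mean, gp.bmd_sd, 0.0, np.inf, n)
        for a, t, b in zip(ages, ts, bmds):
            idx += 1
            q_fat, hu_mean = bmd_to_tissue_params(float(b), coupling)
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{idx:04d}",
                    age=float(a),
                    bmd=float(b),
                    t_score=float(t),
                    group=group,
                    marrow_fat_fraction=q_fat,
                    trabecular_hu_mean=hu_mean,
                )
            )
    return profiles


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU configuration of the rendered proximal femur.

    Lengths are millimetres; the femur must fit strictly inside the grid.
    The slice axis (k) points superiorly: the femoral head is at high k.
    ``side`` controls laterality; only the left femur is rendered by default
    (the study measured the left side). In LPS the medial direction of a left
    femur is -x.
    """

    voxel_spacing: tuple[float, float, float] = (0.67, 0.67, 1.0)
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    head_radius: float = 17.0
    neck_radius: float = 10.5
    neck_length: float = 24.0
    shaft_radius: float = 11.0
    cortical_thickness: float = 1.5
    neck_shaft_angle: float = 130.0
    lesser_trochanter_offset: float = 36.0  # mm below the shaft top, boss center
    hu_cortical: float = 1200.0
    hu_trabecular_ref: float = 400.0
    hu_red_marrow: float = 40.0
    hu_fat: float = -80.0
    hu_soft_tissue: float = 30.0
    noise_sd: float = 10.0
    anatomy_scale_sd: float = 0.04  # per-subject isotropic size variation
    side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_fat < 0 <= self.hu_red_marrow < 126 <= self.hu_cortical):
            raise ValueError(
                "HU ordering must satisfy hu_fat < 0 <= hu_red_marrow < 126 <= hu_cortical"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self._check_fits()

    # -- derived geometry -------------------------------------------------
    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing)

    @property
    def medial_sign(self) -> float:
        return -1.0 if self.side == "left" else 1.0

    def geometry(self) -> dict:
        """Closed-form landmark positions in mm (LPS, voxel-center origin at 0)."""
        ex, ey, ez = self.extent
        m = self.medial_sign
        shaft_x = (0.65 if self.side == "left" else 0.35) * ex
        y_c = 0.5 * ey
        shaft_top = 0.56 * ez
        shaft_bot = max(0.05 * ez, 4.0)
        polar = math.radians(180.0 - self.neck_shaft_angle)
        axis = np.array([m * math.sin(polar), 0.0, math.cos(polar)])
        neck_base = np.array([shaft_x, y_c, shaft_top])
        head_center = neck_base + (self.neck_length + 0.6 * self.head_radius) * axis
        lt_center = np.array(
            [shaft_x + m * (self.shaft_radius + 2.0), y_c, shaft_top - self.lesser_trochanter_offset]
        )
        lt_semi = np.array([9.0, 8.0, 10.0]) * (self.shaft_radius / 11.0)
        gt_center = np.array([shaft_x - m * 4.0, y_c, shaft_top + 2.0])
        gt_semi = np.array([13.0, 12.0, 11.0]) * (self.shaft_radius / 11.0)
        return dict(
            shaft_x=shaft_x,
            y_c=y_c,
            shaft_top=shaft_top,
            shaft_bot=shaft_bot,
            neck_axis=axis,
            neck_base=neck_base,
            head_center=head_center,
            neck_center=neck_base + 0.5 * self.neck_length * axis,
            lt_center=lt_center,
            lt_semi=lt_semi,
            gt_center=gt_center,
            gt_semi=gt_semi,
        )

    def _check_fits(self) -> None:
        g = self.geometry()
        ex, ey, ez = self.extent
        margin = 2.0 * max(self.voxel_spacing)
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)

        def extend(center, radius):
            nonlocal lo, hi
            c = np.asarray(center, float)
            r = np.asarray(radius, float)
            lo = np.minimum(lo, c - r)
            hi = np.maximum(hi, c + r)

        extend(g["head_center"], self.head_radius)
        extend(g["neck_base"], self.neck_radius)
        extend(g["neck_base"] + self.neck_length * g["neck_axis"], self.neck_radius)
        extend([g["shaft_x"], g["y_c"], g["shaft_bot"]], [self.shaft_radius, self.shaft_radius, 0])
        extend([g["shaft_x"], g["y_c"], g["shaft_top"]], [self.shaft_radius, self.shaft_radius, 0])
        extend(g["lt_center"], g["lt_semi"])
        extend(g["gt_center"], g["gt_semi"])
        if np.any(lo < margin) or np.any(hi > np.array([ex, ey, ez]) - margin):
            raise ValueError(
                f"femur geometry [{lo}, {hi}] does not fit strictly inside the "
                f"grid extent {self.extent} (margin {margin} mm)"
            )

    def scaled(self, scale: float) -> "PhantomSpec":
        """Geometrically scaled copy (same voxel spacing, proportional grid)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        shape = tuple(max(32, int(round(n * scale))) for n in self.grid_shape)
        return replace(
            self,
            grid_shape=shape,
            head_radius=self.head_radius * scale,
            neck_radius=self.neck_radius * scale,
            neck_length=self.neck_length * scale,
            shaft_radius=self.shaft_radius * scale,
            lesser_trochanter_offset=self.lesser_trochanter_offset * scale,
        )


@dataclass
class GroundTruth:
    """Truth channel for the rendered phantom (landmarks in mm, LPS)."""

    femur_mask: MaskVolume
    cut_plane_z: int
    head_center: np.ndarray
    neck_center: np.ndarray
    neck_axis: np.ndarray
    labels: np.ndarray  # per-voxel composition codes (LABEL_*)

    def composition_counts(self, mask: np.ndarray | None = None) -> dict[str, int]:
        lab = self.labels if mask is None else self.labels[mask]
        return {
            "cortical": int(np.sum(lab == LABEL_CORTICAL)),
            "trabecular": int(np.sum(lab == LABEL_TRABECULAR)),
            "red_marrow": int(np.sum(lab == LABEL_RED_MARROW)),
            "fat": int(np.sum(lab == LABEL_FAT)),
        }


def _capsule_mask(xx, yy, zz, p0, p1, radius) -> np.ndarray:
    d = p1 - p0
    L2 = float(d @ d)
    px, py, pz = xx - p0[0], yy - p0[1], zz - p0[2]
    t = (px * d[0] + py * d[1] + pz * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    cx, cy, cz = px - t * d[0], py - t * d[1], pz - t * d[2]
    return cx * cx + cy * cy + cz * cz <= radius * radius


def render_phantom(
    profile: SubjectProfile, spec: PhantomSpec | None = None, seed: int | None = None
) -> tuple[CTVolume, GroundTruth]:
    """Render one subject's proximal-femur CT volume with exact ground truth.

    Same (profile, spec, seed) reproduces the volume bit-identically. With
    ``noise_sd = 0`` every voxel's HU equals its tissue constant, so HU
    histogram fractions inside any region equal the planted label fractions
    exactly.
    """
    spec = spec or PhantomSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if spec.anatomy_scale_sd > 0:
        # per-subject femur size; clipped so the geometry stays inside the grid
        s = 1.0 + float(
            np.clip(rng.normal(0.0, spec.anatomy_scale_sd), -3 * spec.anatomy_scale_sd,
                    3 * spec.anatomy_scale_sd)
        )
        spec = replace(
            spec,
            head_radius=spec.head_radius * s,
            neck_radius=spec.neck_radius * s,
            neck_length=spec.neck_length * s,
            shaft_radius=spec.shaft_radius * s,
            lesser_trochanter_offset=spec.lesser_trochanter_offset * s,
        )
    g = spec.geometry()
    sx, sy, sz = spec.voxel_spacing
    nx, ny, nz = spec.grid_shape

    xx = (np.arange(nx, dtype=np.float32) * sx)[:, None, None]
    yy = (np.arange(ny, dtype=np.float32) * sy)[None, :, None]
    zz = (np.arange(nz, dtype=np.float32) * sz)[None, None, :]

    hc = g["head_center"]
    head = (xx - hc[0]) ** 2 + (yy - hc[1]) ** 2 + (zz - hc[2]) ** 2 <= spec.head_radius**2
    neck = _capsule_mask(
        xx, yy, zz, g["neck_base"], g["neck_base"] + spec.neck_length * g["neck_axis"], spec.neck_radius
    )
    shaft = (
        ((xx - g["shaft_x"]) ** 2 + (yy - g["y_c"]) ** 2 <= spec.shaft_radius**2)
        & (zz >= g["shaft_bot"])
        & (zz <= g["shaft_top"])
    )
    lt = (
        ((xx - g["lt_center"][0]) / g["lt_semi"][0]) ** 2
        + ((yy - g["lt_center"][1]) / g["lt_semi"][1]) ** 2
        + ((zz - g["lt_center"][2]) / g["lt_semi"][2]) ** 2
    ) <= 1.0
    gt_boss = (
        ((xx - g["gt_center"][0]) / g["gt_semi"][0]) ** 2
        + ((yy - g["gt_center"][1]) / g["gt_semi"][1]) ** 2
        + ((zz - g["gt_center"][2]) / g["gt_semi"][2]) ** 2
    ) <= 1.0
    femur = head | neck | shaft | lt | gt_boss

    # Cortical shell: all femur voxels within cortical_thickness of background.
    # Thickness >= max spacing guarantees the shell seals the interior for
    # 6-connected hole filling.
    dist_in = bbox_edt(femur, spec.voxel_spacing)
    cortex = femur & (dist_in <= max(spec.cortical_thickness, max(spec.voxel_spacing)))
    interior = femur & ~cortex

    # Interior composition: one uniform field, two moving thresholds. With a
    # fixed seed the fat set shrinks and the trabecular set grows monotonically
    # as BMD increases.
    q_fat = profile.marrow_fat_fraction
    denom = spec.hu_trabecular_ref - spec.hu_red_marrow
    q_bone = (
        profile.trabecular_hu_mean
        - spec.hu_red_marrow
        - q_fat * (spec.hu_fat - spec.hu_red_marrow)
    ) / denom
    q_bone = min(max(q_bone, 0.0), 1.0 - q_fat)

    n_interior = int(np.sum(interior))
    u = rng.random(n_interior)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[cortex] = LABEL_CORTICAL
    interior_labels = np.full(n_interior, LABEL_RED_MARROW, dtype=np.uint8)
    interior_labels[u < q_fat] = LABEL_FAT
    interior_labels[u >= 1.0 - q_bone] = LABEL_TRABECULAR
    labels[interior] = interior_labels

    hu_of = np.array(
        [
            spec.hu_soft_tissue,
            spec.hu_cortical,
            spec.hu_trabecular_ref,
            spec.hu_red_marrow,
            spec.hu_fat,
        ],
        dtype=np.float32,
    )
    values = hu_of[labels]
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape).astype(np.float32)
    values = values.astype(np.float32)

    vol = CTVolume(values, spec.voxel_spacing)
    mask = MaskVolume.like(vol, femur)

    lt_outside_shaft = lt & ~shaft & ~gt_boss
    if np.any(lt_outside_shaft):
        cut_plane_z = int(np.min(np.nonzero(np.any(lt_outside_shaft, axis=(0, 1)))[0]))
    else:  # degenerate scaling: fall back to the analytic inferior margin
        cut_plane_z = int(math.ceil((g["lt_center"][2] - g["lt_semi"][2]) / sz))

    truth = GroundTruth(
        femur_mask=mask,
        cut_plane_z=cut_plane_z,
        head_center=np.asarray(hc, dtype=float),
        neck_center=np.asarray(g["neck_center"], dtype=float),
        neck_axis=np.asarray(g["neck_axis"], dtype=float),
        labels=labels,
    )
    return vol, truth
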