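"""End-to-end pipeline: simulate -> segment -> reformat -> measure -> report.

One root seed drives every stage through per-subject spawned random streams,
so identical configuration reproduces the report exactly. The reliability
experiment re-measures each subject under two simulated "observers" whose
region-growing seed point, cut-plane placement and ROI center are
independently jittered, emulating the interactive steps a radiologist
performs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import measurement as meas
from . import reformation as ref
from . import segmentation as seg
from . import stats as dstats
from .phantom import (
    DEFAULT_COHORT_PARAMS,
    OSTEOPOROSIS,
    CohortParams,
    CouplingConfig,
    PhantomSpec,
    SubjectProfile,
    render_phantom,
    sample_cohort,
)

log = logging.getLogger("femhu")

INDEXES = ("mean_hu", "huha_fat", "huha_bone")
INDEX_DIRECTIONS = {
    "mean_hu": dstats.POSITIVE_IF_LOW,
    "huha_fat": dstats.POSITIVE_IF_HIGH,
    "huha_bone": dstats.POSITIVE_IF_LOW,
}
PREFIXES = (meas.PREFIX_2D, meas.PREFIX_3D)


@dataclass(frozen=True)
class ObserverConfig:
    """Magnitudes of the simulated interobserver perturbations."""

    seed_jitter_vox: int = 2
    roi_jitter_mm: float = 2.0
    cut_jitter_slices: float = 1.0

    def __post_init__(self) -> None:
        if self.seed_jitter_vox < 0 or self.roi_jitter_mm < 0 or self.cut_jitter_slices < 0:
            raise ValueError("jitter magnitudes must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    n_osteo: int = 96
    n_non: int = 334
    cohort_params: CohortParams = DEFAULT_COHORT_PARAMS
    coupling: CouplingConfig = CouplingConfig()
    phantom: PhantomSpec = PhantomSpec()
    hu_low: float = 126.0
    hu_high: float = 3071.0
    connectivity: int = 26
    plane_extent: tuple[float, float] = (80.0, 80.0)
    plane_pixel_spacing: tuple[float, float] = (0.67, 0.67)
    observer: ObserverConfig = ObserverConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (
            ("cohort_params", CohortParams),
            ("coupling", CouplingConfig),
            ("phantom", PhantomSpec),
            ("observer", ObserverConfig),
        ):
            if key in raw:
                val = raw.pop(key)
                if key == "cohort_params":
                    from .phantom import GroupParams

                    val = CohortParams(
                        osteoporosis=GroupParams(**val["osteoporosis"]),
                        non_osteoporosis=GroupParams(**val["non_osteoporosis"]),
                        age_min=val.get("age_min", 50.0),
                    )
                else:
                    for tup in ("voxel_spacing", "grid_shape", "bmd_range",
                                "fat_fraction_range", "bone_fraction_range"):
                        if isinstance(val, dict) and tup in val:
                            val[tup] = tuple(val[tup])
                    val = sub(**val)
                kwargs[key] = val
        for tup in ("plane_extent", "plane_pixel_spacing"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def find_seed_point(volume, hu_low: float, hu_high: float, jitter=None, rng=None):
    """Deterministic bone seed: the global HU maximum (always cortical), with
    optional observer jitter snapped back to the nearest in-band voxel."""
    idx = np.asarray(np.unravel_index(int(np.argmax(volume.values)), volume.values.shape))
    if jitter and rng is not None:
        idx = idx + rng.integers(-jitter, jitter + 1, size=3)
        idx = np.clip(idx, 0, np.asarray(volume.values.shape) - 1)
        if not (hu_low <= volume.values[tuple(idx)] <= hu_high):
            # snap to the nearest in-band voxel within a small neighborhood
            lo = np.maximum(idx - 3, 0)
            hi = np.minimum(idx + 4, volume.values.shape)
            sub = volume.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            cand = np.argwhere((sub >= hu_low) & (sub <= hu_high))
            if len(cand) == 0:
                idx = np.asarray(np.unravel_index(int(np.argmax(volume.values)), volume.values.shape))
            else:
                d = np.linalg.norm(cand + lo - idx, axis=1)
                idx = cand[int(np.argmin(d))] + lo
    return tuple(int(i) for i in idx)


def measure_subject(
    profile: SubjectProfile,
    config: RunConfig,
    render_seed: int,
    observer_rng: np.random.Generator | None = None,
) -> tuple[dict, dict]:
    """Run the full imaging chain for one subject; returns (2D row, 3D row).

    ``observer_rng`` switches on the interactive-step jitter used by the
    reliability experiment.
    """
    vol, _truth = render_phantom(profile, config.phantom, seed=render_seed)
    obs = config.observer if observer_rng is not None else None

    seed_pt = find_seed_point(
        vol, config.hu_low, config.hu_high,
        jitter=(obs.seed_jitter_vox if obs else 0), rng=observer_rng,
    )
    grown = seg.region_grow(
        vol, seg.RegionGrowConfig(seed_pt, config.hu_low, config.hu_high, config.connectivity)
    )
    filled = seg.fill_interior(grown)
    cut = seg.detect_cut_plane(filled, medial_sign=config.phantom.medial_sign)
    if obs and obs.cut_jitter_slices > 0:
        cut = int(np.clip(cut + round(observer_rng.normal(0.0, obs.cut_jitter_slices)),
                          0, vol.values.shape[2] - 1))
    voi = seg.crop_to_voi(filled, cut)
    rec3d = meas.measure_voi(vol, voi, subject_id=profile.subject_id)

    head = ref.estimate_head_center(filled)
    frame = ref.estimate_neck_frame(filled, head)
    center = frame.neck_center
    roi_center = (0.0, 0.0)
    if obs and obs.roi_jitter_mm > 0:
        off = observer_rng.normal(0.0, obs.roi_jitter_mm, size=3)
        center = frame.neck_center + off[2] * frame.normal
        roi_center = (float(off[0]), float(off[1]))
    plane = ref.reformat_plane(
        vol, frame, extent=config.plane_extent,
        pixel_spacing=config.plane_pixel_spacing, mask=filled, center=center,
    )
    roi = meas.largest_inscribed_circle(plane, center=roi_center)
    rec2d = meas.measure_roi(plane, roi, subject_id=profile.subject_id)

    def row(rec):
        return dict(
            subject_id=rec.subject_id,
            prefix=rec.prefix,
            huha_fat=rec.result.huha_fat,
            huha_bone=rec.result.huha_bone,
            huha_mid=rec.result.huha_mid,
            mean_hu=rec.result.mean_hu,
            n=rec.result.n,
            size=rec.size,
            size_unit=rec.size_unit,
        )

    return row(rec2d), row(rec3d)


def cohort_table(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            subject_id=[p.subject_id for p in profiles],
            age=[p.age for p in profiles],
            bmd=[p.bmd for p in profiles],
            t_score=[p.t_score for p in profiles],
            group=[p.group for p in profiles],
        )
    )


def measure_cohort(profiles, config: RunConfig) -> pd.DataFrame:
    """Measurements (both prefixes, all indexes) for every subject."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(len(profiles))
    rows = []
    for i, (p, ss) in enumerate(zip(profiles, seeds)):
        render_seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            r2, r3 = measure_subject(p, config, render_seed)
        except Exception as e:
            raise RuntimeError(f"subject {p.subject_id}: pipeline stage failed: {e}") from e
        rows.extend([r2, r3])
        if (i + 1) % 50 == 0:
            log.info("measured %d/%d subjects", i + 1, len(profiles))
    return pd.DataFrame(rows)


@dataclass
class DiagnosticReport:
    """Machine twin of the study's report tables (ROC/cutoffs, correlations,
    group summaries, box plots), serializable losslessly to JSON."""

    config: dict
    cohort: pd.DataFrame
    measurements: pd.DataFrame
    roc: dict = field(default_factory=dict)          # "prefix-index" -> RocResult
    corr: dict = field(default_factory=dict)         # "prefix-index" -> {vs_t_score, vs_bmd}
    group_p: dict = field(default_factory=dict)      # variable -> p-value
    boxplot: dict = field(default_factory=dict)      # "prefix-index-group" -> 5-number
    delong_2d_vs_3d: dict = field(default_factory=dict)  # index -> DelongResult

    def to_json(self) -> str:
        payload = dict(
            config=self.config,
            cohort=self.cohort.to_dict(orient="list"),
            measurements=self.measurements.to_dict(orient="list"),
            roc={k: dataclasses.asdict(v) for k, v in self.roc.items()},
            corr={
                k: {kk: dataclasses.asdict(vv) for kk, vv in v.items()}
                for k, v in self.corr.items()
            },
            group_p=self.group_p,
            boxplot={k: list(v) for k, v in self.boxplot.items()},
            delong_2d_vs_3d={k: dataclasses.asdict(v) for k, v in self.delong_2d_vs_3d.items()},
        )
        return json.dumps(payload, sort_keys=True, default=_json_default)

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticReport":
        raw = json.loads(text)
        rep = cls(
            config=raw["config"],
            cohort=pd.DataFrame(raw["cohort"]),
            measurements=pd.DataFrame(raw["measurements"]),
            group_p=raw["group_p"],
            boxplot={k: tuple(v) for k, v in raw["boxplot"].items()},
        )
        rep.roc = {
            k: dstats.RocResult(**{**v, "ci95": tuple(v["ci95"])}) for k, v in raw["roc"].items()
        }
        rep.corr = {
            k: {kk: dstats.CorrResult(**{**vv, "ci95": tuple(vv["ci95"])}) for kk, vv in v.items()}
            for k, v in raw["corr"].items()
        }
        rep.delong_2d_vs_3d = {k: dstats.DelongResult(**v) for k, v in raw["delong_2d_vs_3d"].items()}
        return rep

    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _index_scores(measurements: pd.DataFrame, cohort: pd.DataFrame, prefix: str, index: str):
    sub = measurements[measurements.prefix == prefix].set_index("subject_id")
    ordered = sub.loc[cohort.subject_id, index].to_numpy(dtype=float)
    labels = (cohort.group == OSTEOPOROSIS).to_numpy()
    return ordered, labels


def build_report(config: RunConfig, cohort: pd.DataFrame, measurements: pd.DataFrame) -> DiagnosticReport:
    """Assemble ROC/Youden, correlation, group-test and box-plot tables."""
    rep = DiagnosticReport(config=config.to_dict(), cohort=cohort, measurements=measurements)
    labels = (cohort.group == OSTEOPOROSIS).to_numpy()
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    for prefix in PREFIXES:
        for index in INDEXES:
            key = f"{prefix}-{index}"
            scores, _ = _index_scores(measurements, cohort, prefix, index)
            direction = INDEX_DIRECTIONS[index]
            base = dstats.auc_mann_whitney(scores, labels, direction)
            cutoff, sens, spec = dstats.youden_cutoff(scores, labels, direction)
            pred = (scores <= cutoff) if direction == dstats.POSITIVE_IF_LOW else (scores > cutoff)
            tp = int(np.sum(pred & labels))
            fp = int(np.sum(pred & ~labels))
            tn = n_neg - fp
            fn = n_pos - tp
            rep.roc[key] = dstats.RocResult(
                auc=base.auc, ci95=base.ci95, direction=direction, cutoff=cutoff,
                sens=sens, spec=spec,
                ppv=100.0 * tp / (tp + fp) if tp + fp else None,
                npv=100.0 * tn / (tn + fn) if tn + fn else None,
                p_value=base.p_value,
            )
            rep.corr[key] = dict(
                vs_t_score=dstats.spearman_with_ci(scores, cohort.t_score.to_numpy()),
                vs_bmd=dstats.spearman_with_ci(scores, cohort.bmd.to_numpy()),
            )
            rep.group_p[key] = dstats.group_difference_test(scores, labels)
            for grp in (OSTEOPOROSIS, "non-osteoporosis"):
                sel = labels if grp == OSTEOPOROSIS else ~labels
                rep.boxplot[f"{key}-{grp}"] = dstats.boxplot_summary(scores[sel])
    for var in ("age", "bmd", "t_score"):
        rep.group_p[var] = dstats.group_difference_test(cohort[var].to_numpy(), labels)
    for index in INDEXES:
        s2, _ = _index_scores(measurements, cohort, meas.PREFIX_2D, index)
        s3, _ = _index_scores(measurements, cohort, meas.PREFIX_3D, index)
        d = INDEX_DIRECTIONS[index]
        rep.delong_2d_vs_3d[index] = dstats.delong_test(s2, s3, labels, d, d)
    return rep


def run_pipeline(config: RunConfig) -> DiagnosticReport:
    """Simulate the cohort, measure every subject, and build the report."""
    log.info("sampling cohort: %d osteoporotic / %d non-osteoporotic, seed %d",
             config.n_osteo, config.n_non, config.seed)
    profiles = sample_cohort(
        config.n_osteo, config.n_non, config.cohort_params, seed=config.seed,
        coupling=config.coupling,
    )
    cohort = cohort_table(profiles)
    measurements = measure_cohort(profiles, config)
    return build_report(config, cohort, measurements)


RELIABILITY_VARIABLES = ("size", "mean_hu", "huha_fat", "huha_bone")


def run_reliability(config: RunConfig, n_subjects: int = 50) -> pd.DataFrame:
    """Two simulated observers measure ``n_subjects`` subjects each; returns the
    ICC(A,1) table (8 rows: size + three indexes for both prefixes)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    n_osteo = max(1, round(n_subjects * config.n_osteo / max(config.n_osteo + config.n_non, 1)))
    profiles = sample_cohort(
        n_osteo, n_subjects - n_osteo, config.cohort_params,
        seed=config.seed + 1, coupling=config.coupling,
    )
    root = np.random.SeedSequence(config.seed)
    ratings: dict[tuple[str, str], np.ndarray] = {
        (p, v): np.zeros((n_subjects, 2)) for p in PREFIXES for v in RELIABILITY_VARIABLES
    }
    for i, (prof, ss) in enumerate(zip(profiles, root.spawn(len(profiles)))):
        render_seed = int(ss.generate_state(1)[0] % (2**31))
        for obs_i in range(2):
            obs_rng = np.random.default_rng(ss.spawn(1)[0])
            r2, r3 = measure_subject(prof, config, render_seed, observer_rng=obs_rng)
            for row in (r2, r3):
                for var in RELIABILITY_VARIABLES:
                    ratings[(row["prefix"], var)][i, obs_i] = row[var]
    rows = []
    for prefix in PREFIXES:
        for var in RELIABILITY_VARIABLES:
            table = ratings[(prefix, var)]
            if np.allclose(table[:, 0], table[:, 1]) and np.ptp(table) == 0:
                raise dstats.DegenerateInputError(f"zero-variance measurements for {prefix}-{var}")
            res = dstats.icc_two_way_mixed_absolute(table)
            label = {
                "size": "Total Area" if prefix == meas.PREFIX_2D else "Total Volume",
                "mean_hu": "Mean-HU", "huha_fat": "HUHA_Fat", "huha_bone": "HUHA_Bone",
            }[var]
            rows.append(dict(prefix=prefix, variable=label, icc=res.icc,
                             ci_low=res.ci95[0], ci_high=res.ci95[1], category=res.category))
    return pd.DataFrame(rows)
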