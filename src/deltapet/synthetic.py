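"""Synthetic phantom cohorts and activity traces.

Generates two-scan-per-subject, two-group PET phantoms with planted
group-by-region uptake effects, plus frame-wise activity traces with
group-specific freezing-bout structure, so the whole downstream pipeline
is testable with no external data.

The brain is an axis-aligned ellipsoid; regions are boxes inside it
(anatomy-faithful masks are unnecessary to exercise the math).  Voxel
noise is independent Gaussian; an optional Gaussian-blur switch adds
spatial correlation for realism.  By default volumes are mean-calibrated
so the in-brain mean is exactly 1 in both sessions: region effects then
survive brain-mean normalization unchanged, which gives exact zero-noise
effect recovery downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.ndimage

from deltapet.behavior import ActivityTrace
from deltapet.errors import ConfigurationError, GenerationError
from deltapet.roi import RegionMaskSet, VolumeImage

__all__ = [
    "RegionSpec",
    "PhantomConfig",
    "SubjectScans",
    "SyntheticCohort",
    "BoutParams",
    "TraceConfig",
    "SimulatedTrace",
    "DEFAULT_REGION_SPECS",
    "DEFAULT_GROUP_EFFECTS",
    "make_phantom_cohort",
    "make_activity_traces",
    "trace_from_bouts",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class RegionSpec:
    """A box-shaped region inside the phantom brain.

    Ranges are half-open voxel index ranges.  For bilateral regions,
    ``x_range`` describes the right-hemisphere box; the left box is its
    mirror about the grid's x extent.  Single-object regions
    (``bilateral=False``) use ``x_range`` as given and are quantified as
    one object per slice spanning both hemispheres.
    """

    name: str
    x_range: tuple[int, int]
    y_range: tuple[int, int]
    z_range: tuple[int, int]
    baseline: float = 0.0  # additive uptake contrast over the brain background
    bilateral: bool = True


# Eight-region layout analogous to the amygdala / prefrontal / hippocampal /
# entorhinal node set, on the default 48 x 64 x 40 grid.  PLC and ILC are
# single-object (midline prefrontal) regions.
DEFAULT_REGION_SPECS: tuple[RegionSpec, ...] = (
    RegionSpec("BA", (30, 35), (24, 36), (12, 16)),
    RegionSpec("PLC", (21, 27), (8, 13), (17, 23), bilateral=False),
    RegionSpec("ILC", (21, 27), (13, 18), (10, 15), bilateral=False),
    RegionSpec("DH", (26, 31), (26, 34), (24, 28)),
    RegionSpec("VH", (31, 36), (36, 44), (16, 21)),
    RegionSpec("SB", (27, 32), (40, 47), (22, 26)),
    RegionSpec("LEC", (33, 38), (44, 50), (16, 20)),
    RegionSpec("MEC", (28, 33), (48, 54), (16, 20)),
)

# Default planted effects: group mean delta-SUV per region, in normalized
# uptake units, for a control-like group with enhanced amygdala/prefrontal
# uptake and a blunted group without it.
DEFAULT_GROUP_EFFECTS: dict[tuple[str, str], float] = {
    ("CON", "BA"): 0.15, ("CON", "PLC"): 0.12, ("CON", "ILC"): 0.11,
    ("CON", "LEC"): 0.059, ("CON", "DH"): -0.043, ("CON", "VH"): 0.052,
    ("CON", "SB"): 0.016, ("CON", "MEC"): 0.0086,
    ("LS", "BA"): 0.049, ("LS", "PLC"): 0.032, ("LS", "ILC"): 0.046,
    ("LS", "LEC"): -0.012, ("LS", "DH"): -0.028, ("LS", "VH"): 0.023,
    ("LS", "SB"): -0.0024, ("LS", "MEC"): -0.00075,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of a phantom PET cohort."""

    grid_shape: tuple[int, int, int] = (48, 64, 40)
    voxel_size_mm: tuple[float, float, float] = (0.78, 0.78, 0.8)
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"CON": 9, "LS": 15})
    region_specs: tuple[RegionSpec, ...] = DEFAULT_REGION_SPECS
    group_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    noise_sd: float = 0.02
    seed: int = 0
    brain_baseline: float = 1.0
    brain_semiaxes_frac: tuple[float, float, float] = (0.42, 0.46, 0.42)
    calibrate_mean: bool = True
    smooth_fwhm_mm: float = 0.0
    bregma_origin_mm: float = 2.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError(f"non-positive grid {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel_size_mm components must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(n < 1 for n in self.n_subjects_per_group.values()):
            raise ConfigurationError("need >= 1 subject per group")
        names = [s.name for s in self.region_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate region names")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.n_subjects_per_group)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_effects"] = {f"{g}:{r}": e for (g, r), e in self.group_effects.items()}
        return d


@dataclass(frozen=True)
class SubjectScans:
    subject_id: str
    group: str
    f1: VolumeImage
    f3: VolumeImage


@dataclass
class SyntheticCohort:
    """Generated cohort with shared masks and full provenance."""

    subjects: list[SubjectScans]
    brain_mask: np.ndarray
    mask_set: RegionMaskSet
    config: PhantomConfig

    @property
    def groups(self) -> dict[str, list[SubjectScans]]:
        out: dict[str, list[SubjectScans]] = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s)
        return out


def _ellipsoid_mask(shape, semiaxes_frac) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [f * n for f, n in zip(semiaxes_frac, shape)]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _region_boxes(spec: RegionSpec, nx: int) -> list[tuple[slice, slice, slice]]:
    ys = slice(*spec.y_range)
    zs = slice(*spec.z_range)
    if not spec.bilateral:
        return [(slice(*spec.x_range), ys, zs)]
    lo, hi = spec.x_range
    return [(slice(nx - hi, nx - lo), ys, zs), (slice(lo, hi), ys, zs)]


def _paint_labels(config: PhantomConfig, brain: np.ndarray) -> tuple[np.ndarray, dict[int, str]]:
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    names: dict[int, str] = {}
    nx = config.grid_shape[0]
    for i, spec in enumerate(config.region_specs, start=1):
        names[i] = spec.name
        for box in _region_boxes(spec, nx):
            target = labels[box]
            if np.any(target != 0):
                clash = {names[v] for v in np.unique(target) if v != 0}
                raise ConfigurationError(
                    f"region {spec.name} overlaps {sorted(clash)}")
            if not np.all(brain[box]):
                raise ConfigurationError(
                    f"region {spec.name} extends outside the brain ellipsoid")
            labels[box] = i
    return labels, names


def make_phantom_cohort(config: PhantomConfig) -> SyntheticCohort:
    """Generate F1/F3 volumes per subject with planted group effects.

    F1 = baseline + noise; F3 = baseline + group effect in each region +
    noise, with the in-brain mean held constant via a compensating shift
    of the non-region background (so the effect survives brain-mean
    normalization).  Values outside the brain mask are zero.
    Reproducible bit-for-bit from (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    brain = _ellipsoid_mask(config.grid_shape, config.brain_semiaxes_frac)
    labels, names = _paint_labels(config, brain)
    single = tuple(s.name for s in config.region_specs if not s.bilateral)
    mask_set = RegionMaskSet.from_label_volume(
        labels, names, brain_mask=brain, single_object_regions=single)

    base = np.zeros(config.grid_shape)
    base[brain] = config.brain_baseline
    for i, spec in enumerate(config.region_specs, start=1):
        base[labels == i] += spec.baseline
    if config.calibrate_mean:
        base[brain] += 1.0 - base[brain].mean()

    background = brain & (labels == 0)
    n_background = int(background.sum())

    # Per-group F3 effect field plus mean-preserving background compensation.
    effect_fields: dict[str, np.ndarray] = {}
    for group in config.groups:
        eff = np.zeros(config.grid_shape)
        total = 0.0
        for i, spec in enumerate(config.region_specs, start=1):
            e = config.group_effects.get((group, spec.name), 0.0)
            if e:
                region_vox = labels == i
                eff[region_vox] += e
                total += e * int(region_vox.sum())
        if config.calibrate_mean and total != 0.0:
            if n_background == 0:
                raise ConfigurationError("no background voxels left to compensate effects")
            eff[background] -= total / n_background
        effect_fields[group] = eff

    sigma_vox = None
    if config.smooth_fwhm_mm > 0:
        sigma_vox = [config.smooth_fwhm_mm / (2.3548 * v) for v in config.voxel_size_mm]

    def _make_volume(field3d: np.ndarray, sid: str, session: str) -> VolumeImage:
        vox = field3d.copy()
        if config.noise_sd > 0:
            vox = vox + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        if sigma_vox is not None:
            vox = scipy.ndimage.gaussian_filter(vox, sigma_vox)
        vox[~brain] = 0.0
        return VolumeImage(voxels=vox, voxel_size_mm=config.voxel_size_mm,
                           subject_id=sid, session=session,
                           bregma_origin_mm=config.bregma_origin_mm)

    subjects: list[SubjectScans] = []
    for group in config.groups:
        for i in range(config.n_subjects_per_group[group]):
            sid = f"{group}{i:02d}"
            f1 = _make_volume(base, sid, "F1")
            f3 = _make_volume(base + effect_fields[group], sid, "F3")
            subjects.append(SubjectScans(subject_id=sid, group=group, f1=f1, f3=f3))
    return SyntheticCohort(subjects=subjects, brain_mask=brain,
                           mask_set=mask_set, config=config)


# ---------------------------------------------------------------------------
# Activity traces


@dataclass(frozen=True)
class BoutParams:
    """Freezing-bout process for one group: rate and duration distribution.

    Bouts alternate with exponentially distributed mobile gaps; the mean
    gap is derived from ``bout_rate_per_min`` so that one bout+gap cycle
    lasts ``60 / rate`` seconds on average.
    """

    bout_rate_per_min: float
    mean_bout_s: float = 6.0
    duration_dist: str = "exponential"  # or "constant"
    min_bout_s: float = 2.0

    def __post_init__(self) -> None:
        if self.bout_rate_per_min < 0 or self.mean_bout_s < 0:
            raise ConfigurationError("rates and durations must be >= 0")
        if self.duration_dist not in ("exponential", "constant"):
            raise ConfigurationError(f"unknown duration_dist {self.duration_dist!r}")
        if self.bout_rate_per_min > 0:
            if 60.0 / self.bout_rate_per_min <= self.mean_bout_s:
                raise GenerationError(
                    "bout rate too high: bouts cannot be placed without overlap")

    @property
    def mean_gap_s(self) -> float:
        if self.bout_rate_per_min == 0:
            return float("inf")
        return 60.0 / self.bout_rate_per_min - self.mean_bout_s

    @classmethod
    def from_freezing_fraction(cls, fraction: float, mean_bout_s: float = 6.0,
                               **kwargs) -> "BoutParams":
        """Parameters targeting a given long-run freezing fraction."""
        if not 0 <= fraction < 1:
            raise ConfigurationError("fraction must be in [0, 1)")
        if fraction == 0:
            return cls(bout_rate_per_min=0.0, mean_bout_s=mean_bout_s, **kwargs)
        cycle = mean_bout_s / fraction
        return cls(bout_rate_per_min=60.0 / cycle, mean_bout_s=mean_bout_s, **kwargs)


@dataclass(frozen=True)
class TraceConfig:
    """Configuration of simulated activity traces."""

    frame_rate: float = 30.0
    session_length_s: float = 480.0
    group_params: dict[str, BoutParams] = field(
        default_factory=lambda: {
            "CON": BoutParams.from_freezing_fraction(0.73),
            "LS": BoutParams.from_freezing_fraction(0.45),
        })
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"CON": 10, "LS": 18})
    activity_threshold: float = 0.1
    activity_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.session_length_s <= 0:
            raise ConfigurationError("session_length_s must be > 0")
        if self.activity_max <= self.activity_threshold:
            raise ConfigurationError("activity_max must exceed the threshold")


@dataclass(frozen=True)
class SimulatedTrace:
    """A generated trace with its ground-truth bout list."""

    trace: ActivityTrace
    group: str
    true_bouts: tuple[tuple[float, float], ...]  # (start_s, duration_s)


def _sample_bout_frames(params: BoutParams, n_frames: int, frame_rate: float,
                        rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping (start_frame, n_frames) bouts from the renewal process."""
    if params.bout_rate_per_min == 0:
        return []
    min_frames = int(np.ceil(params.min_bout_s * frame_rate))
    bouts: list[tuple[int, int]] = []
    t = int(round(rng.exponential(params.mean_gap_s) * frame_rate))
    while True:
        if params.duration_dist == "constant":
            dur_s = params.mean_bout_s
        else:
            extra = max(params.mean_bout_s - params.min_bout_s, 0.0)
            dur_s = params.min_bout_s + (rng.exponential(extra) if extra > 0 else 0.0)
        dur = max(int(round(dur_s * frame_rate)), min_frames)
        if t + dur > n_frames:
            break
        bouts.append((t, dur))
        gap = max(int(round(rng.exponential(params.mean_gap_s) * frame_rate)), 1)
        t += dur + gap
    return bouts


def trace_from_bouts(bouts_s: list[tuple[float, float]], subject_id: str,
                     session: str, config: TraceConfig,
                     rng: np.random.Generator) -> SimulatedTrace:
    """Build a trace with the given bouts planted (seconds, frame-quantized).

    Activity is 0 during bouts and uniform on (threshold, activity_max]
    elsewhere, so frame classification at the configured threshold is
    unambiguous.
    """
    fr = config.frame_rate
    n_frames = int(round(config.session_length_s * fr))
    frame_bouts = []
    prev_end = -1
    for start_s, dur_s in sorted(bouts_s):
        s = int(round(start_s * fr))
        d = int(round(dur_s * fr))
        if s <= prev_end:
            raise GenerationError("bouts overlap after frame quantization")
        if s + d > n_frames:
            raise GenerationError("bout extends past session end")
        frame_bouts.append((s, d))
        prev_end = s + d
    lo = np.nextafter(config.activity_threshold, np.inf)
    score = rng.uniform(lo, config.activity_max, size=n_frames)
    for s, d in frame_bouts:
        score[s:s + d] = 0.0
    trace = ActivityTrace(subject_id=subject_id, session=session,
                          time_s=np.arange(n_frames) / fr,
                          activity_score=score, frame_rate=fr)
    truth = tuple((s / fr, d / fr) for s, d in frame_bouts)
    return SimulatedTrace(trace=trace, group="", true_bouts=truth)


def make_activity_traces(config: TraceConfig, session: str,
                         subject_ids: dict[str, list[str]] | None = None
                         ) -> list[SimulatedTrace]:
    """Generate one trace per subject with group-specific bout structure.

    Ground-truth bout lists are returned alongside each trace for oracle
    testing.  Subject ids default to the cohort scheme ``<group><index>``;
    pass ``subject_ids`` to align with an existing cohort.
    """
    session_key = int.from_bytes(hashlib.sha256(session.encode()).digest()[:4], "little")
    rng = np.random.default_rng((config.seed, session_key))
    out: list[SimulatedTrace] = []
    for group, params in config.group_params.items():
        n = config.n_subjects_per_group.get(group, 0)
        ids = (subject_ids or {}).get(group) or [f"{group}{i:02d}" for i in range(n)]
        for sid in ids:
            fr = config.frame_rate
            n_frames = int(round(config.session_length_s * fr))
            frame_bouts = _sample_bout_frames(params, n_frames, fr, rng)
            sim = trace_from_bouts([(s / fr, d / fr) for s, d in frame_bouts],
                                   sid, session, config, rng)
            out.append(SimulatedTrace(trace=sim.trace, group=group,
                                      true_bouts=sim.true_bouts))
    return out


# ---------------------------------------------------------------------------
# Statistical calibration harnesses


def simulate_delta_table(rng: np.random.Generator, effect: float = 0.0,
                         n_a: int = 9, n_b: int = 15, rows_per_subject: int = 24,
                         subject_sd: float = 0.01, noise_sd: float = 0.02,
                         region: str = "R") -> pd.DataFrame:
    """Delta-SUV table with a planted between-group effect.

    Each subject carries a Gaussian random intercept (``subject_sd``)
    shared by its ``rows_per_subject`` object rows, plus independent
    row noise; group B additionally carries ``effect``.  Used for
    mixed-model type-I and power calibration.
    """
    recs = []
    for group, n, e in (("A", n_a, 0.0), ("B", n_b, effect)):
        for i in range(n):
            sid = f"{group}{i:02d}"
            intercept = rng.normal(0.0, subject_sd)
            values = e + intercept + rng.normal(0.0, noise_sd, rows_per_subject)
            recs.extend({"subject_id": sid, "group": group, "region": region,
                         "slice_index": j, "hemisphere": "L" if j % 2 else "R",
                         "suv_f1": 1.0, "suv_f3": 1.0 + v, "delta_suv": v}
                        for j, v in enumerate(values))
    return pd.DataFrame(recs)


def make_planted_pattern_matrix(rng: np.random.Generator, n_subjects: int = 12,
                                n_voxels: int = 400, n_loaded: int = 50,
                                effect: float = 0.5, noise_sd: float = 0.02,
                                subject_sd: float = 0.3,
                                dense_pattern: bool = True):
    """Paired-scan matrix with a planted condition-effect voxel pattern.

    Returns ``(ScanMatrix, true_pattern)``.  Each subject has a random
    baseline scan; the second condition adds ``effect * true_pattern``.
    ``dense_pattern`` draws Gaussian loadings on all voxels; otherwise
    ``n_loaded`` voxels get equal-magnitude random-sign loadings and the
    rest are exactly zero (for voxel-recovery calibration).
    """
    from deltapet.ort import ScanMatrix  # local import: avoid cycle at module load

    if dense_pattern:
        pattern = rng.normal(size=n_voxels)
    else:
        pattern = np.zeros(n_voxels)
        idx = rng.choice(n_voxels, n_loaded, replace=False)
        pattern[idx] = rng.choice([-1.0, 1.0], n_loaded)
    pattern /= np.linalg.norm(pattern)
    rows = []
    for _ in range(n_subjects):
        base = rng.normal(0.0, subject_sd, n_voxels)
        rows.append(base + rng.normal(0.0, noise_sd, n_voxels))
        rows.append(base + effect * pattern + rng.normal(0.0, noise_sd, n_voxels))
    data = np.vstack(rows)
    column_mean = data.mean(axis=0)
    matrix = ScanMatrix(data=data - column_mean,
                        subject_ids=[f"s{i:02d}" for i in range(n_subjects)],
                        conditions=("F1", "F3"), column_mean=column_mean)
    return matrix, pattern


# ---------------------------------------------------------------------------
# Fixture bundle I/O


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(cohort: SyntheticCohort,
                         traces: dict[str, list[SimulatedTrace]] | None,
                         out_dir) -> dict:
    """Write a cohort (and optional per-session traces) to disk.

    Volumes and masks go out as uncompressed NIfTI, traces and the subject
    table as CSV, plus a JSON manifest with SHA-256 checksums of every
    file.  Returns the manifest dict.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"cannot write to {out}: {exc}") from exc

    files: dict[str, str] = {}

    def _write_nifti(name: str, img: nib.Nifti1Image) -> str:
        path = out / name
        nib.save(img, str(path))
        files[name] = _sha256(path)
        return name

    mask_affine = np.diag([*cohort.config.voxel_size_mm, 1.0])
    _write_nifti("brain_mask.nii",
                 nib.Nifti1Image(cohort.brain_mask.astype(np.uint8), mask_affine))
    labels, names = cohort.mask_set.to_label_volume()
    _write_nifti("region_labels.nii", nib.Nifti1Image(labels, mask_affine))

    subject_rows = []
    for subj in cohort.subjects:
        f1_name = _write_nifti(f"{subj.subject_id}_F1.nii", subj.f1.to_nifti())
        f3_name = _write_nifti(f"{subj.subject_id}_F3.nii", subj.f3.to_nifti())
        subject_rows.append({"subject_id": subj.subject_id, "group": subj.group,
                             "f1_path": f1_name, "f3_path": f3_name})
    subjects = pd.DataFrame(subject_rows)

    trace_index: list[dict] = []
    if traces:
        for session, sims in traces.items():
            for sim in sims:
                name = f"trace_{sim.trace.subject_id}_{session}.csv"
                sim.trace.to_frame().to_csv(out / name, index=False)
                files[name] = _sha256(out / name)
                truth_name = f"true_bouts_{sim.trace.subject_id}_{session}.csv"
                pd.DataFrame(list(sim.true_bouts), columns=["start_s", "duration_s"]
                             ).to_csv(out / truth_name, index=False)
                files[truth_name] = _sha256(out / truth_name)
                trace_index.append({"subject_id": sim.trace.subject_id,
                                    "session": session, "group": sim.group,
                                    "path": name})
    subjects.to_csv(out / "subjects.csv", index=False)
    files["subjects.csv"] = _sha256(out / "subjects.csv")

    meta = {
        "region_names": {str(i): n for i, n in names.items()},
        "single_object_regions": [s.name for s in cohort.config.region_specs
                                  if not s.bilateral],
        "bregma_origin_mm": cohort.config.bregma_origin_mm,
        "config": cohort.config.to_jsonable(),
        "traces": trace_index,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    files["meta.json"] = _sha256(out / "meta.json")

    manifest = {"seed": cohort.config.seed, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
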