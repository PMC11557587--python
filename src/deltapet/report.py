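"""Pipeline orchestration and figure-style tabular outputs.

Runs behavior -> ROI -> stats -> classify -> ordinal-trend stages on a
fixture bundle (the on-disk layout written by
:func:`deltapet.synthetic.write_fixture_bundle`) and emits plot-ready
CSV/JSON tables: per-epoch group time-series (mean +/- SEM), bout
tables, network maps (per-region group-mean delta-SUV or Pearson r),
classifier reports and pattern maps.  Every output is traceable to one
upstream operation, and a run manifest records seed, versions and
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from deltapet import behavior, classify, ort, roi, stats
from deltapet.errors import DeltaPetError, InputError

__all__ = [
    "RunConfig",
    "load_bundle",
    "epoch_timeseries",
    "bout_table",
    "network_map_from_delta",
    "network_map_from_correlations",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run over a fixture bundle."""

    bundle_dir: str
    out_dir: str
    activity_threshold: float = 0.1
    epoch_s: float = 10.0
    min_bout_s: float = 2.0
    behavior_session: str = "F3"
    behavior_window: tuple[float, float] = (180.0, 480.0)
    model_kinds: tuple[str, ...] = ("linear-logistic",)
    n_scrambles: int = 0
    pattern_group: str | None = None  # default: first group in the subject table
    n_perm: int = 500
    n_boot: int = 500
    max_pcs: int = 5
    run_ort: bool = True
    run_classify: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "behavior_window" in raw:
            raw["behavior_window"] = tuple(raw["behavior_window"])
        if "model_kinds" in raw:
            raw["model_kinds"] = tuple(raw["model_kinds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["behavior_window"] = list(self.behavior_window)
        d["model_kinds"] = list(self.model_kinds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class Bundle:
    """In-memory view of an on-disk fixture bundle."""

    subjects: pd.DataFrame  # subject_id, group, f1_path, f3_path
    brain_mask: np.ndarray
    mask_set: roi.RegionMaskSet
    bregma_origin_mm: float
    traces: dict[tuple[str, str], behavior.ActivityTrace] = field(default_factory=dict)
    root: Path = Path(".")
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def volume(self, subject_id: str, session: str) -> roi.VolumeImage:
        row = self.subjects.set_index("subject_id").loc[subject_id]
        path = self.root / row["f1_path" if session == "F1" else "f3_path"]
        return roi.VolumeImage.from_nifti(path, subject_id=subject_id,
                                          session=session,
                                          bregma_origin_mm=self.bregma_origin_mm)


def load_bundle(bundle_dir) -> Bundle:
    """Read a fixture bundle (subject table, masks, traces) from disk."""
    root = Path(bundle_dir)
    if not root.is_dir():
        raise InputError(f"bundle directory not found: {root}")
    subjects = pd.read_csv(root / "subjects.csv")
    meta = json.loads((root / "meta.json").read_text())
    mask_path = root / "brain_mask.nii"
    if not mask_path.exists():
        raise InputError(f"missing mask file: {mask_path}")
    mask_img = nib.load(str(mask_path))
    brain_mask = np.asanyarray(mask_img.dataobj) > 0
    labels_img = nib.load(str(root / "region_labels.nii"))
    labels = np.asanyarray(labels_img.dataobj)
    names = {int(k): v for k, v in meta["region_names"].items()}
    mask_set = roi.RegionMaskSet.from_label_volume(
        labels, names, brain_mask=brain_mask,
        single_object_regions=tuple(meta.get("single_object_regions", ())))
    traces: dict[tuple[str, str], behavior.ActivityTrace] = {}
    for entry in meta.get("traces", []):
        frame = pd.read_csv(root / entry["path"])
        traces[(entry["subject_id"], entry["session"])] = behavior.ActivityTrace.from_frame(
            frame, subject_id=entry["subject_id"], session=entry["session"])
    return Bundle(subjects=subjects, brain_mask=brain_mask, mask_set=mask_set,
                  bregma_origin_mm=float(meta.get("bregma_origin_mm", 0.0)),
                  traces=traces, root=root, affine=np.asarray(mask_img.affine))


def epoch_timeseries(results: list[behavior.FreezingResult],
                     groups: dict[str, str], epoch_s: float = 10.0) -> pd.DataFrame:
    """Group time-series: per-epoch mean +/- SEM across subjects."""
    rows = []
    for res in results:
        for i, pct in enumerate(res.epoch_percent):
            rows.append({"epoch_index": i, "time_s": (i + 0.5) * epoch_s,
                         "group": groups[res.subject_id], "percent": pct})
    frame = pd.DataFrame(rows)
    out = (frame.groupby(["group", "epoch_index", "time_s"])["percent"]
           .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
           .reset_index())
    return out


def bout_table(results: list[behavior.FreezingResult],
               groups: dict[str, str]) -> pd.DataFrame:
    """Lollipop-style bout table: one row per bout."""
    rows = []
    for res in results:
        for start_s, duration_s in res.bouts:
            rows.append({"subject_id": res.subject_id, "group": groups[res.subject_id],
                         "session": res.session, "start_s": start_s,
                         "duration_s": duration_s})
    return pd.DataFrame(rows, columns=["subject_id", "group", "session",
                                       "start_s", "duration_s"])


def network_map_from_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Node values: mean delta-SUV per (region, group)."""
    rows = []
    for group in sorted(table["group"].unique()):
        for region in sorted(table["region"].unique()):
            rows.append({"region": region, "group": group,
                         "value": roi.region_group_mean(table, region, group),
                         "source": "region_group_mean"})
    return pd.DataFrame(rows)


def network_map_from_correlations(fits: list[stats.CorrelationFit]) -> pd.DataFrame:
    """Node values: Pearson r per (region, group)."""
    return pd.DataFrame([{"region": f.region, "group": f.group, "value": f.r,
                          "source": "correlate_region_behavior"} for f in fits])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest.

    Each stage's outputs are CSV/JSON (NIfTI for voxel maps); any stage
    error halts the run with a stage-named diagnostic and the manifest is
    written with ``complete: false``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "complete": False, "stages": {},
                      "config": dataclasses.asdict(config)}
    outputs: list[Path] = []
    t_start = time.time()

    def _finish_stage(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    def _emit_csv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format="%.12g")
        outputs.append(path)

    try:
        t0 = time.time()
        bundle = load_bundle(config.bundle_dir)
        groups = dict(zip(bundle.subjects["subject_id"], bundle.subjects["group"]))
        _finish_stage("load", t0)

        # behavior
        t0 = time.time()
        behavior_means = pd.Series(dtype=float)
        if bundle.traces:
            cfg = behavior.FreezingConfig(activity_threshold=config.activity_threshold,
                                          epoch_s=config.epoch_s,
                                          min_bout_s=config.min_bout_s)
            results = [behavior.score_trace(tr, cfg)
                       for (sid, session), tr in sorted(bundle.traces.items())
                       if session == config.behavior_session]
            if results:
                _emit_csv("epoch_timeseries.csv",
                          epoch_timeseries(results, groups, config.epoch_s))
                _emit_csv("bouts.csv", bout_table(results, groups))
                behavior_means = pd.Series(
                    {r.subject_id: behavior.window_mean(
                        r.epoch_percent, config.behavior_window, config.epoch_s)
                     for r in results}, name="mean_freezing")
                _emit_csv("behavior_summary.csv",
                          behavior_means.rename_axis("subject_id").reset_index())
        _finish_stage("behavior", t0)

        # roi
        t0 = time.time()
        suv_frames = {"F1": [], "F3": []}
        for _, row in bundle.subjects.iterrows():
            for session in ("F1", "F3"):
                vol = bundle.volume(row["subject_id"], session)
                norm = roi.normalize_to_brain_mean(vol, bundle.brain_mask)
                suv_frames[session].append(
                    roi.extract_suvs(norm, bundle.mask_set, group=row["group"]))
        f1 = pd.concat(suv_frames["F1"], ignore_index=True)
        f3 = pd.concat(suv_frames["F3"], ignore_index=True)
        delta = roi.compute_delta_suv(f1, f3)
        _emit_csv("suv_f1.csv", f1)
        _emit_csv("suv_f3.csv", f3)
        _emit_csv("delta_suv.csv", delta)
        _emit_csv("network_map_delta.csv", network_map_from_delta(delta))
        _finish_stage("roi", t0)

        # stats
        t0 = time.time()
        regions = sorted(delta["region"].unique())
        lmm = {r: stats.lmm_region_group_test(delta, r).to_dict() for r in regions}
        _write_json(out / "lmm_tests.json", lmm)
        outputs.append(out / "lmm_tests.json")
        if not behavior_means.empty:
            fits = []
            for group in sorted(delta["group"].unique()):
                sub = delta[delta["group"] == group]
                for region in regions:
                    feats = roi.subject_region_mean(sub, region)
                    try:
                        fits.append(stats.correlate_region_behavior(
                            feats, behavior_means, region=region, group=group))
                    except InputError:
                        log.warning("stats: skipping correlation for %s/%s "
                                    "(too few subjects)", region, group)
            _write_json(out / "correlations.json", [f.to_dict() for f in fits])
            outputs.append(out / "correlations.json")
            if fits:
                _emit_csv("network_map_r.csv", network_map_from_correlations(fits))
        _finish_stage("stats", t0)

        # classify
        if config.run_classify:
            t0 = time.time()
            features = classify.FeatureTable.from_delta_table(delta, tuple(regions))
            payload = {}
            for kind in config.model_kinds:
                outcome = classify.loocv_classify(features, kind, seed=config.seed)
                conf = classify.confusion_rates(outcome)
                curve = classify.roc_from_scores(outcome)
                entry = {"outcome": outcome.to_dict(),
                         "confusion": dataclasses.asdict(conf),
                         "roc": {"fpr": curve.fpr.tolist(), "tpr": curve.tpr.tolist(),
                                 "auc": curve.auc}}
                if config.n_scrambles:
                    aucs = classify.scrambled_label_control(
                        features, kind, config.n_scrambles, seed=config.seed)
                    entry["scrambled_auc"] = aucs.tolist()
                payload[kind] = entry
            _write_json(out / "classify.json", payload)
            outputs.append(out / "classify.json")
            _finish_stage("classify", t0)

        # ordinal trend
        if config.run_ort:
            t0 = time.time()
            pattern_group = config.pattern_group or bundle.subjects["group"].iloc[0]
            fit_subjects = bundle.subjects[bundle.subjects["group"] == pattern_group]
            triples = [(row["subject_id"], bundle.volume(row["subject_id"], "F1"),
                        bundle.volume(row["subject_id"], "F3"))
                       for _, row in fit_subjects.iterrows()]
            matrix = ort.build_scan_matrix(triples, bundle.brain_mask)
            perm_p, model = ort.permutation_test(matrix, n_iter=config.n_perm,
                                                 seed=config.seed,
                                                 max_pcs=config.max_pcs)
            inference = ort.bootstrap_voxel_pmap(matrix, n_boot=config.n_boot,
                                                 seed=config.seed,
                                                 max_pcs=config.max_pcs)
            all_scans = [(row["subject_id"], row["group"],
                          bundle.volume(row["subject_id"], "F1"),
                          bundle.volume(row["subject_id"], "F3"))
                         for _, row in bundle.subjects.iterrows()]
            expr = ort.nodal_expression_delta(model, all_scans, bundle.brain_mask)
            _emit_csv("nodal_expression.csv", expr.frame)
            _emit_csv("nodal_expression_delta.csv", expr.delta())
            affine = bundle.affine
            for name, values in (("ort_weights.nii", inference.signed_weights),
                                 ("ort_pmap.nii", inference.voxel_p),
                                 ("ort_significant.nii",
                                  inference.significant.astype(np.uint8))):
                vol = np.zeros(bundle.brain_mask.shape, dtype=np.float32)
                vol[bundle.brain_mask] = values
                nib.save(nib.Nifti1Image(vol, affine), str(out / name))
                outputs.append(out / name)
            _write_json(out / "ort_summary.json", {
                "pattern_group": pattern_group,
                "selected_components": list(model.selected),
                "ordinal_statistic": inference.ordinal_statistic,
                "n_subjects": inference.n_subjects,
                "permutation_p": perm_p,
                "n_permutations": config.n_perm,
                "n_bootstrap": config.n_boot,
                "n_significant_voxels": int(inference.significant.sum()),
            })
            outputs.append(out / "ort_summary.json")
            _finish_stage("ort", t0)

        manifest["complete"] = True
    except DeltaPetError:
        raise
    finally:
        manifest["outputs"] = {p.name: _sha256(p) for p in outputs if p.exists()}
        manifest["total_seconds"] = round(time.time() - t_start, 3)
        try:
            import importlib.metadata
            manifest["versions"] = {
                pkg: importlib.metadata.version(pkg)
                for pkg in ("deltapet", "numpy", "scipy", "pandas",
                            "scikit-learn", "statsmodels", "nibabel")}
        except Exception:
            pass
        _write_json(out / "manifest.json", manifest)
    return manifest
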