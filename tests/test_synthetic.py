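import json

import numpy as np
import pytest

from deltapet import behavior, roi, synthetic
from deltapet.errors import ConfigurationError, GenerationError
from deltapet.synthetic import (
    BoutParams,
    PhantomConfig,
    RegionSpec,
    TraceConfig,
    make_activity_traces,
    make_phantom_cohort,
    trace_from_bouts,
    write_fixture_bundle,
)


class TestPhantomConfig:
    def test_defaults_valid(self):
        cohort = make_phantom_cohort(PhantomConfig(
            n_subjects_per_group={"CON": 1, "LS": 1}, noise_sd=0.0))
        assert len(cohort.subjects) == 2

    def test_non_positive_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(grid_shape=(0, 10, 10))

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(noise_sd=-0.1)

    def test_overlapping_regions_rejected(self):
        specs = (RegionSpec("A", (20, 26), (20, 30), (16, 22)),
                 RegionSpec("B", (22, 28), (25, 35), (18, 24)))
        with pytest.raises(ConfigurationError, match="overlaps"):
            make_phantom_cohort(PhantomConfig(region_specs=specs,
                                              n_subjects_per_group={"X": 1}))

    def test_region_outside_brain_rejected(self):
        specs = (RegionSpec("A", (0, 4), (0, 6), (0, 4)),)
        with pytest.raises(ConfigurationError, match="outside"):
            make_phantom_cohort(PhantomConfig(region_specs=specs,
                                              n_subjects_per_group={"X": 1}))


class TestPhantomCohort:
    def test_zero_noise_zero_effect_identity(self):
        config = PhantomConfig(n_subjects_per_group={"A": 2}, noise_sd=0.0,
                               group_effects={})
        cohort = make_phantom_cohort(config)
        for subj in cohort.subjects:
            assert np.array_equal(subj.f1.voxels, subj.f3.voxels)

    def test_zero_noise_planted_effect_exact(self):
        config = PhantomConfig(
            n_subjects_per_group={"A": 2, "B": 2}, noise_sd=0.0,
            group_effects={("A", "BA"): 0.15})
        cohort = make_phantom_cohort(config)
        ba = [o for o in cohort.mask_set.objects_for("BA")]
        for subj in cohort.subjects:
            deltas = [subj.f3.voxels[:, o.slice_index, :][o.mask].mean()
                      - subj.f1.voxels[:, o.slice_index, :][o.mask].mean()
                      for o in ba]
            expected = 0.15 if subj.group == "A" else 0.0
            assert np.allclose(deltas, expected, atol=1e-12)

    def test_in_brain_mean_calibrated_to_one(self):
        cohort = make_phantom_cohort(PhantomConfig(
            n_subjects_per_group={"A": 1, "B": 1}, noise_sd=0.0))
        for subj in cohort.subjects:
            for vol in (subj.f1, subj.f3):
                assert vol.voxels[cohort.brain_mask].mean() == pytest.approx(1.0, abs=1e-12)
                assert (vol.voxels[~cohort.brain_mask] == 0).all()

    def test_noisy_effect_within_standard_error_bound(self):
        noise_sd = 0.05
        config = PhantomConfig(n_subjects_per_group={"A": 20}, noise_sd=noise_sd,
                               group_effects={("A", "BA"): 0.15}, seed=5)
        cohort = make_phantom_cohort(config)
        objects = cohort.mask_set.objects_for("BA")
        m = sum(int(o.mask.sum()) for o in objects)
        deltas = []
        for subj in cohort.subjects:
            for o in objects:
                deltas.append(subj.f3.voxels[:, o.slice_index, :][o.mask].mean()
                              - subj.f1.voxels[:, o.slice_index, :][o.mask].mean())
        # mean over n subjects x all mask voxels; bound 3 * sqrt(2) * sd / sqrt(n*m)
        se = np.sqrt(2) * noise_sd / np.sqrt(20 * m)
        assert abs(np.mean(deltas) - 0.15) < 3 * se

    def test_determinism(self):
        config = PhantomConfig(n_subjects_per_group={"A": 2}, noise_sd=0.03, seed=9)
        a = make_phantom_cohort(config)
        b = make_phantom_cohort(config)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.f1.voxels, sb.f1.voxels)
            assert np.array_equal(sa.f3.voxels, sb.f3.voxels)

    def test_masks_inside_brain_and_disjoint(self, small_cohort):
        labels, _ = small_cohort.mask_set.to_label_volume()
        assert not np.any((labels > 0) & ~small_cohort.brain_mask)

    def test_smoothing_switch(self):
        import scipy.ndimage

        config = PhantomConfig(n_subjects_per_group={"A": 1}, noise_sd=0.05,
                               smooth_fwhm_mm=1.6, seed=3)
        cohort = make_phantom_cohort(config)
        smooth = cohort.subjects[0].f1.voxels
        rough = make_phantom_cohort(
            PhantomConfig(n_subjects_per_group={"A": 1}, noise_sd=0.05, seed=3)
        ).subjects[0].f1.voxels
        # blur reduces voxel noise deep inside the brain (edges attenuate)
        interior = scipy.ndimage.binary_erosion(cohort.brain_mask, iterations=4)
        assert smooth[interior].std() < rough[interior].std()


class TestActivityTraces:
    def test_zero_rate_no_freezing(self):
        cfg = TraceConfig(group_params={"A": BoutParams(bout_rate_per_min=0.0)},
                          n_subjects_per_group={"A": 3}, session_length_s=60)
        for sim in make_activity_traces(cfg, "F3"):
            assert sim.true_bouts == ()
            assert (sim.trace.activity_score > cfg.activity_threshold).all()

    def test_single_planted_bout_recovered(self, rng):
        cfg = TraceConfig(session_length_s=60)
        sim = trace_from_bouts([(10.0, 5.0)], "s1", "F3", cfg, rng)
        mask = behavior.score_inactivity(
            sim.trace, behavior.FreezingConfig(activity_threshold=cfg.activity_threshold))
        assert behavior.detect_bouts(mask, cfg.frame_rate) == [(10.0, 5.0)]

    def test_ground_truth_matches_detection(self):
        cfg = TraceConfig(n_subjects_per_group={"CON": 3, "LS": 3}, seed=21)
        for sim in make_activity_traces(cfg, "F3"):
            mask = behavior.score_inactivity(
                sim.trace,
                behavior.FreezingConfig(activity_threshold=cfg.activity_threshold))
            got = behavior.detect_bouts(mask, cfg.frame_rate)
            assert [tuple(b) for b in got] == list(sim.true_bouts)

    def test_bouts_never_overlap(self):
        cfg = TraceConfig(n_subjects_per_group={"CON": 5}, seed=2)
        for sim in make_activity_traces(cfg, "F3"):
            end = -1.0
            for start, dur in sim.true_bouts:
                assert start > end
                end = start + dur
            assert sum(d for _, d in sim.true_bouts) <= cfg.session_length_s

    def test_group_freezing_targets(self):
        # targets ~73% / ~45%; window means within +/- 5 points at n = 10
        cfg = TraceConfig(n_subjects_per_group={"CON": 10, "LS": 10}, seed=4)
        fcfg = behavior.FreezingConfig(activity_threshold=cfg.activity_threshold)
        means = {"CON": [], "LS": []}
        for sim in make_activity_traces(cfg, "F3"):
            res = behavior.score_trace(sim.trace, fcfg)
            means[sim.group].append(
                behavior.window_mean(res.epoch_percent, (180.0, 480.0)))
        assert abs(np.mean(means["CON"]) - 73.0) < 5.0
        assert abs(np.mean(means["LS"]) - 45.0) < 5.0

    def test_excessive_rate_rejected(self):
        with pytest.raises(GenerationError):
            BoutParams(bout_rate_per_min=30.0, mean_bout_s=6.0)

    def test_trace_determinism(self):
        cfg = TraceConfig(n_subjects_per_group={"CON": 2}, seed=6)
        a = make_activity_traces(cfg, "F3")
        b = make_activity_traces(cfg, "F3")
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.trace.activity_score, sb.trace.activity_score)

    def test_from_freezing_fraction(self):
        params = BoutParams.from_freezing_fraction(0.5, mean_bout_s=6.0)
        assert params.mean_gap_s == pytest.approx(6.0)


class TestFixtureBundle:
    @pytest.fixture
    def bundle_dir(self, tmp_path, small_cohort):
        tcfg = TraceConfig(n_subjects_per_group={"CON": 3, "LS": 4}, seed=7,
                           session_length_s=120)
        traces = {"F3": make_activity_traces(tcfg, "F3")}
        manifest = write_fixture_bundle(small_cohort, traces, tmp_path / "bundle")
        return tmp_path / "bundle", manifest

    def test_round_trip_voxels_bit_exact(self, bundle_dir, small_cohort):
        out, _ = bundle_dir
        subj = small_cohort.subjects[0]
        back = roi.VolumeImage.from_nifti(out / f"{subj.subject_id}_F1.nii")
        assert np.array_equal(back.voxels.astype(np.float32),
                              subj.f1.voxels.astype(np.float32))

    def test_manifest_lists_one_pair_per_subject(self, bundle_dir, small_cohort):
        _, manifest = bundle_dir
        for subj in small_cohort.subjects:
            assert f"{subj.subject_id}_F1.nii" in manifest["files"]
            assert f"{subj.subject_id}_F3.nii" in manifest["files"]

    def test_same_seed_same_checksums(self, tmp_path, small_cohort):
        m1 = write_fixture_bundle(small_cohort, None, tmp_path / "b1")
        m2 = write_fixture_bundle(small_cohort, None, tmp_path / "b2")
        assert m1["files"] == m2["files"]

    def test_meta_json_well_formed(self, bundle_dir):
        out, _ = bundle_dir
        meta = json.loads((out / "meta.json").read_text())
        assert set(meta["region_names"].values()) == {
            "BA", "PLC", "ILC", "DH", "VH", "SB", "LEC", "MEC"}
        assert meta["single_object_regions"] == ["PLC", "ILC"]


class TestCalibrationHarnesses:
    def test_simulate_delta_table_shape(self, rng):
        table = synthetic.simulate_delta_table(rng, n_a=3, n_b=4,
                                               rows_per_subject=5)
        assert len(table) == 35
        assert table.groupby("subject_id").size().eq(5).all()

    def test_planted_pattern_matrix_structure(self, rng):
        matrix, pattern = synthetic.make_planted_pattern_matrix(
            rng, n_subjects=4, n_voxels=50)
        assert matrix.data.shape == (8, 50)
        assert np.linalg.norm(pattern) == pytest.approx(1.0)
        assert np.allclose(matrix.data.mean(axis=0), 0.0, atol=1e-12)

    def test_sparse_pattern_support(self, rng):
        _, pattern = synthetic.make_planted_pattern_matrix(
            rng, n_subjects=4, n_voxels=100, n_loaded=10, dense_pattern=False)
        assert (pattern != 0).sum() == 10
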