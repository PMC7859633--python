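"""Phantom/gait generators: determinism, presets, measurement closure."""

import numpy as np
import pytest

from strokequant import (
    GroundTruth,
    PhantomSpec,
    aggregate_parameters,
    breed_presets,
    diffusion_report,
    gait_changes,
    generate_gait_cohort,
    generate_phantom,
    herniation_indices,
    phantom_spec_for_breed,
    run_parameters,
    runs_from_frame,
    volumetry_report,
)


class TestPresets:
    def test_four_presets_with_printed_values(self):
        presets = breed_presets()
        assert set(presets) == {"yc-pre", "yc-post", "lr-pre", "lr-post"}
        assert presets["yc-pre"].gait["velocity"] == (205.2, 13.1)
        assert presets["yc-post"].gait_change["velocity"] == (-66.6, 21.1)
        assert presets["lr-pre"].gait["stride_length_LF"] == (76.3, 9.0)
        assert presets["lr-post"].mri["fa_change_percent"] == (-30.4, 6.6)
        assert presets["yc-post"].mri["cth"] == (0.12, 0.02)

    def test_sds_non_negative(self):
        for preset in breed_presets().values():
            for table in (preset.gait, preset.gait_change, preset.mri):
                assert all(sd >= 0 for _, sd in table.values())


class TestPhantom:
    def test_determinism(self):
        spec = PhantomSpec(spacing=2.0, noise_sd_adc=0.05, seed=9)
        b1, b2 = generate_phantom(spec), generate_phantom(spec)
        np.testing.assert_array_equal(b1.labels.data, b2.labels.data)
        np.testing.assert_array_equal(b1.adc.data, b2.adc.data)
        np.testing.assert_array_equal(b1.fa.data, b2.fa.data)
        assert b1.truth.metrics == b2.truth.metrics

    def test_lesion_volume_matches_spec(self, phantom_bundle):
        truth = phantom_bundle.truth.metrics
        assert truth["lesion_uncorrected"] == pytest.approx(10.0, rel=0.02)

    def test_symmetric_phantom_measures_zero_swelling_and_mls(self):
        spec = PhantomSpec(
            spacing=1.5, hv_contra=79.8, hv_ipsi=79.8, mls_mm=0.0, lesion_volume=0.0
        )
        bundle = generate_phantom(spec)
        vol = volumetry_report(bundle.labels)
        assert vol.swelling_percent == pytest.approx(0.0, abs=0.1)
        geo = herniation_indices(bundle.landmarks_sagittal, bundle.landmarks_axial)
        assert geo.mls_mm == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(hv_ipsi=50.0, lesion_volume=60.0)
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(spacing=1.0, hv_contra=500.0, hv_ipsi=500.0))

    def test_full_measurement_closure(self, phantom_bundle):
        """Every pipeline metric equals ground truth within stated tolerances."""
        b = phantom_bundle
        truth = b.truth.metrics
        vol = volumetry_report(b.labels, adc=b.adc)
        diff = diffusion_report(b.adc, b.fa, b.labels)
        geo = herniation_indices(b.landmarks_sagittal, b.landmarks_axial)
        assert vol.hv_ipsi == pytest.approx(truth["hv_ipsi"], rel=0.02)
        assert vol.swelling_percent == pytest.approx(truth["swelling_percent"], abs=1.0)
        assert vol.ventricle_compression_percent == pytest.approx(
            truth["ventricle_compression_percent"], abs=1.0
        )
        assert vol.lesion_uncorrected == pytest.approx(truth["lesion_uncorrected"], rel=0.02)
        assert diff.adc_change_percent == pytest.approx(truth["adc_change_percent"], abs=1.0)
        assert diff.fa_change_percent == pytest.approx(truth["fa_change_percent"], abs=1.0)
        assert geo.mls_mm == pytest.approx(truth["mls_mm"], abs=1.0)  # one voxel
        assert geo.cth == pytest.approx(truth["cth"], abs=0.005)
        assert geo.fmh == pytest.approx(truth["fmh"], abs=0.005)

    def test_breed_spec_builder_uses_printed_means(self):
        spec = phantom_spec_for_breed("yc", spacing=1.0)
        assert spec.hv_contra == pytest.approx(79.8)
        assert spec.hv_ipsi == pytest.approx(79.8 * 1.134)
        assert spec.lesion_adc_ratio == pytest.approx(0.655)
        assert spec.ttx_mm == pytest.approx(12.0)

    def test_write_roundtrip(self, tmp_path, phantom_bundle):
        from strokequant import read_image_volume, read_landmarks

        paths = phantom_bundle.write(tmp_path / "phantom")
        labels = read_image_volume(paths["labels"], scheme=phantom_bundle.scheme)
        assert labels.modality == "label"
        np.testing.assert_array_equal(labels.data, phantom_bundle.labels.data)
        lm = read_landmarks(paths["landmarks_sagittal"])
        np.testing.assert_allclose(
            lm.points["cribriform_dorsal"],
            phantom_bundle.landmarks_sagittal.points["cribriform_dorsal"],
        )
        truth = GroundTruth.from_json(paths["ground_truth"])
        assert truth.metrics == phantom_bundle.truth.metrics


class TestGaitCohort:
    def test_determinism(self):
        c1, t1 = generate_gait_cohort("yc", n_pigs=2, seed=4)
        c2, t2 = generate_gait_cohort("yc", n_pigs=2, seed=4)
        assert t1.metrics == t2.metrics
        for p1, p2 in zip(c1.pigs, c2.pigs):
            for (d1, f1), (d2, f2) in zip(p1.pre_frames, p2.pre_frames):
                assert d1 == d2
                assert f1.equals(f2)

    def test_zero_noise_extraction_inverts_generator(self):
        cohort, truth = generate_gait_cohort("lr", n_pigs=2, noise_sd_scale=0.0, seed=12)
        for pig in cohort.pigs:
            pre = aggregate_parameters(
                [(d, run_parameters(runs_from_frame(f)[0])) for d, f in pig.pre_frames], "pre"
            )
            post = aggregate_parameters(
                [("post", run_parameters(runs_from_frame(f)[0])) for f in pig.post_frames],
                "post",
            )
            for key, val in pig.params_pre.as_flat().items():
                assert pre.as_flat()[key] == pytest.approx(val, rel=1e-6)
            changes = gait_changes(post, pre)
            for key, val in pig.change.items():
                assert changes[key] == pytest.approx(val, rel=1e-6, abs=1e-9)

    def test_cohort_mean_velocity_converges_to_printed_value(self):
        cohort, _ = generate_gait_cohort("yc", n_pigs=250, seed=1, include_post=False)
        mean_v = float(np.mean([p.params_pre.velocity for p in cohort.pigs]))
        # SE = 13.1 / sqrt(250) ~ 0.83; allow ~3.5 SE
        assert mean_v == pytest.approx(205.2, abs=3.0)

    def test_csv_write_and_reparse(self, tmp_path):
        cohort, _ = generate_gait_cohort("yc", n_pigs=1, seed=2, out_dir=tmp_path)
        from strokequant import parse_footfalls

        runs = parse_footfalls(tmp_path / "yc01_pre.csv")
        assert len(runs) == 6  # 3 days x 2 runs
        runs_post = parse_footfalls(tmp_path / "yc01_post.csv")
        assert len(runs_post) == 5
        assert (tmp_path / "ground_truth.json").exists()

    def test_invalid_pig_count_rejected(self):
        with pytest.raises(ValueError):
            generate_gait_cohort("yc", n_pigs=0)
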