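"""Synthetic-data generator contracts: geometry, determinism, calibration."""

import numpy as np
import pytest

from fibromet import morpho, segment, synthgen
from fibromet.errors import OverlapError, ParameterError, ResolutionError
from fibromet.synthgen import MotilitySpec, SceneTruth, ShapeSpec


class TestShapeSpec:
    def test_class_consistency_enforced(self):
        with pytest.raises(ParameterError):
            ShapeSpec("spindle", 50.0, 0.6, (0, 0))
        with pytest.raises(ParameterError):
            ShapeSpec("signet", 50.0, 0.3, (0, 0))

    @pytest.mark.parametrize(
        "kwargs",
        [dict(target_feret=-1.0), dict(target_circularity=1.4),
         dict(peak_intensity=300), dict(geometry_class="round")],
    )
    def test_invalid_fields(self, kwargs):
        base = dict(geometry_class="signet", target_feret=35.0,
                    target_circularity=0.8, centre=(0.0, 0.0))
        base.update(kwargs)
        with pytest.raises(ParameterError):
            ShapeSpec(**base)


class TestMakeCellMask:
    def test_signet_feret_within_five_percent(self, pixel_size):
        spec = ShapeSpec("signet", 35.0, 0.9, (0, 0))
        _, realized = synthgen.make_cell_mask(spec, pixel_size)
        assert 33.25 <= realized.feret <= 36.75
        assert realized.circularity == pytest.approx(0.9, abs=0.1)

    def test_spindle_realized_indices_near_target(self, pixel_size):
        spec = ShapeSpec("spindle", 60.0, 0.25, (0, 0), orientation=0.8)
        _, realized = synthgen.make_cell_mask(spec, pixel_size)
        assert realized.feret == pytest.approx(60.0, rel=0.05)
        assert realized.circularity == pytest.approx(0.25, abs=0.1)

    def test_spindle_less_circular_than_signet_at_equal_feret(self, pixel_size):
        spindle = ShapeSpec("spindle", 50.0, 0.3, (0, 0))
        signet = ShapeSpec("signet", 50.0, 0.8, (0, 0))
        _, r_spindle = synthgen.make_cell_mask(spindle, pixel_size)
        _, r_signet = synthgen.make_cell_mask(signet, pixel_size)
        assert r_spindle.circularity < r_signet.circularity

    def test_subresolution_feret_raises(self):
        with pytest.raises(ResolutionError):
            synthgen.make_cell_mask(ShapeSpec("signet", 2.0, 0.9, (0, 0)), 1.0)

    def test_masks_are_single_components(self, pixel_size):
        rng = np.random.default_rng(2)
        for cls in ("spindle", "signet"):
            for _ in range(5):
                mask, _ = synthgen.make_cell_mask(
                    synthgen.random_shape_spec(cls, rng), pixel_size)
                assert len(segment.detect_objects(mask, 1)) == 1

    def test_class_separation_over_random_spec_pairs(self, pixel_size):
        # every spindle's measured circularity below every signet's, over
        # 50 + 50 random specs drawn at the default class parameter ranges
        rng = np.random.default_rng(9)
        spindles = [
            synthgen.make_cell_mask(synthgen.random_shape_spec("spindle", rng),
                                    pixel_size)[1].circularity
            for _ in range(50)
        ]
        signets = [
            synthgen.make_cell_mask(synthgen.random_shape_spec("signet", rng),
                                    pixel_size)[1].circularity
            for _ in range(50)
        ]
        assert max(spindles) < min(signets)


class TestRenderScene:
    def test_detection_recovers_object_count(self, five_object_scene):
        _, mask = segment.auto_threshold(five_object_scene.image)
        assert len(segment.detect_objects(mask, 200)) == 5

    def test_intensities_are_8bit_and_objects_at_peak(self, five_object_scene):
        img = five_object_scene.image.intensity
        assert img.dtype == np.uint8
        for obj in five_object_scene.objects:
            vals = img[obj.pixels[:, 0], obj.pixels[:, 1]]
            assert np.all(vals == obj.spec.peak_intensity)
            assert obj.spec.peak_intensity / 2 <= vals.mean()

    def test_same_seed_same_truth_bit_identical(self):
        truth = synthgen.random_scene_truth(1, 2, seed=5)
        a = synthgen.render_scene(truth)
        b = synthgen.render_scene(truth)
        assert np.array_equal(a.image.intensity, b.image.intensity)

    def test_overlapping_footprints_raise(self):
        specs = (
            ShapeSpec("signet", 35.0, 0.9, (100.0, 100.0)),
            ShapeSpec("signet", 35.0, 0.9, (110.0, 100.0)),
        )
        with pytest.raises(OverlapError):
            synthgen.render_scene(SceneTruth(shape_specs=specs))

    def test_out_of_bounds_footprint_raises(self):
        spec = (ShapeSpec("signet", 35.0, 0.9, (5.0, 5.0)),)
        with pytest.raises(ParameterError):
            synthgen.render_scene(SceneTruth(shape_specs=spec))

    def test_background_must_stay_below_peaks(self):
        spec = (ShapeSpec("signet", 35.0, 0.9, (100.0, 100.0), peak_intensity=50),)
        with pytest.raises(ParameterError):
            synthgen.render_scene(SceneTruth(shape_specs=spec), background_mean=60)


class TestMakeTimelapse:
    def test_canonical_recording_has_433_frames(self):
        spec = MotilitySpec(n_cells=3, duration=72.0, frame_interval=10.0,
                            step_mean=20.0, step_sd=5.0)
        seq = synthgen.make_timelapse(spec, seed=1)
        assert seq.n_frames == 72 * 6 + 1
        assert seq.times_h[-1] == pytest.approx(72.0)

    def test_straight_line_motion_has_exact_path_length(self):
        spec = MotilitySpec(n_cells=4, step_mean=10.0, step_sd=0.0, persistence=1.0)
        seq = synthgen.make_timelapse(spec, dims=(1600, 2400), seed=3)
        assert np.allclose(seq.true_path_lengths(), 6 * 10.0)
        # interpolated 10-min positions lie on the segment chords, so the
        # 12-h-sampled path of a straight walk equals the full path
        pos = seq.positions_um
        net = np.linalg.norm(pos[-1] - pos[0], axis=1)
        assert np.allclose(net, 60.0, atol=1e-8)

    def test_path_length_calibration_over_500_cells(self):
        spec = MotilitySpec(n_cells=500, step_mean=18.83, step_sd=6.5)
        seq = synthgen.make_timelapse(spec, dims=(4000, 6000), seed=8)
        lengths = seq.true_path_lengths()
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 6 * 18.83) <= 3 * se

    def test_high_motility_calibration_matches_printed_mean(self):
        spec = MotilitySpec(n_cells=500, step_mean=37.0, step_sd=14.7)
        seq = synthgen.make_timelapse(spec, dims=(4000, 6000), seed=8)
        lengths = seq.true_path_lengths()
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 222.0) <= 3 * se

    def test_frames_deterministic_and_order_independent(self):
        spec = MotilitySpec(n_cells=5, step_mean=20.0, step_sd=5.0)
        a = synthgen.make_timelapse(spec, seed=12)
        b = synthgen.make_timelapse(spec, seed=12)
        assert np.array_equal(a.positions_um, b.positions_um)
        # access frames in different orders; pixels must not depend on order
        fa = a.frame(100).intensity
        _ = b.frame(0)
        fb = b.frame(100).intensity
        assert np.array_equal(fa, fb)

    def test_positions_stay_in_frame(self):
        spec = MotilitySpec(n_cells=15, step_mean=37.0, step_sd=14.7)
        seq = synthgen.make_timelapse(spec, dims=(764, 560), seed=4)
        pos = seq.positions_um
        r = spec.nucleus_radius
        assert np.all(pos[..., 0] >= r) and np.all(pos[..., 0] <= 560 * 0.5 - r)
        assert np.all(pos[..., 1] >= r) and np.all(pos[..., 1] <= 764 * 0.5 - r)

    def test_subresolution_nucleus_raises(self):
        spec = MotilitySpec(n_cells=2, step_mean=10.0, step_sd=1.0,
                            nucleus_radius=1.5)
        with pytest.raises(ResolutionError):
            synthgen.make_timelapse(spec, pixel_size=1.0, seed=0)


class TestSampleGroupMeasurements:
    def test_values_respect_truncation_bounds(self):
        vals = synthgen.sample_group_measurements(0.60, 0.11, 12, 0.0, 1.0, seed=1)
        assert vals.shape == (12,)
        assert np.all((vals > 0) & (vals < 1))

    def test_zero_sd_returns_copies_of_mean(self):
        vals = synthgen.sample_group_measurements(0.5, 0.0, 5, 0.0, 1.0, seed=1)
        assert np.all(vals == 0.5)

    def test_bounds_excluding_mean_raise(self):
        with pytest.raises(ParameterError):
            synthgen.sample_group_measurements(0.5, 0.1, 5, 0.6, 1.0, seed=1)

    def test_reproducible_under_seed(self):
        a = synthgen.sample_group_measurements(10.0, 2.0, 20, seed=33)
        b = synthgen.sample_group_measurements(10.0, 2.0, 20, seed=33)
        assert np.array_equal(a, b)


def test_realized_record_agrees_with_morpho_remeasurement(pixel_size):
    """The generator's ground truth is, by construction, what the analysis
    modules measure on the same mask."""
    spec = ShapeSpec("spindle", 55.0, 0.2, (0, 0), orientation=1.1)
    mask, realized = synthgen.make_cell_mask(spec, pixel_size)
    roi = segment.detect_objects(mask, 1)[0]
    feret, orth = morpho.feret_diameters(roi, pixel_size)
    assert feret == pytest.approx(realized.feret)
    assert orth == pytest.approx(realized.orthogonal)
    assert morpho.area(roi, pixel_size) == pytest.approx(realized.area)
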