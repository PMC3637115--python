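"""Tracking contracts: frame sampling, nucleus detection, linking, kinetics."""

import logging

import numpy as np
import pytest

from fibromet import motility, synthgen
from fibromet.errors import ParameterError
from fibromet.motility import CellTrack
from fibromet.segment import CalibratedImage
from fibromet.synthgen import MotilitySpec, SceneTruth, ShapeSpec


def make_track(positions, times=None):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions)) * 12.0
    return CellTrack(cell_id=0, times=np.asarray(times, float), positions=positions)


@pytest.fixture(scope="module")
def small_sequence():
    """A 72-h sequence of 12 well-separated nuclei (positions + frames)."""
    spec = MotilitySpec(n_cells=12, step_mean=20.0, step_sd=6.0)
    return synthgen.make_timelapse(spec, dims=(1600, 2400), seed=21)


class TestSampleFrames:
    def test_twelve_hour_sampling_gives_seven_frames(self, small_sequence):
        times, frames = motility.sample_frames(small_sequence, 12.0)
        assert len(frames) == 7
        assert np.allclose(times, [0, 12, 24, 36, 48, 60, 72])

    def test_incommensurate_interval_raises(self, small_sequence):
        with pytest.raises(ParameterError):
            motility.sample_frames(small_sequence, 7.0)

    def test_movie_compression_factor(self):
        assert motility.movie_compression(72.0, 40.0) == pytest.approx(1.8)


class TestDetectNuclei:
    def test_centroids_within_one_pixel_of_truth(self, small_sequence):
        frame = small_sequence.frame(0)
        truth = small_sequence.positions_um[0]
        found = motility.detect_nuclei(frame, expected_radius_um=5.0)
        assert len(found) == len(truth)
        for t in truth:
            d = np.linalg.norm(found - t[None, :], axis=1).min()
            assert d <= frame.pixel_size

    def test_blank_frame_gives_empty_list(self):
        frame = CalibratedImage(np.zeros((50, 50), dtype=np.uint8), 0.5)
        assert motility.detect_nuclei(frame).shape == (0, 2)

    def test_close_nuclei_merge_with_warning(self, caplog):
        grid = np.zeros((80, 80), dtype=np.uint8)
        yy, xx = np.mgrid[0:80, 0:80]
        for cx in (30.0, 44.0):  # centers 14 px apart, radius 10 px: fused blob
            grid[(yy - 40.0) ** 2 + (xx - cx) ** 2 <= 100.0] = 220
        frame = CalibratedImage(grid, 0.5)
        with caplog.at_level(logging.WARNING, logger="fibromet.motility"):
            found = motility.detect_nuclei(frame, expected_radius_um=5.0)
        assert len(found) == 1
        assert any("merged" in rec.message for rec in caplog.records)


class TestLinkTracks:
    def test_recovers_ground_truth_identities(self, small_sequence):
        seq = small_sequence
        times, frames = motility.sample_frames(seq, 12.0)
        cents = [motility.detect_nuclei(f, expected_radius_um=5.0) for f in frames]
        tracks = motility.link_tracks(times, cents)
        assert len(tracks) == seq.n_cells
        _, truth = seq.truth_positions(12.0)
        for tr in tracks:
            start = tr.positions[0]
            cell = int(np.argmin(np.linalg.norm(truth[0] - start[None], axis=1)))
            err = np.linalg.norm(tr.positions - truth[:, cell], axis=1)
            assert err.max() <= 2 * seq.pixel_size

    def test_stationary_cells_give_constant_tracks(self):
        pts = np.array([[10.0, 10.0], [50.0, 50.0]])
        tracks = motility.link_tracks([0, 12, 24], [pts, pts, pts], gate_um=10)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.allclose(tr.positions, tr.positions[0])

    def test_cell_leaving_the_field_is_excluded(self):
        t0 = np.array([[10.0, 10.0], [80.0, 80.0]])
        t1 = np.array([[12.0, 10.0], [82.0, 80.0]])
        t2 = np.array([[14.0, 10.0]])  # second cell gone
        tracks = motility.link_tracks([0, 12, 24], [t0, t1, t2], gate_um=10)
        assert len(tracks) == 1
        assert np.allclose(tracks[0].positions[:, 1], 10.0)

    def test_empty_first_timepoint(self):
        out = motility.link_tracks([0, 12], [np.empty((0, 2)), np.ones((2, 2))])
        assert out == []

    def test_identity_accuracy_on_twenty_seeded_sequences(self):
        # well-separated cells (grid spacing far above the per-segment step):
        # every linked track must follow one true cell throughout
        for seed in range(20):
            spec = MotilitySpec(n_cells=9, step_mean=20.0, step_sd=6.0)
            seq = synthgen.make_timelapse(spec, dims=(1600, 2400), seed=100 + seed)
            times, truth = seq.truth_positions(12.0)
            noisy = [p + np.random.default_rng(seed * 7 + t).normal(0, 0.2, p.shape)
                     for t, p in enumerate(truth)]
            tracks = motility.link_tracks(times, noisy)
            assert len(tracks) == 9
            for tr in tracks:
                cell = int(np.argmin(
                    np.linalg.norm(truth[0] - tr.positions[0][None], axis=1)))
                err = np.linalg.norm(tr.positions - truth[:, cell], axis=1)
                assert err.max() <= 1.0  # never switches identity


class TestKinetics:
    def test_total_displacement_sums_waypoint_distances(self):
        tr = make_track([(0, 0), (3, 4), (6, 8)])
        assert motility.total_displacement(tr) == pytest.approx(10.0)

    def test_stationary_track(self):
        tr = make_track([(5, 5), (5, 5), (5, 5)])
        assert motility.total_displacement(tr) == 0.0
        assert motility.velocity(tr) == 0.0

    def test_velocity_is_displacement_over_elapsed_time(self):
        tr = make_track([(0, 0), (108, 0), (216, 0)], times=[0, 36, 72])
        assert motility.velocity(tr) == pytest.approx(3.0)
        assert motility.velocity(tr) * tr.duration_h == pytest.approx(
            motility.total_displacement(tr))

    def test_path_length_at_least_net_displacement(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = rng.normal(0, 30, size=(7, 2))
            tr = make_track(pts)
            assert motility.total_displacement(tr) >= motility.net_displacement(tr) - 1e-12

    def test_straight_walk_sampling_invariance(self):
        spec = MotilitySpec(n_cells=3, step_mean=15.0, step_sd=0.0, persistence=1.0)
        seq = synthgen.make_timelapse(spec, dims=(1600, 2400), seed=2)
        times, truth = seq.truth_positions(12.0)
        for c in range(3):
            tr = CellTrack(cell_id=c, times=times, positions=truth[:, c])
            assert motility.total_displacement(tr) == pytest.approx(6 * 15.0)


class TestShapeTimecourse:
    @staticmethod
    def _constant_shape_sequence(circs=(0.8, 0.8, 0.8)):
        frames = []
        for circ in circs:
            spec = ShapeSpec("signet", 40.0, circ, (95.0, 95.0))
            truth = SceneTruth(shape_specs=(spec,), image_dims=(380, 380), seed=3)
            frames.append(synthgen.render_scene(truth).image)

        class Seq:
            frame_interval_min = 36 * 60.0
            n_frames = 3

            def frame(self, i):
                return frames[i]

        return Seq()

    @staticmethod
    def _track_at(pos, times=(0.0, 36.0, 72.0)):
        return CellTrack(cell_id=0, times=np.asarray(times),
                         positions=np.tile(np.asarray(pos, float), (len(times), 1)))

    def test_constant_shapes_give_identical_records(self):
        seq = self._constant_shape_sequence()
        df = motility.shape_timecourse(seq, [self._track_at((95.0, 95.0))],
                                       min_size=200)
        assert len(df) == 3
        assert df["circularity"].max() - df["circularity"].min() <= 0.02 * df["circularity"].max()
        assert df["feret_um"].max() <= 1.02 * df["feret_um"].min()

    def test_elongating_shapes_lose_circularity(self):
        seq = self._constant_shape_sequence(circs=(0.9, 0.7, 0.5))
        df = motility.shape_timecourse(seq, [self._track_at((95.0, 95.0))],
                                       min_size=200)
        circ = df.sort_values("time_h")["circularity"].to_numpy()
        assert circ[0] > circ[1] > circ[2]

    def test_record_count_is_cells_times_timepoints(self, small_sequence):
        times, frames = motility.sample_frames(small_sequence, 12.0)
        cents = [motility.detect_nuclei(f, expected_radius_um=5.0) for f in frames]
        tracks = motility.link_tracks(times, cents)
        df = motility.shape_timecourse(small_sequence, tracks,
                                       times_h=(0.0, 36.0, 72.0), min_size=100)
        assert len(df) == len(tracks) * 3

    def test_missing_timepoint_raises(self):
        seq = self._constant_shape_sequence()
        with pytest.raises(ParameterError):
            motility.shape_timecourse(seq, [self._track_at((95.0, 95.0))],
                                      times_h=(0.0, 48.0))


def test_recovered_displacement_tracks_generator_truth():
    """Full pipeline on one sequence: recovered per-cell path lengths match
    the generator's ground truth to sub-pixel mean error."""
    spec = MotilitySpec(n_cells=15, step_mean=37.0, step_sd=14.7)
    seq = synthgen.make_timelapse(spec, dims=(1600, 2400), seed=77)
    times, frames = motility.sample_frames(seq, 12.0)
    cents = [motility.detect_nuclei(f, expected_radius_um=5.0) for f in frames]
    tracks = motility.link_tracks(times, cents)
    assert len(tracks) == 15
    truth_lengths = np.sort(seq.true_path_lengths())
    got = np.sort([motility.total_displacement(t) for t in tracks])
    assert np.abs(got - truth_lengths).mean() <= 2 * seq.pixel_size
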