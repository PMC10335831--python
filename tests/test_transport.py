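"""Run/pause segmentation, transport metrics and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reference_transport import ref_metrics, trajectory_from_speeds

from mtkit.errors import (
    ConfigurationError,
    InsufficientDataError,
    NeverMotileError,
    TrajectoryError,
)
from mtkit.transport import (
    SegmentationParams,
    Trajectory,
    assign_direction,
    compare_groups,
    compute_metrics,
    detect_run_window,
    instant_velocity,
    is_motile,
    segment_run,
    sem,
    trajectory_kymograph,
)

P = SegmentationParams()


class TestTrajectoryValidation:
    def test_rejects_single_point(self):
        with pytest.raises(TrajectoryError):
            Trajectory("x", [0.0], [[0.0, 0.0]])

    def test_rejects_non_uniform_sampling_naming_frame(self):
        with pytest.raises(TrajectoryError, match="frame 2"):
            Trajectory("x", [0.0, 2.0, 5.0], [[0, 0], [1, 0], [2, 0]])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(TrajectoryError):
            Trajectory("x", [0.0, 2.0, 2.0], [[0, 0], [1, 0], [2, 0]])


class TestInstantVelocity:
    @pytest.mark.parametrize(
        "speeds",
        [
            [0.5, 0.5],
            [0.0, 0.0, 0.0],
            [0.15, 0.0, 0.6],
        ],
    )
    def test_speed_sequences_recovered_exactly(self, traj_from_speeds, speeds):
        # positions built so displacements/dt reproduce the sequence
        v = instant_velocity(traj_from_speeds(speeds))
        np.testing.assert_allclose(v, speeds, atol=1e-12)

    def test_euclidean_not_projected(self):
        # diagonal step of 1 um in each axis at dt=2 -> speed sqrt(2)/2
        t = Trajectory("d", [0.0, 2.0], [[0, 0], [1, 1]])
        np.testing.assert_allclose(instant_velocity(t), [np.sqrt(2) / 2])


class TestSegmentation:
    def test_pause_stretch_merges_into_one_event(self, traj_from_speeds):
        labels, events = segment_run(traj_from_speeds([0.5, 0.1, 0.1, 0.6]), P)
        assert labels.tolist() == [True, False, False, True]
        assert len(events) == 1 and events[0].n_intervals == 2

    def test_all_subthreshold_is_single_whole_run_pause(self, traj_from_speeds):
        labels, events = segment_run(traj_from_speeds([0.19] * 5), P)
        assert not labels.any()
        assert len(events) == 1 and events[0].n_intervals == 5

    def test_separated_pauses_count_as_two_events(self, traj_from_speeds):
        _, events = segment_run(traj_from_speeds([0.1, 0.5, 0.1]), P)
        assert len(events) == 2

    def test_boundary_speed_counts_as_transport(self, traj_from_speeds):
        labels, _ = segment_run(traj_from_speeds([0.2]), P)
        assert labels.tolist() == [True]

    def test_min_pause_frames_filters_short_pauses(self, traj_from_speeds):
        params = SegmentationParams(min_pause_frames=2)
        _, events = segment_run(traj_from_speeds([0.5, 0.1, 0.5, 0.1, 0.1, 0.5]), params)
        assert len(events) == 1 and events[0].start == 3


class TestRunWindow:
    def test_stationary_tails_excluded(self, traj_from_speeds):
        assert detect_run_window(traj_from_speeds([0, 0, 0.5, 0.5, 0, 0]), P) == (2, 3)

    def test_fully_motile_track_spans_all_intervals(self, traj_from_speeds):
        assert detect_run_window(traj_from_speeds([0.3] * 4), P) == (0, 3)

    def test_never_motile_signalled(self, traj_from_speeds):
        with pytest.raises(NeverMotileError):
            detect_run_window(traj_from_speeds([0.1] * 4), P)


class TestMotility:
    def test_long_run_is_motile(self, traj_from_speeds):
        assert is_motile(traj_from_speeds([0.5] * 5), P)  # 5 um

    def test_exactly_two_micron_is_not_motile(self, traj_from_speeds):
        # strict 'more than 2 um'
        assert not is_motile(traj_from_speeds([0.5, 0.5]), P)  # exactly 2.0 um

    def test_never_motile_is_not_motile(self, traj_from_speeds):
        assert not is_motile(traj_from_speeds([0.1] * 4), P)


class TestMetrics:
    def test_uninterrupted_run(self, traj_from_speeds):
        m = compute_metrics(traj_from_speeds([0.5] * 4), P)
        assert m.run_length == pytest.approx(4.0)
        assert m.run_time == pytest.approx(8.0)
        assert m.total_run_velocity == pytest.approx(0.5)
        assert m.transport_velocity == pytest.approx(0.5)
        assert m.pausing_time_ratio == 0.0
        assert m.pausing_frequency == 0.0

    def test_run_with_one_pause_hand_computed(self, traj_from_speeds):
        m = compute_metrics(traj_from_speeds([0.6, 0.6, 0.0, 0.0, 0.6]), P)
        assert m.run_length == pytest.approx(3.6)
        assert m.run_time == pytest.approx(10.0)
        assert m.total_run_velocity == pytest.approx(0.36)
        assert m.transport_velocity == pytest.approx(0.6)
        assert m.pausing_time_total == pytest.approx(4.0)
        assert m.pausing_time_ratio == pytest.approx(0.4)
        assert m.n_pauses == 1
        assert m.pausing_frequency == pytest.approx(1 / 3.6)

    def test_run_time_decomposition_exact(self, traj_from_speeds):
        m = compute_metrics(traj_from_speeds([0.5, 0.1, 0.4, 0.0, 0.3]), P)
        assert abs(m.run_time - (m.pausing_time_total + m.transporting_time)) < 1e-9

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from([0.0, 0.1, 0.3, 0.6]), min_size=1, max_size=8
        )
    )
    def test_metrics_match_brute_force_reference(self, speeds):
        """Vectorized implementation equals the loop-based oracle."""
        ref = ref_metrics(speeds)
        traj = trajectory_from_speeds(speeds)
        if ref is None:
            with pytest.raises(NeverMotileError):
                compute_metrics(traj, P)
            return
        m = compute_metrics(traj, P)
        assert detect_run_window(traj, P) == ref["window"]
        for key in (
            "run_length",
            "run_time",
            "total_run_velocity",
            "transport_velocity",
            "pausing_time_total",
            "pausing_time_ratio",
            "pausing_frequency",
        ):
            assert getattr(m, key) == pytest.approx(ref[key]), key
        assert m.n_pauses == ref["n_pauses"]
        assert 0.0 <= m.pausing_time_ratio <= 1.0


class TestDirection:
    def test_net_positive_projection_is_anterograde(self, traj_from_speeds):
        assert assign_direction(traj_from_speeds([0.5] * 6)) == "anterograde"

    def test_net_negative_projection_is_retrograde(self, traj_from_speeds):
        assert assign_direction(traj_from_speeds([0.5] * 6), axis=(-1.0, 0.0)) == "retrograde"

    def test_small_net_displacement_is_ambiguous(self, traj_from_speeds):
        # net +0.2 um < 0.5 um threshold
        assert assign_direction(traj_from_speeds([0.1])) == "ambiguous"

    def test_zero_axis_rejected(self, traj_from_speeds):
        with pytest.raises(ConfigurationError):
            assign_direction(traj_from_speeds([0.5] * 3), axis=(0.0, 0.0))


class TestTrajectoryKymograph:
    def test_constant_velocity_gives_straight_line(self, traj_from_speeds):
        line = trajectory_kymograph(traj_from_speeds([0.5] * 5))
        slopes = np.diff(line.distance) / np.diff(line.times)
        np.testing.assert_allclose(slopes, 0.5)

    def test_pause_appears_as_plateau(self, traj_from_speeds):
        line = trajectory_kymograph(traj_from_speeds([0.6, 0.0, 0.0, 0.6]))
        assert len(line.pause_spans) == 1
        t0, t1 = line.pause_spans[0]
        assert t1 - t0 == pytest.approx(4.0)
        i0, i1 = int(t0 // 2), int(t1 // 2)
        assert line.distance[i0] == pytest.approx(line.distance[i1])

    def test_plateau_count_matches_n_pauses(self, traj_from_speeds):
        speeds = [0.6, 0.0, 0.6, 0.0, 0.0, 0.6]
        line = trajectory_kymograph(traj_from_speeds(speeds))
        m = compute_metrics(trajectory_from_speeds(speeds), P)
        assert len(line.pause_spans) == m.n_pauses


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        for test in ("t", "mannwhitney"):
            assert compare_groups([1, 2, 3], [1, 2, 3], test=test)["p_value"] == pytest.approx(1.0)

    def test_exact_mannwhitney_small_sample(self):
        # all C(4,2)=6 rank splits; most extreme split both tails -> 2/6
        res = compare_groups([1, 2], [3, 4], test="mannwhitney")
        assert res["p_value"] == pytest.approx(1 / 3)

    def test_sem_closed_form(self):
        assert sem([1, 2, 3]) == pytest.approx(1 / np.sqrt(3))

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [2.0, 3.0])

    def test_t_test_detects_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        assert compare_groups(a, b, test="t")["p_value"] < 1e-6
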