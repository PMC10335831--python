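"""Synthetic-data generators: ground-truth correctness and determinism."""

import numpy as np
import pytest

from mtkit.errors import ConfigurationError
from mtkit.simulate import (
    OocyteSimConfig,
    PSMSimConfig,
    StreamingSimConfig,
    TrajectorySimConfig,
    simulate_oocyte_image,
    simulate_psm_table,
    simulate_streaming_movie,
    simulate_trajectories,
)


class TestTrajectorySim:
    def test_noise_free_constant_velocity_is_strictly_monotone(self):
        cfg = TrajectorySimConfig(
            n_tracks=1,
            duration_s=18.0,
            frame_interval_s=2.0,
            transport_speed_mean=0.5,
            transport_speed_sd=0.0,
            p_pause_per_frame=0.0,
            localization_sd=0.0,
            seed=1,
        )
        (sim,) = simulate_trajectories(cfg)
        x = sim.trajectory.positions[:, 0]
        assert len(x) == 10
        np.testing.assert_allclose(np.diff(x), 1.0, atol=1e-12)
        assert sim.transport_truth.all()

    def test_pause_is_absorbing_when_resume_prob_zero(self):
        cfg = TrajectorySimConfig(
            n_tracks=20, p_pause_per_frame=0.5, p_resume_per_frame=0.0, seed=2
        )
        for sim in simulate_trajectories(cfg):
            truth = sim.transport_truth
            paused = np.flatnonzero(~truth)
            if paused.size:
                assert not truth[paused[0]:].any()

    def test_pause_fraction_matches_stationary_distribution(self):
        # two-state chain: stationary pause prob = 0.1/(0.1+0.5) = 1/6
        cfg = TrajectorySimConfig(
            n_tracks=500, p_pause_per_frame=0.1, p_resume_per_frame=0.5, seed=3
        )
        sims = simulate_trajectories(cfg)
        per_track = np.array([1.0 - s.transport_truth.mean() for s in sims])
        se = per_track.std(ddof=1) / np.sqrt(len(per_track))
        assert abs(per_track.mean() - 1 / 6) < 3 * se

    def test_track_has_expected_number_of_points(self):
        cfg = TrajectorySimConfig(n_tracks=1, seed=0)
        (sim,) = simulate_trajectories(cfg)
        assert sim.trajectory.positions.shape[0] == 180 / 2.0 + 1

    def test_pause_displacement_is_pure_localization_noise(self):
        cfg = TrajectorySimConfig(
            n_tracks=50, p_pause_per_frame=0.9, p_resume_per_frame=0.1,
            localization_sd=0.05, seed=4,
        )
        disps = []
        for sim in simulate_trajectories(cfg):
            steps = np.diff(sim.trajectory.positions, axis=0)
            disps.extend(np.linalg.norm(steps[~sim.transport_truth], axis=1))
        # Rayleigh with sigma = sd*sqrt(2): mean = sd*sqrt(2)*sqrt(pi/2)
        expected = 0.05 * np.sqrt(2) * np.sqrt(np.pi / 2)
        assert np.mean(disps) == pytest.approx(expected, rel=0.1)

    @pytest.mark.parametrize(
        "bad",
        [
            {"p_pause_per_frame": 1.5},
            {"transport_speed_mean": -1.0},
            {"frame_interval_s": 0.0},
            {"localization_sd": float("nan")},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            TrajectorySimConfig(**bad)

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_trajectories(TrajectorySimConfig(n_tracks=3, seed=7))
        b = simulate_trajectories(TrajectorySimConfig(n_tracks=3, seed=7))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.trajectory.positions, sb.trajectory.positions)
            np.testing.assert_array_equal(sa.transport_truth, sb.transport_truth)


class TestStreamingSim:
    def test_rigid_rotation_truth_velocities_are_tangential(self):
        cfg = StreamingSimConfig(pattern="circular_central", noise_sd=0.0, n_vesicles=40, seed=5)
        m = simulate_streaming_movie(cfg)
        c = np.asarray(m.rotation_center_px)
        for t in (0, 10, 30):
            r = m.tracks[t] - c
            dots = np.abs(np.sum(m.velocities[t] * r, axis=1))
            np.testing.assert_allclose(dots, 0.0, atol=1e-9)

    def test_zero_angular_speed_gives_static_tracks(self):
        cfg = StreamingSimConfig(angular_speed=0.0, noise_sd=0.0, n_vesicles=20, seed=6)
        m = simulate_streaming_movie(cfg)
        np.testing.assert_allclose(m.tracks[-1], m.tracks[0], atol=1e-9)

    def test_vesicle_count_conserved_in_field(self):
        m = simulate_streaming_movie(StreamingSimConfig(n_vesicles=80, seed=8))
        h, w = m.config.field_shape
        inside = (
            (m.tracks[..., 0] >= 0) & (m.tracks[..., 0] <= w - 1)
            & (m.tracks[..., 1] >= 0) & (m.tracks[..., 1] <= h - 1)
        )
        assert inside.all()

    def test_empty_movie_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_streaming_movie(StreamingSimConfig(n_vesicles=0))

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_streaming_movie(StreamingSimConfig(n_vesicles=30, seed=9))
        b = simulate_streaming_movie(StreamingSimConfig(n_vesicles=30, seed=9))
        np.testing.assert_array_equal(a.stack, b.stack)
        np.testing.assert_array_equal(a.tracks, b.tracks)


class TestPsmSim:
    def test_all_unmodified_when_prob_mass_on_zero(self):
        from mtkit.ptm import summarize

        cfg = PSMSimConfig(sidechain_probs=(1.0, 0.0, 0.0, 0.0), seed=10)
        table = simulate_psm_table(cfg)
        cell = summarize(table).cell("w", "alphaTub84B/D")
        assert cell["n_0e"] == cfg.n_psm_84bd
        assert cell["n_1e"] == cell["n_2e"] == cell["n_3e"] == 0

    def test_exact_counts_mode_reproduces_configured_counts(self):
        cfg = PSMSimConfig(
            n_psm_84bd=58,
            sidechain_probs=(17 / 58, 29 / 58, 8 / 58, 4 / 58),
            seed=11,
        )
        table = simulate_psm_table(cfg, exact_counts=True)
        from mtkit.ptm import summarize

        cell = summarize(table).cell("w", "alphaTub84B/D")
        assert (cell["n_0e"], cell["n_1e"], cell["n_2e"], cell["n_3e"]) == (17, 29, 8, 4)

    def test_site_weights_restrict_modified_sites(self):
        cfg = PSMSimConfig(
            sidechain_probs=(0.0, 0.5, 0.3, 0.2),
            site_weights=(0.0, 0.0, 0.5, 0.5),
            seed=12,
        )
        table = simulate_psm_table(cfg)
        mods = ";".join(m for m in table["mods"] if m)
        assert "E443" not in mods and "E445" not in mods
        assert "E448" in mods or "E449" in mods

    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ConfigurationError):
            PSMSimConfig(sidechain_probs=(0.5, 0.5, 0.1, 0.0))

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_psm_table(PSMSimConfig(seed=13))
        b = simulate_psm_table(PSMSimConfig(seed=13))
        assert a.equals(b)


class TestOocyteSim:
    def test_truth_records_crescent_and_peaks(self):
        cfg = OocyteSimConfig(
            crescent_arc_um=30.0, inner_peaks=((0.6, 200.0, 6.0),), seed=14
        )
        sim = simulate_oocyte_image(cfg)
        assert sim.truth["crescent_arc_um"] == 30.0
        assert sim.truth["inner_peak_fracs"] == [0.6]
        assert sim.image.shape == cfg.image_shape

    def test_crescent_longer_than_cortex_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_oocyte_image(OocyteSimConfig(crescent_arc_um=1e5))

    def test_zero_amplitude_truth_is_zero_length(self):
        sim = simulate_oocyte_image(OocyteSimConfig(crescent_amplitude=0.0, seed=15))
        assert sim.truth["crescent_arc_um"] == 0.0

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_oocyte_image(OocyteSimConfig(seed=16))
        b = simulate_oocyte_image(OocyteSimConfig(seed=16))
        np.testing.assert_array_equal(a.image, b.image)
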