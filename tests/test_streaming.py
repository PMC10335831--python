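"""Kymographs, flow estimation, rotation-center fitting and the
streaming-pattern classifier."""

import numpy as np
import pytest

from mtkit.errors import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedResultError,
)
from mtkit.simulate import StreamingSimConfig, simulate_streaming_movie
from mtkit.streaming import (
    ClassifierParams,
    FlowField,
    FlowParams,
    Kymograph,
    build_kymograph,
    classify_movie,
    classify_streaming,
    cortical_unidirectionality,
    estimate_flow,
    fit_rotation_center,
    summarize_patterns,
    tangential_coherence,
)


def _spot_stack(n_frames, h, w, path, sigma=2.0, amp=500.0, bg=50.0):
    """Movie of one Gaussian spot following ``path`` (list of (x, y))."""
    yy, xx = np.mgrid[0:h, 0:w]
    frames = []
    for x, y in path:
        frames.append(bg + amp * np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))))
    return np.asarray(frames)


def _rotation_field(center, n=200, omega=0.1, seed=0, radius=40.0):
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0.1, 1.0, n))
    pos = np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])
    rel = pos - np.asarray(center)
    vel = omega * np.column_stack([-rel[:, 1], rel[:, 0]])
    return pos, vel


class TestKymograph:
    def test_static_movie_gives_identical_columns(self):
        stack = _spot_stack(5, 40, 60, [(30, 20)] * 5)
        line = np.array([[5.0, 20.0], [55.0, 20.0]])
        kymo = build_kymograph(stack, line, width=1)
        for j in range(1, kymo.matrix.shape[1]):
            np.testing.assert_allclose(kymo.matrix[:, j], kymo.matrix[:, 0])

    def test_translating_spot_draws_sloped_streak(self):
        # 2 px/frame along the line -> streak slope 2 px/frame (+-1 px)
        path = [(10 + 2 * t, 20) for t in range(8)]
        stack = _spot_stack(8, 40, 60, path)
        kymo = build_kymograph(stack, np.array([[0.0, 20.0], [59.0, 20.0]]), width=3)
        rows = np.argmax(kymo.matrix, axis=0)
        np.testing.assert_allclose(np.diff(rows), 2, atol=1)
        assert rows[0] == pytest.approx(10, abs=1)

    def test_width_one_equals_direct_pixel_sampling(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (30, 50))
        line = np.array([[2.0, 7.0], [47.0, 7.0]])
        kymo = build_kymograph(img[None], line, width=1)
        np.testing.assert_allclose(kymo.matrix[:, 0], img[7, 2:48])

    def test_out_of_bounds_polyline_rejected(self):
        stack = np.zeros((2, 20, 20))
        with pytest.raises(ConfigurationError):
            build_kymograph(stack, np.array([[0.0, 0.0], [100.0, 0.0]]))


class TestFlowEstimation:
    def test_static_movie_gives_zero_velocities(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 200, (60, 80))
        stack = np.stack([frame] * 6)
        flow = estimate_flow(stack, params=FlowParams(frame_gap=1, n_pairs=3))
        np.testing.assert_allclose(flow.velocities, 0.0)

    def test_pure_translation_modal_displacement_exact(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 200, (80, 100))
        from scipy.ndimage import shift as ndshift

        stack = np.stack([ndshift(base, (0, 2 * t), order=1, mode="nearest") for t in range(4)])
        flow = estimate_flow(
            stack,
            params=FlowParams(frame_gap=1, n_pairs=3, patch_px=16, step_px=16),
            pixel_size=1.0,
            frame_interval=1.0,
        )
        dx = flow.velocities[:, 0]  # px/frame at unit scale
        vals, counts = np.unique(dx, return_counts=True)
        assert vals[np.argmax(counts)] == pytest.approx(2.0)

    def test_rotation_movie_recovers_tangential_directions(self):
        m = simulate_streaming_movie(
            StreamingSimConfig(pattern="circular_central", noise_sd=0.0, seed=21)
        )
        flow = estimate_flow(m.stack)
        c = np.asarray(m.rotation_center_px)
        r = flow.positions - c
        vn = np.linalg.norm(flow.velocities, axis=1)
        keep = vn > 0
        t_hat = np.column_stack([-r[:, 1], r[:, 0]])
        t_hat /= np.linalg.norm(t_hat, axis=1)[:, None]
        cosang = np.sum(flow.velocities[keep] * t_hat[keep], axis=1) / vn[keep]
        ang_err = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.median(ang_err) < 10.0

    def test_empty_mask_rejected(self):
        stack = np.zeros((3, 40, 40))
        with pytest.raises(ConfigurationError):
            estimate_flow(stack, mask=np.zeros((40, 40), dtype=bool))


class TestRotationCenterFit:
    def test_exact_rotation_center_recovered(self):
        pos, vel = _rotation_field((50.0, 50.0), seed=3)
        fit = fit_rotation_center((pos, vel))
        assert np.hypot(fit.center[0] - 50, fit.center[1] - 50) < 2.0  # 2% of 100
        assert fit.coherence > 0.95

    def test_random_directions_have_low_coherence(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 100, (200, 2))
        ang = rng.uniform(0, 2 * np.pi, 200)
        vel = np.column_stack([np.cos(ang), np.sin(ang)])
        fit = fit_rotation_center((pos, vel))
        assert fit.coherence < 0.2

    def test_counter_rotating_halves_cancel(self):
        pos1, vel1 = _rotation_field((30.0, 50.0), n=100, seed=5, radius=20)
        pos2, vel2 = _rotation_field((70.0, 50.0), n=100, omega=-0.1, seed=6, radius=20)
        pos = np.vstack([pos1, pos2])
        vel = np.vstack([vel1, vel2])
        kappa = tangential_coherence(pos, vel, np.asarray([50.0, 50.0]))
        assert kappa < 0.2

    def test_translation_equivariance(self):
        pos, vel = _rotation_field((40.0, 40.0), seed=7)
        f0 = fit_rotation_center((pos, vel))
        f1 = fit_rotation_center((pos + np.array([13.0, -7.0]), vel))
        assert f1.center[0] - f0.center[0] == pytest.approx(13.0, abs=0.5)
        assert f1.center[1] - f0.center[1] == pytest.approx(-7.0, abs=0.5)

    def test_coherence_invariant_under_speed_rescaling(self):
        pos, vel = _rotation_field((50.0, 50.0), seed=8)
        rng = np.random.default_rng(9)
        vel = vel + rng.normal(0, 0.5, vel.shape)
        k1 = fit_rotation_center((pos, vel)).coherence
        k2 = fit_rotation_center((pos, vel * 7.3)).coherence
        assert k1 == pytest.approx(k2, abs=1e-9)

    def test_parallel_field_flagged_degenerate(self):
        rng = np.random.default_rng(10)
        pos = rng.uniform(0, 100, (50, 2))
        vel = np.tile([1.0, 0.0], (50, 1))
        assert fit_rotation_center((pos, vel)).degenerate

    def test_too_few_vectors_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_rotation_center((np.zeros((4, 2)), np.ones((4, 2))))


class TestClassifier:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("circular_central", "circular_central"),
            ("circular_anterior_biased", "circular_anterior_biased"),
            ("disordered", "abnormal_chaotic"),
            ("partial_posterior_disrupted", "abnormal_partial"),
        ],
    )
    def test_round_trip_on_default_noise(self, pattern, expected):
        m = simulate_streaming_movie(StreamingSimConfig(pattern=pattern, seed=31))
        call = classify_movie(m.stack, ap_axis=m.ap_axis)
        assert call.pattern == expected

    def test_anterior_biased_center_recovered_within_five_percent(self):
        cfg = StreamingSimConfig(
            pattern="circular_anterior_biased", center_frac_ap=0.3, seed=32
        )
        m = simulate_streaming_movie(cfg)
        call = classify_movie(m.stack, ap_axis=m.ap_axis)
        assert call.center_ap_frac == pytest.approx(0.3, abs=0.05)

    def test_classification_deterministic_given_flow(self):
        m = simulate_streaming_movie(StreamingSimConfig(seed=33))
        flow = estimate_flow(m.stack)
        c1 = classify_streaming(flow, ap_axis=m.ap_axis)
        c2 = classify_streaming(flow, ap_axis=m.ap_axis)
        assert c1 == c2


class TestPatternSummary:
    def test_printed_percentages_reproduced(self):
        calls = {
            "control": ["circular_central"] * 17,
            "rescued": ["circular_central"] * 5 + ["abnormal_chaotic"] * 2,
            "mutant": ["abnormal_chaotic"] * 9 + ["abnormal_partial"] * 7
            + ["circular_central"] * 5,
        }
        table = summarize_patterns(calls).set_index("genotype")
        assert table.loc["control", "pct_circular"] == 100
        assert table.loc["control", "n"] == 17
        assert table.loc["rescued", "pct_circular"] == 71
        assert table.loc["mutant", "pct_abnormal"] == 76
        assert table.loc["mutant", "n"] == 21

    def test_empty_genotype_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_patterns({"empty": []})


class TestCorticalUnidirectionality:
    def _kymo(self, matrix):
        return Kymograph(matrix, np.array([[0.0, 0.0], [1.0, 0.0]]), 1, 1.0, 1.0)

    def _streak_matrix(self, slopes, n_rows=60, n_cols=40, seed=0):
        rng = np.random.default_rng(seed)
        m = np.zeros((n_rows, n_cols))
        rows = np.arange(n_cols, dtype=float)
        for slope in slopes:
            r0 = rng.uniform(5, n_rows - 5)
            center = (r0 + slope * rows) % n_rows
            for j in range(n_cols):
                m[:, j] += 80 * np.exp(-0.5 * ((np.arange(n_rows) - center[j]) / 1.5) ** 2)
        return m

    def test_unidirectional_streaks_give_fraction_near_one(self):
        m = self._streak_matrix([1.0] * 8, seed=1)
        assert cortical_unidirectionality(self._kymo(m)) > 0.9

    def test_counter_moving_streaks_split_evenly(self):
        # mirror-symmetric superposition: every +1 streak has a -1 twin
        s = self._streak_matrix([1.0] * 6, seed=2)
        m = s + s[::-1, :]
        assert cortical_unidirectionality(self._kymo(m)) == pytest.approx(0.5, abs=0.1)

    def test_static_kymograph_is_undefined(self):
        m = np.tile(np.linspace(0, 100, 60)[:, None], (1, 40))
        with pytest.raises(UndefinedResultError):
            cortical_unidirectionality(self._kymo(m))
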