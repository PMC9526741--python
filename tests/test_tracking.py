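"""Lobe detection, displacement estimation, and trajectory building."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from speckletrack.correlations import CorrelationMap, autocorrelate, differential_correlation
from speckletrack.optics_model import MemoryKernel, OpticalConfig
from speckletrack.scenes import (
    Motion,
    SubObject,
    apply_motion,
    disk_sprite,
    linear_motion,
    make_dotfield_scene,
    make_multishape_scene,
    square_path_motion,
    star_sprite,
)
from speckletrack.speckle_sim import ScatteringScreen, add_camera_noise, render_sequence
from speckletrack.tracking import (
    TrackingParams,
    Trajectory,
    build_trajectory,
    choose_reference_lag,
    estimate_displacement,
    estimate_rotation,
    estimate_step,
    extract_motion_features,
    save_trajectory,
)


def synthetic_differential(pos_lobe, neg_lobe, amplitude=1.0, noise=0.01, shape=(121, 121), seed=0, width=2.0):
    """A hand-built differential map: one ±Gaussian pair over white noise."""
    rng = np.random.default_rng(seed)
    values = noise * rng.normal(size=shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    center = (shape[0] // 2, shape[1] // 2)
    for (dr, dc), amp in ((pos_lobe, amplitude), (neg_lobe, -amplitude)):
        values += amp * np.exp(
            -((rr - center[0] - dr) ** 2 + (cc - center[1] - dc) ** 2) / (2 * width**2)
        )
    return CorrelationMap(values=values, lag_pitch=1.0, kind="differential")


class TestExtractFeatures:
    def test_constructed_lobe_pair(self):
        cmap = synthetic_differential((10, 0), (-10, 0), amplitude=0.5, noise=0.05)
        feats = extract_motion_features(cmap, search_radius_px=50)
        assert len(feats) == 1
        np.testing.assert_allclose(feats[0].displacement_det, (-20.0, 0.0), atol=0.5)
        assert feats[0].positive_amplitude > 0 > feats[0].negative_amplitude

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(1)
        cmap = CorrelationMap(
            values=rng.normal(size=(121, 121)), lag_pitch=1.0, kind="differential"
        )
        assert extract_motion_features(cmap, threshold_sigma=5.0) == []

    def test_wrong_kind_rejected(self):
        cmap = CorrelationMap(values=np.zeros((9, 9)), lag_pitch=1.0, kind="auto")
        with pytest.raises(ValueError, match="differential"):
            extract_motion_features(cmap)

    def test_two_movers_recovered(self, tracking_config):
        """Two independently moving stars give two lobe-pair features whose
        displacements match both ground-truth motions."""
        pitch = tracking_config.object_pixel_pitch
        subs = [
            SubObject(disk_sprite(5.0), anchor=(-25 * pitch, -62 * pitch)),
            SubObject(disk_sprite(5.0), anchor=(-68 * pitch, -32 * pitch)),
            SubObject(disk_sprite(5.0), anchor=(25 * pitch, 62 * pitch)),
            SubObject(disk_sprite(5.0), anchor=(68 * pitch, 32 * pitch)),
            SubObject(star_sprite(16, n_points=5), anchor=(-48 * pitch, -48 * pitch), mobile=True),
            SubObject(star_sprite(16, n_points=6), anchor=(48 * pitch, 48 * pitch), mobile=True),
        ]
        seq = make_multishape_scene(subs, grid=(256, 256), pixel_pitch=pitch)
        truths = np.array([[0.0, 18.0], [15.0, 0.0]])
        seq = apply_motion(seq, 4, [Motion(), Motion(translation=(0.0, 18 * pitch))])
        seq = apply_motion(seq, 5, [Motion(), Motion(translation=(15 * pitch, 0.0))])
        frames = render_sequence(seq, ScatteringScreen(seed=41, shape=(256, 256)), tracking_config)
        dmap = differential_correlation(frames[1], frames[0])
        feats = extract_motion_features(dmap, max_features=8, search_radius_px=80)
        assert len(feats) >= 2
        disps = np.array([estimate_displacement(f, tracking_config) / pitch for f in feats[:2]])
        errors = np.linalg.norm(disps[:, None, :] - truths[None, :, :], axis=-1)
        # each truth matched by one of the two strongest features
        assert errors.min(axis=0).max() < 2.5


class TestEstimateDisplacement:
    def test_coincident_lobes_give_zero(self, config):
        cmap = synthetic_differential((5, 5), (5, 5), noise=0.0)
        feats = extract_motion_features(cmap, max_pair_px=1.0, search_radius_px=50)
        if feats:  # fully overlapping ± lobes cancel; zero displacement if paired
            np.testing.assert_allclose(
                estimate_displacement(feats[0], config), (0.0, 0.0), atol=1e-6
            )

    def test_half_pixel_shift_recovered(self):
        """Sub-pixel lobe positions from the 3-point parabolic fit are good
        to a quarter pixel on constructed Gaussian lobes."""
        cmap = synthetic_differential((10, 0), (-10, -15), amplitude=1.0, noise=0.0, width=2.5)
        shifted = synthetic_differential((10, 0), (-10, -14), amplitude=1.0, noise=0.0, width=2.5)
        blend = CorrelationMap(
            values=0.5 * (cmap.values + shifted.values), lag_pitch=1.0, kind="differential"
        )  # negative lobe centred at col −14.5
        feats = extract_motion_features(blend, search_radius_px=55)
        assert len(feats) == 1
        assert feats[0].negative_lobe_px[1] == pytest.approx(-14.5, abs=0.25)

    def test_geometry_mapping_uses_printed_scale(self):
        config = OpticalConfig()  # L_o=430, L_s=50, flipped
        cmap = synthetic_differential((0, 10), (0, -10), noise=0.0)
        feats = extract_motion_features(cmap, search_radius_px=50)
        det_mm = np.array(feats[0].displacement_det)
        obj_mm = estimate_displacement(feats[0], config)
        np.testing.assert_allclose(obj_mm, -det_mm * 430.0 / 50.0, atol=1e-6)


class TestSimulatedDisplacementRecovery:
    def test_star_displacement_within_five_percent(self):
        """Forward-simulate a 2.15 mm object-plane shift with the printed
        430/50 mm geometry and invert it through the pipeline."""
        config = replace(OpticalConfig(), L=0.01)  # wide isoplanatic patch
        pitch = config.object_pixel_pitch
        seq = make_dotfield_scene(
            n_dots=25, grid=(256, 256), seed=501, pixel_pitch=pitch
        )
        shift_mm = 2.15  # ≈ 66.7 object px; detector lobes 0.25 mm apart
        seq = apply_motion(
            seq,
            len(seq.sub_objects) - 1,
            [Motion(), Motion(translation=(0.0, shift_mm))],
        )
        frames = render_sequence(seq, ScatteringScreen(seed=502, shape=(256, 256)), config)
        est = estimate_step(
            differential_correlation(frames[1], frames[0]), config,
            TrackingParams(search_radius_px=90),
        )
        assert est is not None
        assert est.step_mm[1] == pytest.approx(shift_mm, rel=0.05)

    def test_random_motions_median_error_below_one_pixel(self):
        """Displacement recovery over random single-object motions: median
        error < 1 object px, 95th percentile < 2 px."""
        config = replace(OpticalConfig(), L=0.01)
        pitch = config.object_pixel_pitch
        rng = np.random.default_rng(42)
        errors = []
        for trial in range(10):
            seq = make_dotfield_scene(n_dots=25, grid=(256, 256), seed=510 + trial, pixel_pitch=pitch)
            angle = rng.uniform(0, 2 * np.pi)
            magnitude = rng.uniform(15, 40)
            step = magnitude * np.array([np.sin(angle), np.cos(angle)])
            seq = apply_motion(
                seq,
                len(seq.sub_objects) - 1,
                [Motion(), Motion(translation=tuple(step * pitch))],
            )
            frames = render_sequence(seq, ScatteringScreen(seed=530 + trial, shape=(256, 256)), config)
            est = estimate_step(differential_correlation(frames[1], frames[0]), config)
            assert est is not None
            errors.append(np.linalg.norm(est.step_mm / pitch - step))
        errors = np.array(errors)
        assert np.median(errors) < 1.0
        assert np.quantile(errors, 0.95) < 2.0


class TestReferenceLag:
    def test_single_candidate_returned(self, moving_star_frames, tracking_config):
        frames, _ = moving_star_frames
        choice = choose_reference_lag(frames, 1, [1], config=tracking_config)
        assert choice.lag == 1

    def test_stop_and_go_prefers_longer_lag(self, tracking_config):
        """An object static for two frames then jumping is invisible at the
        static steps and detected against the older reference."""
        pitch = tracking_config.object_pixel_pitch
        seq = make_dotfield_scene(n_dots=60, grid=(256, 256), seed=79, pixel_pitch=pitch)
        motions = [Motion(), Motion(), Motion(), Motion(translation=(0.0, 14 * pitch))]
        seq = apply_motion(seq, len(seq.sub_objects) - 1, motions)
        frames = render_sequence(seq, ScatteringScreen(seed=80, shape=(256, 256)), tracking_config)
        static = choose_reference_lag(frames, 2, [1, 2], config=tracking_config)
        assert static.lag is None  # nothing moved yet
        moved = choose_reference_lag(frames, 3, [1, 2, 3], config=tracking_config)
        assert moved.lag is not None

    def test_empty_history_rejected(self, tracking_config):
        with pytest.raises(ValueError):
            choose_reference_lag([], 0, [1], config=tracking_config)


class TestBuildTrajectory:
    def test_static_scene_gives_zero_trajectory(self, tracking_config):
        pitch = tracking_config.object_pixel_pitch
        seq = make_dotfield_scene(n_dots=40, grid=(256, 256), seed=90, pixel_pitch=pitch)
        seq = apply_motion(seq, len(seq.sub_objects) - 1, [Motion()] * 4)
        frames = render_sequence(seq, ScatteringScreen(seed=91, shape=(256, 256)), tracking_config)
        traj = build_trajectory(frames, tracking_config)
        np.testing.assert_array_equal(traj.steps, 0.0)
        np.testing.assert_array_equal(traj.cumulative, 0.0)

    def test_beyond_memory_tracking(self, moving_star_frames, tracking_config):
        """Ten 12-px steps chain to >3× the ~31 px memory range with a small
        relative error — mosaicing of the isoplanatic patch."""
        frames, step_px = moving_star_frames
        pitch = tracking_config.object_pixel_pitch
        traj = build_trajectory(frames, tracking_config, TrackingParams(candidate_lags=(1,)))
        total_px = traj.cumulative[-1] / pitch
        truth_px = 9 * np.asarray(step_px)
        path_len = np.linalg.norm(truth_px)
        memory_range_px = MemoryKernel(tracking_config).half_range_object_mm() / pitch
        assert path_len > 3 * memory_range_px
        assert np.linalg.norm(total_px - truth_px) < 0.025 * path_len

    def test_cumulative_is_exact_prefix_sum(self, moving_star_frames, tracking_config):
        frames, _ = moving_star_frames
        traj = build_trajectory(frames, tracking_config, TrackingParams(candidate_lags=(1,)))
        np.testing.assert_array_equal(
            traj.cumulative, np.vstack([np.zeros(2), np.cumsum(traj.steps, axis=0)])
        )

    def test_loop_closure_on_square_path(self, tracking_config):
        pitch = tracking_config.object_pixel_pitch
        seq = make_dotfield_scene(n_dots=60, grid=(256, 256), seed=77, pixel_pitch=pitch)
        seq = apply_motion(seq, len(seq.sub_objects) - 1, square_path_motion(36.0, 3, pitch))
        frames = render_sequence(seq, ScatteringScreen(seed=78, shape=(256, 256)), tracking_config)
        traj = build_trajectory(frames, tracking_config, TrackingParams(candidate_lags=(1,)))
        closure_px = np.linalg.norm(traj.cumulative[-1]) / pitch
        assert closure_px < 2.0

    def test_no_false_motion_on_noisy_static_scenes(self, tracking_config):
        """20 static sequences with camera noise: zero motion features at 5σ."""
        pitch = tracking_config.object_pixel_pitch
        false_steps = 0
        false_features = 0
        for s in range(5):
            seq = make_dotfield_scene(n_dots=40, grid=(256, 256), seed=100 + s, pixel_pitch=pitch)
            seq = apply_motion(seq, len(seq.sub_objects) - 1, [Motion()] * 2)
            frames = render_sequence(
                seq, ScatteringScreen(seed=200 + s, shape=(256, 256)), tracking_config
            )
            for t in range(4):
                noisy = [
                    add_camera_noise(f, seed=300 + s * 10 + t * 2 + j)
                    for j, f in enumerate(frames)
                ]
                dmap = differential_correlation(noisy[1], noisy[0])
                false_features += len(extract_motion_features(dmap, threshold_sigma=5.0))
                if estimate_step(dmap, tracking_config) is not None:
                    false_steps += 1
        assert false_features == 0
        assert false_steps == 0

    def test_trajectory_export(self, tmp_path, moving_star_frames, tracking_config):
        frames, _ = moving_star_frames
        traj = build_trajectory(frames[:4], tracking_config, TrackingParams(candidate_lags=(1,)))
        path = tmp_path / "trajectory.tsv"
        save_trajectory(traj, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == [
            "frame", "dx_mm", "dy_mm", "cum_x_mm", "cum_y_mm", "ref_lag", "snr",
        ]
        assert len(lines) == 4  # header + 3 steps


class TestRotation:
    @pytest.mark.parametrize("truth", [12.5, -9.0])
    def test_rotating_star_angle_recovered(self, config, truth):
        """The autocorrelation rotates with a rotating object; the polar
        estimator recovers the angle within 2°."""
        pitch = config.object_pixel_pitch
        subs = [SubObject(star_sprite(30, n_points=5), anchor=(0.0, 0.0), mobile=True)]
        seq = make_multishape_scene(subs, grid=(256, 256), pixel_pitch=pitch)
        seq = apply_motion(seq, 0, [Motion(), Motion(rotation_deg=truth)])
        frames = render_sequence(seq, ScatteringScreen(seed=24, shape=(256, 256)), config)
        estimate = estimate_rotation(autocorrelate(frames[1]), autocorrelate(frames[0]))
        assert estimate == pytest.approx(truth, abs=2.0)
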