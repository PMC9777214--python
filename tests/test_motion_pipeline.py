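"""Marker pipeline: centres, poses, angle trajectories, ROM, cohort stats."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from armkin import (
    DEFAULT_GEOMETRY,
    EndEffectorPose,
    InvalidInputError,
    MarkerFrameSeries,
    MotionProfileSpec,
    ROMRecord,
    TrajectoryQualityError,
    angles_over_time,
    build_end_effector_poses,
    cohort_stats,
    composite_rom,
    compute_rom,
    estimate_joint_centers,
    forward_kinematics,
    generate_joint_profiles,
    geometry_from_centers,
    lowpass_markers,
    read_marker_csv,
    round_half_away,
    synthesize_markers,
)
from armkin.motion_pipeline import (
    MARKER_LABELS,
    AngleTrajectory,
    records_from_csv,
    records_to_csv,
)


def constant_frames(n=5, dt=0.02, overrides=None):
    """Minimal marker series with all clusters at fixed positions."""
    base = {
        "SC": (0.0, 0.0, 0.0),
        "SH1": (180.0, 50.0, 0.0),
        "SH2": (180.0, -25.0, 43.0),
        "SH3": (180.0, -25.0, -43.0),
        "EL1": (180.0, 35.0, -300.0),
        "EL2": (180.0, -35.0, -300.0),
        "WR1": (180.0, 25.0, -560.0),
        "WR2": (180.0, -25.0, -560.0),
    }
    if overrides:
        base.update(overrides)
    markers = {lab: np.tile(np.asarray(base[lab], float), (n, 1)) for lab in MARKER_LABELS}
    return MarkerFrameSeries(time=np.arange(n) * dt, markers=markers)


class TestEstimateJointCenters:
    def test_shoulder_centroid(self):
        frames = constant_frames(overrides={
            "SH1": (1.0, 0.0, 0.0), "SH2": (0.0, 1.0, 0.0), "SH3": (0.0, 0.0, 1.0),
        })
        # centroid in world coordinates, before base-frame rotation
        s_w = (frames.markers["SH1"] + frames.markers["SH2"] + frames.markers["SH3"]) / 3
        np.testing.assert_allclose(s_w[0], [1 / 3, 1 / 3, 1 / 3])

    def test_inverts_synthetic_markers_exactly(self, geometry, rng):
        # theta_1 pinned to zero so the calibration yaw is exactly zero and
        # the base frame coincides with the generator's
        spec = MotionProfileSpec(
            amplitude_jitter_sd=0.0, marker_noise_sd=0.0, seed=4,
            amplitude=(0.0, -15.0, 39.0, 129.0, 57.0, 23.0),
            offset=(0.0, -8.0, -20.0, 12.0, 12.0, 15.0),
        )
        truth = generate_joint_profiles(spec)
        markers = synthesize_markers(truth, geometry, spec)
        centers = estimate_joint_centers(markers)
        for i in range(0, len(truth), 97):
            chain = forward_kinematics(geometry, truth.theta[i])
            np.testing.assert_allclose(centers.shoulder[i], chain.shoulder, atol=1e-9)
            np.testing.assert_allclose(centers.elbow[i], chain.elbow, atol=1e-9)
            np.testing.assert_allclose(centers.end_effector[i], chain.end_effector, atol=1e-9)

    def test_base_normalization_undoes_world_placement(self, geometry):
        spec = MotionProfileSpec(
            amplitude_jitter_sd=0.0, marker_noise_sd=0.0, seed=4,
            amplitude=(0.0, -15.0, 39.0, 129.0, 57.0, 23.0),
            offset=(0.0, -8.0, -20.0, 12.0, 12.0, 15.0),
            base_position=(500.0, -300.0, 1100.0),
        )
        truth = generate_joint_profiles(spec)
        markers = synthesize_markers(truth, geometry, spec)
        centers = estimate_joint_centers(markers)
        chain = forward_kinematics(geometry, truth.theta[0])
        np.testing.assert_allclose(centers.end_effector[0], chain.end_effector, atol=1e-6)

    def test_gap_frame_flagged_nan(self):
        frames = constant_frames(n=6)
        frames.markers["WR1"][3] = np.nan
        centers = estimate_joint_centers(frames, calibration_seconds=0.05)
        assert centers.gap[3] and not centers.gap[2]
        assert np.all(np.isnan(centers.end_effector[3]))
        assert np.all(np.isfinite(centers.end_effector[2]))

    def test_geometry_from_centers(self, geometry):
        spec = MotionProfileSpec(amplitude_jitter_sd=0.0, marker_noise_sd=0.0, seed=4)
        truth = generate_joint_profiles(spec)
        markers = synthesize_markers(truth, geometry, spec)
        g = geometry_from_centers(estimate_joint_centers(markers))
        assert g.l2 == pytest.approx(geometry.l2, abs=1e-6)
        assert g.d5 == pytest.approx(geometry.d5, abs=1e-6)
        assert g.l6 == pytest.approx(geometry.l6, abs=1e-6)


class TestBuildPoses:
    def test_cross_product_construction(self):
        # E at origin, wrist along +x, shoulder along +y:
        # x = (1,0,0); z = unit(x cross (S-E)) = (0,0,1); y = z cross x = (0,1,0)
        from armkin.motion_pipeline import JointCenterSeries

        centers = JointCenterSeries(
            time=np.array([0.0]),
            shoulder=np.array([[0.0, 1.0, 0.0]]),
            elbow=np.array([[0.0, 0.0, 0.0]]),
            end_effector=np.array([[1.0, 0.0, 0.0]]),
            gap=np.array([False]),
            world_to_base=np.eye(3),
        )
        [pose] = build_end_effector_poses(centers)
        np.testing.assert_allclose(pose.rotation[:, 0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(pose.rotation[:, 2], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(pose.rotation[:, 1], [0, 1, 0], atol=1e-12)

    def test_matches_fk_wrist_frame(self, geometry):
        spec = MotionProfileSpec(
            amplitude_jitter_sd=0.0, marker_noise_sd=0.0, seed=4,
            amplitude=(0.0, -15.0, 39.0, 129.0, 57.0, 23.0),
            offset=(0.0, -8.0, -20.0, 12.0, 12.0, 15.0),
        )
        truth = generate_joint_profiles(spec)
        markers = synthesize_markers(truth, geometry, spec)
        poses = build_end_effector_poses(estimate_joint_centers(markers))
        for i in range(0, len(truth), 181):
            chain = forward_kinematics(geometry, truth.theta[i])
            np.testing.assert_allclose(poses[i].rotation[:, 0], chain.pose[:3, 0], atol=1e-9)
            np.testing.assert_allclose(poses[i].rotation, chain.pose[:3, :3], atol=1e-9)

    def test_collinear_centers_flagged(self):
        from armkin.motion_pipeline import JointCenterSeries

        centers = JointCenterSeries(
            time=np.array([0.0]),
            shoulder=np.array([[2.0, 0.0, 0.0]]),
            elbow=np.array([[0.0, 0.0, 0.0]]),
            end_effector=np.array([[1.0, 0.0, 0.0]]),
            gap=np.array([False]),
            world_to_base=np.eye(3),
        )
        assert build_end_effector_poses(centers) == [None]


class TestAnglesOverTime:
    def test_constant_pose_constant_series(self, geometry):
        th = np.radians([5.0, -25.0, -10.0, 70.0, 40.0, 25.0])
        pose = EndEffectorPose.from_matrix(forward_kinematics(geometry, th).pose)
        traj = angles_over_time([pose] * 100, geometry)
        assert np.allclose(traj.theta, np.tile(th, (100, 1)), atol=1e-9)

    def test_unwrap_through_pi_boundary(self, geometry):
        """theta_3 sweeping through +-pi must unwrap smoothly."""
        n = 120
        t3 = np.pi - 0.2 + 0.4 * np.arange(n) / n  # crosses +pi
        poses = []
        for v in t3:
            th = np.array([0.1, -0.5, v, 1.2, 0.7, 0.4])
            poses.append(EndEffectorPose.from_matrix(forward_kinematics(geometry, th).pose))
        traj = angles_over_time(poses, geometry)
        steps = np.abs(np.diff(traj.theta[:, 2]))
        assert np.nanmax(steps) < np.pi

    def test_gap_and_violation_frames_isolated(self, geometry):
        th = np.radians([5.0, -25.0, -10.0, 70.0, 40.0, 25.0])
        pose = EndEffectorPose.from_matrix(forward_kinematics(geometry, th).pose)
        poses = [pose] * 7
        poses[3] = None
        traj = angles_over_time(poses, geometry)
        assert traj.qc[3]["flag"] == "gap"
        assert np.all(np.isnan(traj.theta[3]))
        assert np.all(np.isfinite(traj.theta[2])) and np.all(np.isfinite(traj.theta[4]))

    def test_mostly_flagged_trajectory_rejected(self, geometry):
        th = np.radians([5.0, -25.0, -10.0, 70.0, 40.0, 25.0])
        pose = EndEffectorPose.from_matrix(forward_kinematics(geometry, th).pose)
        poses = [pose, None, None, None]
        with pytest.raises(TrajectoryQualityError):
            angles_over_time(poses, geometry)

    def test_qc_log_json_lines(self, geometry, tmp_path):
        th = np.radians([5.0, -25.0, -10.0, 70.0, 40.0, 25.0])
        pose = EndEffectorPose.from_matrix(forward_kinematics(geometry, th).pose)
        traj = angles_over_time([pose] * 3, geometry)
        path = tmp_path / "qc.jsonl"
        traj.write_qc_log(path)
        recs = [json.loads(line) for line in path.read_text().splitlines()]
        assert len(recs) == 3 and all(r["flag"] == "ok" for r in recs)


def raised_cosine_trajectory(amplitudes_per_cycle, offset=0.3, n_per=100, dt=0.02):
    """Ground-truth style trajectory: one joint dominant, others scaled."""
    reps = len(amplitudes_per_cycle)
    n = reps * n_per + 1
    u = (np.arange(n) % n_per) / n_per
    u[-1] = 1.0
    cyc = np.minimum(np.arange(n) // n_per, reps - 1)
    amp = np.asarray(amplitudes_per_cycle)[cyc]
    bump = 0.5 * (1 - np.cos(2 * np.pi * u))
    theta = np.zeros((n, 6))
    scale = (0.2, 0.1, 0.3, 1.0, 0.4, 0.15)
    for k in range(6):
        theta[:, k] = offset + scale[k] * amp * bump
    return AngleTrajectory(time=np.arange(n) * dt, theta=theta, qc=[])


class TestComputeRom:
    def test_sinusoid_rom_is_twice_amplitude(self):
        t = np.linspace(0, 20, 2001)
        a = 0.7
        theta = np.tile(a * np.sin(2 * np.pi * 0.5 * t)[:, None], (1, 6))
        traj = AngleTrajectory(time=t, theta=theta, qc=[])
        for mode in ("global", "per_cycle"):
            rom = compute_rom(traj, mode)
            np.testing.assert_allclose(rom, np.degrees(2 * a), atol=0.01)

    def test_constant_series_zero_rom(self):
        traj = AngleTrajectory(time=np.arange(10.0), theta=np.ones((10, 6)), qc=[])
        np.testing.assert_allclose(compute_rom(traj, "global"), 0.0)
        np.testing.assert_allclose(compute_rom(traj, "per_cycle"), 0.0)

    def test_per_cycle_mean_vs_global_max(self, rng):
        amps = np.radians(rng.uniform(120.0, 140.0, size=10))
        traj = raised_cosine_trajectory(amps)
        per = compute_rom(traj, "per_cycle")
        glob = compute_rom(traj, "global")
        assert per[3] == pytest.approx(np.degrees(amps.mean()), abs=0.5)
        assert glob[3] == pytest.approx(np.degrees(amps.max()), abs=1e-6)

    def test_invariances(self):
        amps = np.radians(np.full(10, 130.0))
        traj = raised_cosine_trajectory(amps)
        base = compute_rom(traj, "per_cycle")
        shifted = AngleTrajectory(time=traj.time + 42.0, theta=traj.theta.copy(), qc=[])
        offset = AngleTrajectory(time=traj.time, theta=traj.theta + 1.23, qc=[])
        resampled = AngleTrajectory(time=traj.time[::2], theta=traj.theta[::2], qc=[])
        np.testing.assert_allclose(compute_rom(shifted, "per_cycle"), base, atol=1e-9)
        np.testing.assert_allclose(compute_rom(offset, "per_cycle"), base, atol=1e-9)
        np.testing.assert_allclose(compute_rom(resampled, "per_cycle"), base, atol=0.1)

    def test_all_nan_rejected(self):
        traj = AngleTrajectory(time=np.arange(5.0), theta=np.full((5, 6), np.nan), qc=[])
        with pytest.raises(TrajectoryQualityError):
            compute_rom(traj, "global")


class TestCompositeRom:
    def test_abduction_sums_theta2_theta4(self):
        rom = [28.9, 17.6, 46.1, 130.4, 69.3, 20.7]
        assert composite_rom(rom, "abduction_adduction") == pytest.approx(148.0)

    def test_female_abduction_value(self):
        rom = [18.3, 11.5, 31.9, 127.2, 44.8, 26.2]
        assert composite_rom(rom, "abduction_adduction") == pytest.approx(138.7)

    def test_rotation_uses_theta5(self):
        rom = [4.9, 3.2, 8.0, 8.5, 111.1, 23.4]
        assert composite_rom(rom, "external_internal") == pytest.approx(111.1)

    def test_zero_rom(self):
        assert composite_rom([0.0] * 6, "abduction_adduction") == 0.0

    def test_unknown_motion(self):
        with pytest.raises(InvalidInputError):
            composite_rom([0.0] * 6, "circumduction")


def record(sid, sex, height, rom, motion="abduction_adduction"):
    return ROMRecord(subject_id=sid, sex=sex, height=height, motion=motion, rom=tuple(rom))


class TestCohortStats:
    def test_population_sd_matches_printed_heights(self):
        """Male heights 170,174,177,190,172 -> SD 7.1 only with divisor n."""
        recs = [record(f"M{i}", "M", h, [1.0] * 6) for i, h in
                enumerate([170, 174, 177, 190, 172])]
        recs += [record(f"F{i}", "F", h, [1.0] * 6) for i, h in
                 enumerate([161, 159, 165, 160, 154])]
        table = cohort_stats(recs)
        assert round_half_away(table.sd["M"]["height"]) == 7.1
        assert round_half_away(table.sem["M"]["height"]) == 3.2

    def test_sem_is_sd_over_sqrt_n(self):
        recs = [record(f"M{i}", "M", 175, [float(i)] * 6) for i in range(5)]
        recs += [record(f"F{i}", "F", 160, [float(2 * i)] * 6) for i in range(5)]
        table = cohort_stats(recs)
        for stratum in ("M", "F", "T"):
            np.testing.assert_allclose(
                table.sem[stratum], table.sd[stratum] / math.sqrt(table.n[stratum])
            )

    def test_single_record_stratum_zero_spread(self):
        recs = [record("M1", "M", 175, [10.0] * 6), record("F1", "F", 160, [12.0] * 6)]
        table = cohort_stats(recs)
        assert float(table.sd["M"]["theta1"]) == 0.0
        assert float(table.sem["M"]["theta1"]) == 0.0

    def test_mixed_motions_rejected(self):
        recs = [record("M1", "M", 175, [10.0] * 6),
                record("F1", "F", 160, [12.0] * 6, motion="external_internal")]
        with pytest.raises(InvalidInputError):
            cohort_stats(recs)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            cohort_stats([])


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.25, 0.3), (-0.25, -0.3), (0.24, 0.2), (1.05, 1.1), (-1.05, -1.1), (2.0, 2.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == pytest.approx(expected)


class TestMarkerIO:
    def test_csv_round_trip(self, tmp_path, geometry):
        spec = MotionProfileSpec(amplitude_jitter_sd=0.0, marker_noise_sd=0.0, seed=4,
                                 n_reps=1)
        truth = generate_joint_profiles(spec)
        markers = synthesize_markers(truth, geometry, spec)
        p = tmp_path / "markers.csv"
        markers.to_csv(p)
        back = read_marker_csv(p)
        np.testing.assert_allclose(back.time, markers.time)
        for lab in MARKER_LABELS:
            np.testing.assert_allclose(back.markers[lab], markers.markers[lab], atol=1e-9)

    def test_label_map(self, tmp_path):
        frames = constant_frames(n=3)
        df = frames.to_frame().rename(columns={f"SC_{ax}": f"Clav_{ax}" for ax in "xyz"})
        p = tmp_path / "renamed.csv"
        df.to_csv(p, index=False)
        back = read_marker_csv(p, label_map={"SC": "Clav"})
        np.testing.assert_allclose(back.markers["SC"], frames.markers["SC"])

    def test_records_csv_round_trip(self, tmp_path):
        recs = [record("M1", "M", 175, [1, 2, 3, 4, 5, 6.0])]
        p = tmp_path / "rom.csv"
        records_to_csv(recs, p)
        back = records_from_csv(p)
        assert back == recs

    def test_lowpass_preserves_slow_waveform(self):
        t = np.arange(0, 20, 0.02)
        slow = 100 * np.sin(2 * np.pi * 0.5 * t)
        markers = {lab: np.column_stack([slow, slow, slow]) for lab in MARKER_LABELS}
        frames = MarkerFrameSeries(time=t, markers=markers)
        out = lowpass_markers(frames, 3.0)
        err = np.abs(out.markers["SC"][:, 0] - slow)
        # ignore short filter edge transients
        assert err[50:-50].max() < 0.5
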