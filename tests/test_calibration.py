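"""Rigid registration (SVD with reflection guard) and checkerboard
calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gaitconcord.calibration import (
    CheckerboardObservation,
    GridSpec,
    PointSet,
    RigidTransform,
    calibrate_device_to_reference,
    extrapolate_corner_markers,
    fit_grid_to_board,
    generate_grid,
    rigid_register,
    transform_sequence,
)
from gaitconcord.simulate import random_rigid_transform, simulate_checkerboard_scene


def brute_force_min_residual(P: np.ndarray, Q: np.ndarray, n_grid: int = 24) -> float:
    """Independent minimum of the rigid objective over proper rotations:
    coarse Euler-angle grid followed by local polish; the translation is
    optimal in closed form for each rotation."""

    def rms_for(R):
        t = Q.mean(axis=0) - R @ P.mean(axis=0)
        r = P @ R.T + t - Q
        return np.sqrt(np.sum(r**2) / P.shape[0])

    best = np.inf
    best_angles = None
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    grid_b = np.linspace(-np.pi / 2, np.pi / 2, n_grid // 2)
    for a in grid:
        for b in grid_b:
            for c in grid:
                R = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                v = rms_for(R)
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(
        lambda ang: rms_for(Rotation.from_euler("zyx", ang).as_matrix()),
        best_angles,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return min(best, float(res.fun))


class TestGenerateGrid:
    def test_single_point_board(self):
        pts = generate_grid(GridSpec(1, 1, 50.0)).points
        np.testing.assert_allclose(pts, [[50.0, 50.0, 0.0]])

    def test_two_by_two_row_major(self):
        pts = generate_grid(GridSpec(2, 2, 50.0)).points
        np.testing.assert_allclose(
            pts, [[50, 50, 0], [100, 50, 0], [50, 100, 0], [100, 100, 0]]
        )

    def test_eight_by_five_extent(self):
        pts = generate_grid(GridSpec(8, 5, 50.0)).points
        assert pts.shape == (40, 3)
        np.testing.assert_allclose(pts.min(axis=0), [50, 50, 0])
        np.testing.assert_allclose(pts.max(axis=0), [400, 250, 0])

    def test_degenerate_board_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            GridSpec(0, 5, 50.0)


class TestRigidRegister:
    def test_identity_on_equal_sets(self, rng):
        P = PointSet(rng.normal(size=(10, 3)) * 100)
        T, rms = rigid_register(P, P)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0, atol=1e-9)
        assert rms < 1e-9

    def test_recovers_constructed_transform(self, rng):
        P = PointSet(rng.normal(size=(8, 3)) * 100)
        R0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t0 = np.array([10.0, 20.0, 30.0])
        Q = PointSet(P.points @ R0.T + t0)
        T, rms = rigid_register(P, Q)
        np.testing.assert_allclose(T.rotation, R0, atol=1e-9)
        np.testing.assert_allclose(T.translation, t0, atol=1e-9)
        assert rms < 1e-9

    @pytest.mark.parametrize("angle_deg", [1.0, 90.0, 179.0, 179.99])
    def test_exact_including_near_half_turn(self, rng, angle_deg):
        P = PointSet(rng.normal(size=(6, 3)) * 100)
        R0 = Rotation.from_rotvec(np.radians(angle_deg) * np.array([0.6, 0.64, 0.48])).as_matrix()
        Q = PointSet(P.points @ R0.T + [5.0, -3.0, 7.0])
        T, rms = rigid_register(P, Q)
        assert rms < 1e-9
        np.testing.assert_allclose(T.rotation, R0, atol=1e-8)

    def test_mirrored_set_gets_proper_rotation_at_brute_force_minimum(self, rng):
        P = PointSet(rng.normal(size=(4, 3)) * 100)
        Q = PointSet(P.points * np.array([1.0, 1.0, -1.0]))  # reflection
        T, rms = rigid_register(P, Q)
        assert np.isclose(np.linalg.det(T.rotation), 1.0, atol=1e-9)
        brute = brute_force_min_residual(P.points, Q.points)
        assert rms <= brute * 1.01 + 1e-9

    def test_underdetermined_rejected(self):
        P = PointSet(np.array([[0.0, 0, 0], [1, 0, 0]]))
        with pytest.raises(ValueError, match="underdetermined"):
            rigid_register(P, P)

    @given(st.integers(0, 2**31 - 1))
    def test_residual_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        P = PointSet(rng.normal(size=(7, 3)) * 50)
        Q = PointSet(P.points + rng.normal(size=(7, 3)))
        _, rms1 = rigid_register(P, Q)
        M = random_rigid_transform(rng)
        _, rms2 = rigid_register(PointSet(M.apply(P.points)), PointSet(M.apply(Q.points)))
        assert np.isclose(rms1, rms2, atol=1e-8)

    @given(st.integers(0, 2**31 - 1))
    def test_determinant_always_plus_one(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        P = rng.normal(size=(5, 3)) * 100
        if kind == 1:  # planar
            P[:, 2] = 0.0
        Q = P @ Rotation.random(random_state=rng).as_matrix().T
        if kind == 2:  # mirrored
            Q = Q * np.array([1.0, -1.0, 1.0])
        T, _ = rigid_register(PointSet(P), PointSet(Q))
        assert np.isclose(np.linalg.det(T.rotation), 1.0, atol=1e-9)


class TestBoardFitAndExtrapolation:
    def test_grid_onto_itself_is_identity(self):
        board = GridSpec(4, 3, 50.0)
        T, rms = fit_grid_to_board(generate_grid(board), board)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        assert rms < 1e-9

    def test_posed_grid_recovered_exactly(self, rng):
        board = GridSpec(8, 5, 50.0)
        pose = random_rigid_transform(rng)
        obs = PointSet(pose.apply(generate_grid(board).points))
        T, rms = fit_grid_to_board(obs, board)
        assert rms < 1e-9
        np.testing.assert_allclose(T.rotation, pose.rotation, atol=1e-8)

    def test_incomplete_board_rejected(self):
        board = GridSpec(8, 5, 50.0)
        with pytest.raises(ValueError, match="incomplete board"):
            fit_grid_to_board(PointSet(np.zeros((10, 3)) + np.arange(30).reshape(10, 3)), board)

    def test_corner_extrapolation_matches_matrix_apply(self, rng):
        board = GridSpec(8, 5, 50.0)
        pose = random_rigid_transform(rng)
        got = extrapolate_corner_markers(pose, board).points
        expected = board.corner_marker_offsets @ pose.rotation.T + pose.translation
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_corner_extrapolation_pure_translation(self):
        board = GridSpec(2, 2, 50.0)
        T = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        got = extrapolate_corner_markers(T, board).points
        np.testing.assert_allclose(got, board.corner_marker_offsets + [1, 2, 3], atol=1e-12)


class TestDeviceCalibration:
    def test_noiseless_identity_scene(self):
        scenes = simulate_checkerboard_scene(
            RigidTransform.identity(), GridSpec(8, 5, 50.0), 1, 0.0, seed=1
        )
        T, rms = calibrate_device_to_reference(scenes)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-6)
        assert rms < 1e-6

    def test_noiseless_recovery_of_known_transform(self, rng):
        truth = random_rigid_transform(rng)
        scenes = simulate_checkerboard_scene(truth, GridSpec(8, 5, 50.0), 5, 0.0, seed=2)
        T, rms = calibrate_device_to_reference(scenes)
        np.testing.assert_allclose(T.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(T.translation, truth.translation, atol=1e-6)

    def test_noisy_recovery_within_tolerance(self, rng):
        truth = random_rigid_transform(rng)
        scenes = simulate_checkerboard_scene(truth, GridSpec(8, 5, 50.0), 5, 0.5, seed=3)
        T, _ = calibrate_device_to_reference(scenes)
        err = T.compose(truth.inverse())
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(T.translation - truth.translation) < 1.0

    def test_all_incomplete_placements_rejected(self):
        board = GridSpec(8, 5, 50.0)
        obs = CheckerboardObservation(
            device_points=PointSet(np.eye(3) * 10),  # 3 of 40 points
            reference_corner_points=PointSet(board.corner_marker_offsets),
            board=board,
        )
        with pytest.raises(ValueError, match="no usable observations"):
            calibrate_device_to_reference([obs])


class TestTransformSequence:
    def test_identity_leaves_sequence_unchanged(self, make_sequence):
        seq = make_sequence(missing_frac=0.1)
        out = transform_sequence(seq, RigidTransform.identity())
        np.testing.assert_allclose(out.positions, seq.positions, equal_nan=True)

    def test_inverse_round_trip(self, make_sequence, rng):
        seq = make_sequence()
        T = random_rigid_transform(rng)
        back = transform_sequence(transform_sequence(seq, T), T.inverse())
        np.testing.assert_allclose(back.positions, seq.positions, atol=1e-9)

    def test_matches_per_point_matrix_apply_and_keeps_missing(self, make_sequence, rng):
        seq = make_sequence(missing_frac=0.2)
        T = random_rigid_transform(rng)
        out = transform_sequence(seq, T)
        assert np.array_equal(np.isnan(out.positions), np.isnan(seq.positions))
        ok = ~np.isnan(seq.positions).any(axis=2)
        expected = seq.positions[ok] @ T.rotation.T + T.translation
        np.testing.assert_allclose(out.positions[ok], expected, atol=1e-9)
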