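"""Spatial calibration between a device camera frame and the reference frame.

The calibration targets a checkerboard carrying four retro-reflective
corner markers.  The device detects the board's interior intersection
points in its own 3D frame; the reference system measures the four corner
markers directly.  Calibration proceeds in two stages:

1. a synthetic planar grid with the board's known spacing is registered
   onto the detected intersection points (least-squares rigid fit), and the
   corner-marker offsets are extrapolated through that fit into the device
   frame;
2. the extrapolated device-frame corners are registered onto the measured
   reference-frame corners, pooled over all board placements, giving the
   device-to-reference rigid transform.

Rigid registration is the SVD (Kabsch) solution of

    argmin_{R, t}  sum_i || (R p_i + t) - q_i ||^2

with the determinant sign correction that excludes reflections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from gaitconcord.core import SkeletonSequence

__all__ = [
    "DegenerateConfigurationWarning",
    "GridSpec",
    "PointSet",
    "RigidTransform",
    "CheckerboardObservation",
    "generate_grid",
    "rigid_register",
    "fit_grid_to_board",
    "extrapolate_corner_markers",
    "calibrate_device_to_reference",
    "transform_sequence",
]


class DegenerateConfigurationWarning(UserWarning):
    """Point configuration leaves the rotation partly unconstrained."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform p -> R p + t (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal (tol 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1 (tol 1e-9)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to (..., 3) points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Rotation angle of R in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path: str | Path, **metadata) -> None:
        payload = {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            **metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class PointSet:
    """Ordered 3D points (mm) in a named coordinate frame."""

    points: np.ndarray
    frame_id: str = "unknown"

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
            raise ValueError("points must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(p)):
            raise ValueError("points must be finite")
        self.points = p

    def __len__(self) -> int:
        return self.points.shape[0]


def _default_corner_offsets(w: int, h: int, s: float) -> np.ndarray:
    # board outer corners, one square beyond the interior grid on each side
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [(w + 1) * s, 0.0, 0.0],
            [0.0, (h + 1) * s, 0.0],
            [(w + 1) * s, (h + 1) * s, 0.0],
        ]
    )


@dataclass
class GridSpec:
    """Checkerboard grid: w x h intersection points spaced s mm apart.

    ``corner_marker_offsets`` are the four corner-marker positions in board
    coordinates; the default places them at the board's outer corners.
    """

    w: int
    h: int
    s: float
    corner_marker_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("degenerate board: w and h must be >= 1")
        if self.s <= 0:
            raise ValueError("square side s must be positive")
        if self.corner_marker_offsets is None:
            self.corner_marker_offsets = _default_corner_offsets(self.w, self.h, self.s)
        self.corner_marker_offsets = np.asarray(self.corner_marker_offsets, dtype=float)
        if self.corner_marker_offsets.shape != (4, 3):
            raise ValueError("exactly four corner marker offsets required")

    @property
    def n_points(self) -> int:
        return self.w * self.h


@dataclass
class CheckerboardObservation:
    """One board placement: device-frame intersections + reference corners."""

    device_points: PointSet
    reference_corner_points: PointSet
    board: GridSpec

    def __post_init__(self) -> None:
        if len(self.reference_corner_points) != 4:
            raise ValueError("exactly four reference corner markers required")

    @property
    def complete(self) -> bool:
        return len(self.device_points) == self.board.n_points


def generate_grid(board: GridSpec) -> PointSet:
    """Synthetic board grid: points (x*s, y*s, 0), 1 <= x <= w, 1 <= y <= h.

    Row-major order: y is the outer loop, x the inner one.
    """
    ys, xs = np.meshgrid(np.arange(1, board.h + 1), np.arange(1, board.w + 1), indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(board.n_points)]) * [
        board.s,
        board.s,
        1.0,
    ]
    return PointSet(pts, frame_id="board")


def rigid_register(P: PointSet, Q: PointSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration of P onto Q (index correspondence).

    Returns the proper rigid transform minimising
    ``sum_i ||(R p_i + t) - q_i||^2`` together with the RMS residual in mm.
    The rotation is obtained from the SVD of the centred cross-covariance
    with the sign-correction diagonal that enforces det(R) = +1, so mirrored
    configurations never yield a reflection.
    """
    p = P.points
    q = Q.points
    n = p.shape[0]
    if q.shape[0] != n:
        raise ValueError(f"point counts differ: {n} vs {q.shape[0]}")
    if n < 3:
        raise ValueError("underdetermined: at least 3 point correspondences required")
    p_bar = p.mean(axis=0)
    q_bar = q.mean(axis=0)
    X = (p - p_bar).T  # centred vectors as columns
    Y = (q - q_bar).T
    S = X @ Y.T
    U, sv, Vt = np.linalg.svd(S)
    V = Vt.T
    d = np.sign(np.linalg.det(V @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = V @ D @ U.T
    t = q_bar - R @ p_bar
    # planar sets (rank-2 covariance) still fix the rotation once
    # reflections are excluded; only near-collinear sets are ambiguous
    if sv[0] > 0 and sv[1] < 1e-12 * sv[0]:
        warnings.warn(
            "degenerate configuration: rotation may be partly unconstrained",
            DegenerateConfigurationWarning,
            stacklevel=2,
        )
    resid = p @ R.T + t - q
    rms = float(np.sqrt(np.sum(resid**2) / n))
    return RigidTransform(R, t), rms


def fit_grid_to_board(obs_points: PointSet, board: GridSpec) -> tuple[RigidTransform, float]:
    """Fit the synthetic grid into detected intersections (grid -> device)."""
    if len(obs_points) != board.n_points:
        raise ValueError(
            f"incomplete board: expected {board.n_points} points, got {len(obs_points)}"
        )
    return rigid_register(generate_grid(board), obs_points)


def extrapolate_corner_markers(grid_to_device: RigidTransform, board: GridSpec) -> PointSet:
    """Map the four corner-marker offsets through the grid fit."""
    return PointSet(grid_to_device.apply(board.corner_marker_offsets), frame_id="device")


def calibrate_device_to_reference(
    observations: Sequence[CheckerboardObservation],
) -> tuple[RigidTransform, float]:
    """Two-stage device -> reference calibration over board placements.

    For every complete placement the grid is fitted into the detected
    device-frame intersections and the corner markers are extrapolated into
    the device frame; the pooled (extrapolated corner, measured reference
    corner) pairs across all placements feed one final rigid registration.
    """
    device_corners: list[np.ndarray] = []
    reference_corners: list[np.ndarray] = []
    for obs in observations:
        if not obs.complete:
            continue
        grid_to_device, _ = fit_grid_to_board(obs.device_points, obs.board)
        extrap = extrapolate_corner_markers(grid_to_device, obs.board)
        device_corners.append(extrap.points)
        reference_corners.append(obs.reference_corner_points.points)
    if not device_corners:
        raise ValueError("no usable observations: all placements incomplete")
    P = PointSet(np.vstack(device_corners), frame_id="device")
    Q = PointSet(np.vstack(reference_corners), frame_id="reference")
    return rigid_register(P, Q)


def transform_sequence(seq: SkeletonSequence, T: RigidTransform, frame_id: str | None = None) -> SkeletonSequence:
    """Apply a rigid transform to every non-missing position of a sequence."""
    pos = T.apply(seq.positions)
    # NaN triplets propagate through the affine map unchanged in pattern
    out = seq.copy()
    out.positions = pos
    out.frame_id = frame_id if frame_id is not None else f"{seq.frame_id}->transformed"
    return out
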