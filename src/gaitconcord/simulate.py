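"""Synthetic treadmill-gait world and camera observation models.

The simulator produces a ground-truth "world" of joint trajectories for a
subject walking on a treadmill between two triple-jump bouts, then renders
that world through configurable camera observation models: a low-noise
100 Hz reference stream and jittery ~30 Hz device streams with dropout
gaps, per-joint systematic offsets, distinct rigid coordinate frames and
unknown temporal lags.  Every injected quantity (event times, step
parameters, frame transforms, lags) is recorded in a :class:`GroundTruth`
ledger so each downstream processing stage can be verified exactly.

Signal model
------------
The anterio-posterior (AP) position of each foot relative to the sacrum is
a sinusoid — the belt pulls the stance foot back at near-constant speed
and the swing returns it — with a phase offset of π between sides and a
configurable left/right asymmetry.  Heel strikes are the AP maxima of the
heel/ankle signal, toe offs the AP minima of the toe signal, whose phase
lead is set by the duty factor (stance fraction of the stride).  The
pelvis vertical channel carries a small two-per-stride oscillation plus
Gaussian jump spikes (default amplitude 300 mm, σ = 0.1 s) at the
configured jump times; the sternum shares the pelvis vertical motion, so
either serves as the synchronization channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from gaitconcord.calibration import (
    CheckerboardObservation,
    GridSpec,
    PointSet,
    RigidTransform,
    generate_grid,
)
from gaitconcord.core import SkeletonSequence

__all__ = [
    "GaitWorldConfig",
    "ObservationModelConfig",
    "GroundTruth",
    "TREADMILL_PRESETS",
    "simulate_trial",
    "simulate_checkerboard_scene",
]

MM = 1000.0  # mm per metre

#: Walking regimes matching the three treadmill belt speeds of a typical
#: healthy-adult protocol (slow/medium/fast), with the corresponding mean
#: stride times and reference-system step parameters.
TREADMILL_PRESETS: dict[str, dict] = {
    "slow": {"treadmill_speed": 3.0 / 3.6, "stride_time": 1.28, "step_length": 0.48, "step_width": 0.21},
    "medium": {"treadmill_speed": 3.9 / 3.6, "stride_time": 1.13, "step_length": 0.55, "step_width": 0.20},
    "fast": {"treadmill_speed": 4.7 / 3.6, "stride_time": 1.04, "step_length": 0.61, "step_width": 0.20},
}

#: Canonical world joints (device naming); the reference stream renames a
#: subset to marker labels (LANK, RPSI, STRN, ...).
WORLD_JOINTS = [
    "pelvis",
    "sternum",
    "ankle_left",
    "ankle_right",
    "heel_left",
    "heel_right",
    "foot_left",
    "foot_right",
]

_REFERENCE_MARKER_OF = {
    "ankle_left": "LANK",
    "ankle_right": "RANK",
    "heel_left": "LHEE",
    "heel_right": "RHEE",
    "foot_left": "LTOE",
    "foot_right": "RTOE",
    "sternum": "STRN",
}


@dataclass
class GaitWorldConfig:
    """Ground-truth world parameters for one simulated treadmill trial.

    Lengths in metres, times in seconds.  ``duty_factor`` is the stance
    share of the stride.  ``jump_times`` are the centres of the six jump
    spikes (three before, three after the walking bout); defaults are
    placed 1 s apart starting 2 s into the trial and ending 2 s before its
    end.  The walking bout spans an integer number of strides between the
    jump bouts with a 2 s margin on both sides.
    """

    treadmill_speed: float = 3.0 / 3.6
    step_length: float = 0.48
    step_width: float = 0.21
    stride_time: float = 1.28
    duty_factor: float = 0.62
    trial_duration: float = 40.0
    jump_times: tuple[float, ...] | None = None
    jump_amplitude_mm: float = 300.0
    jump_sigma_s: float = 0.1
    asymmetry: float = 0.0
    subject_joint_set: tuple[str, ...] = tuple(WORLD_JOINTS)

    def __post_init__(self) -> None:
        for name in ("treadmill_speed", "step_length", "step_width", "stride_time", "trial_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.5 < self.duty_factor < 0.8:
            raise ValueError("duty_factor must lie in (0.5, 0.8)")
        if self.step_width >= self.step_length:
            raise ValueError("step_width must be smaller than step_length")
        if self.jump_times is None:
            d = self.trial_duration
            self.jump_times = (2.0, 3.0, 4.0, d - 4.0, d - 3.0, d - 2.0)
        self.jump_times = tuple(float(t) for t in self.jump_times)
        if any(t < 0 or t > self.trial_duration for t in self.jump_times):
            raise ValueError("jump_times must lie within the trial")
        t0, t1 = self.walking_window()
        if t1 - t0 < 2 * self.stride_time:
            raise ValueError(
                "trial_duration too short: walking bout must contain jumps plus "
                "at least two strides"
            )

    def walking_window(self) -> tuple[float, float]:
        """Walking bout [t0, t1]: between jump bouts with a 2 s margin,
        trimmed to an integer number of strides."""
        pre = [t for t in self.jump_times if t < self.trial_duration / 2]
        post = [t for t in self.jump_times if t >= self.trial_duration / 2]
        t0 = (max(pre) if pre else 0.0) + 2.0
        t1 = (min(post) if post else self.trial_duration) - 2.0
        if t1 <= t0:
            raise ValueError(
                "trial_duration too short: no room for a walking bout between the jump bouts"
            )
        n_strides = int(np.floor((t1 - t0) / self.stride_time))
        return t0, t0 + n_strides * self.stride_time

    # -- trajectory model --------------------------------------------------
    def world_positions(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluate the noiseless world trajectories (mm) at times ``t``.

        Defined for all real t: the subject stands still outside the walking
        bout and the jump spikes.
        """
        t = np.asarray(t, dtype=float)
        t0, t1 = self.walking_window()
        walking = ((t >= t0) & (t <= t1)).astype(float)
        T = self.stride_time
        phase = 2 * np.pi * (t - t0) / T

        # amplitude of the sacrum-relative AP foot sinusoid: the 3D
        # ankle-ankle distance at heel strike equals the configured step
        # length (ankles share a constant vertical height)
        half_span = np.sqrt((self.step_length * MM) ** 2 - (self.step_width * MM) ** 2) / 2.0
        amp_left = half_span * (1.0 + self.asymmetry)
        amp_right = half_span * (1.0 - self.asymmetry)

        jump = np.zeros_like(t)
        for tj in self.jump_times:
            jump += self.jump_amplitude_mm * np.exp(-((t - tj) ** 2) / (2 * self.jump_sigma_s**2))

        # whole-body ML sway, shared by pelvis and feet: it cancels in the
        # ankle-ankle difference, so step width stays exactly as configured
        sway = 15.0 * np.sin(phase) * walking
        pelvis = np.column_stack(
            [
                8.0 * np.sin(2 * phase) * walking,  # trunk AP bob
                sway,
                1000.0 + 15.0 * np.cos(2 * phase) * walking + jump,
            ]
        )
        sternum = pelvis + np.array([20.0, 0.0, 450.0])

        half_width = self.step_width * MM / 2.0
        d = self.duty_factor
        dphi = np.pi - 2 * np.pi * d  # toe-off phase lead

        def foot(side: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            sgn = 1.0 if side == "left" else -1.0
            amp = amp_left if side == "left" else amp_right
            ph = phase if side == "left" else phase + np.pi
            # feet ride on the pelvis AP, so the sacrum-relative signal is
            # exactly amp·sin(ph) and the analytic event times are exact
            ap_ankle = pelvis[:, 0] + amp * np.sin(ph) * walking
            # raised-cosine lift during swing (cycle fraction u past this
            # side's heel strike; swing spans u in (duty, 1)).  The bump is
            # zero at every heel strike — the landing foot is at u = 1 and
            # the contralateral foot at u = 0.5 (stance) — so the configured
            # step length is preserved exactly.
            u = np.mod((ph - np.pi / 2) / (2 * np.pi), 1.0)
            swing = (u > d) & (walking > 0)
            lift = np.where(swing, np.sin(np.pi * (u - d) / (1.0 - d)) ** 2, 0.0) * 60.0
            ankle = np.column_stack(
                [ap_ankle, sgn * half_width + sway, 100.0 + lift]
            )
            heel = ankle + np.array([-50.0, 0.0, -70.0])
            toe_ap = pelvis[:, 0] + amp * np.sin(ph + dphi) * walking + 120.0
            toe = np.column_stack(
                [toe_ap, sgn * half_width + sway, 30.0 + lift]
            )
            return ankle, heel, toe

        al, hl, tl = foot("left")
        ar, hr, tr = foot("right")
        return {
            "pelvis": pelvis,
            "sternum": sternum,
            "ankle_left": al,
            "ankle_right": ar,
            "heel_left": hl,
            "heel_right": hr,
            "foot_left": tl,
            "foot_right": tr,
        }

    def true_event_times(self) -> dict[str, dict[str, np.ndarray]]:
        """Analytic heel-strike / toe-off times inside the walking bout."""
        t0, t1 = self.walking_window()
        T = self.stride_time
        d = self.duty_factor
        n = int(round((t1 - t0) / T))

        def series(offset_strides: float) -> np.ndarray:
            # offset reduced modulo one stride: the first extremum of a kind
            # may fall in a partial cycle at the start of the bout
            k = np.arange(n + 1)
            times = t0 + (k + np.mod(offset_strides, 1.0)) * T
            return times[(times > t0) & (times < t1)]

        return {
            "heel_strike": {"left": series(0.25), "right": series(0.75)},
            "toe_off": {"left": series(0.25 + d), "right": series(0.75 + d)},
        }


@dataclass
class ObservationModelConfig:
    """Rendering of the world through one camera.

    ``frame_transform`` maps world (reference) coordinates into the device
    frame.  ``temporal_lag`` delays the stream's content: the device
    records ``world(t - temporal_lag)`` at its own timestamp ``t``.
    Inter-frame intervals are truncated-normal with the configured mean
    (``1/nominal_rate``) and standard deviation.  Gaps drop a run of frames
    (geometric length) starting with per-frame probability
    ``gap_probability``.  ``systematic_joint_offsets`` (mm, device frame)
    emulate the constant bias between skin markers and in-body joint
    estimates.
    """

    system_id: str = "device"
    frame_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    nominal_rate: float = 30.0
    interframe_jitter_sd: float = 0.0  # ms
    gap_probability: float = 0.0
    gap_length_mean: float = 3.0  # frames, geometric
    position_noise_sd: float = 0.0  # mm
    systematic_joint_offsets: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    temporal_lag: float = 0.0  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        for name in ("interframe_jitter_sd", "position_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.gap_probability < 1:
            raise ValueError("gap_probability must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Ledger of every injected truth for recovery tests."""

    heel_strike_times: dict[str, np.ndarray]
    toe_off_times: dict[str, np.ndarray]
    step_length_m: np.ndarray
    step_width_m: np.ndarray
    step_time_s: np.ndarray
    stride_time_s: np.ndarray
    walking_window: tuple[float, float]
    device_transforms: dict[str, RigidTransform]
    device_lags: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "heel_strike_times": {k: v.tolist() for k, v in self.heel_strike_times.items()},
            "toe_off_times": {k: v.tolist() for k, v in self.toe_off_times.items()},
            "step_length_m": self.step_length_m.tolist(),
            "step_width_m": self.step_width_m.tolist(),
            "step_time_s": self.step_time_s.tolist(),
            "stride_time_s": self.stride_time_s.tolist(),
            "walking_window": list(self.walking_window),
            "device_transforms": {
                k: {"rotation": T.rotation.tolist(), "translation": T.translation.tolist()}
                for k, T in self.device_transforms.items()
            },
            "device_lags": self.device_lags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _ground_truth(world: GaitWorldConfig, observers: Sequence[ObservationModelConfig]) -> GroundTruth:
    ev = world.true_event_times()
    hs = ev["heel_strike"]
    # pooled heel strikes in temporal order, with sides
    pooled = sorted(
        [(t, "left") for t in hs["left"]] + [(t, "right") for t in hs["right"]]
    )
    times = np.array([t for t, _ in pooled])
    pos = world.world_positions(times)
    diff = pos["ankle_left"] - pos["ankle_right"]
    step_len = np.linalg.norm(diff, axis=1) / MM
    step_wid = np.abs(diff[:, 1]) / MM
    step_t = []
    for (tp, sp), (tc, sc) in zip(pooled[:-1], pooled[1:]):
        if sp != sc:
            step_t.append(tc - tp)
    stride_parts = [np.diff(hs[s]) for s in ("left", "right") if hs[s].size > 1]
    stride_t = np.concatenate(stride_parts) if stride_parts else np.array([])
    return GroundTruth(
        heel_strike_times=hs,
        toe_off_times=ev["toe_off"],
        step_length_m=step_len,
        step_width_m=step_wid,
        step_time_s=np.array(step_t),
        stride_time_s=stride_t,
        walking_window=world.walking_window(),
        device_transforms={o.system_id: o.frame_transform for o in observers},
        device_lags={o.system_id: o.temporal_lag for o in observers},
    )


def _jittered_clock(
    rng: np.random.Generator, rate: float, jitter_sd_ms: float, duration: float
) -> np.ndarray:
    mean_dt = 1.0 / rate
    n_max = int(np.ceil(duration / mean_dt)) + 10
    if jitter_sd_ms <= 0:
        # exact grid (no accumulated float error) so a degenerate observer
        # shares the reference clock bit for bit
        t = np.arange(n_max + 1) / rate
    else:
        sd = jitter_sd_ms / 1000.0
        lo = 1e-3  # intervals cannot be shorter than 1 ms
        a = (lo - mean_dt) / sd
        dts = truncnorm.rvs(a, np.inf, loc=mean_dt, scale=sd, size=n_max, random_state=rng)
        t = np.concatenate([[0.0], np.cumsum(dts)])
    return t[t <= duration]


def _render_observer(
    world: GaitWorldConfig, obs: ObservationModelConfig, rng: np.random.Generator
) -> SkeletonSequence:
    t = _jittered_clock(rng, obs.nominal_rate, obs.interframe_jitter_sd, world.trial_duration)
    pos_world = world.world_positions(t - obs.temporal_lag)
    joints = list(world.subject_joint_set)
    n = t.size
    P = np.empty((n, len(joints), 3))
    for j, name in enumerate(joints):
        p = obs.frame_transform.apply(pos_world[name])
        if name in obs.systematic_joint_offsets:
            p = p + np.asarray(obs.systematic_joint_offsets[name], dtype=float)
        P[:, j, :] = p
    if obs.position_noise_sd > 0:
        P = P + rng.normal(0.0, obs.position_noise_sd, size=P.shape)
    if obs.gap_probability > 0:
        keep = np.ones(n, dtype=bool)
        i = 0
        while i < n:
            if rng.random() < obs.gap_probability:
                glen = rng.geometric(1.0 / max(1.0, obs.gap_length_mean))
                keep[i : i + glen] = False
                i += glen
            i += 1
        t, P = t[keep], P[keep]
    return SkeletonSequence(
        system_id=obs.system_id,
        joint_names=joints,
        timestamps=t,
        positions=P,
        nominal_rate=obs.nominal_rate,
        frame_id=obs.system_id,
    )


def simulate_trial(
    world: GaitWorldConfig,
    observers: Sequence[ObservationModelConfig],
    seed: int,
    reference_rate: float = 100.0,
) -> tuple[SkeletonSequence, list[SkeletonSequence], GroundTruth]:
    """Simulate one trial: a clean reference stream, one stream per
    observer, and the injected ground truth.

    The reference stream samples the world on an exact uniform grid and
    uses optical-marker naming (LANK/RANK, LHEE/RHEE, LTOE/RTOE, STRN, and
    an RPSI/LPSI pair whose mean is the pelvis); device streams use the
    canonical joint names.  Per-observer random generators are spawned
    deterministically from the master seed (and the observer's own seed
    field, when set), so the same seed reproduces the trial bit for bit.
    """
    n_ref = int(np.floor(world.trial_duration * reference_rate)) + 1
    t_ref = np.arange(n_ref) / reference_rate
    pos = world.world_positions(t_ref)
    psi_half_width = 60.0  # mm, iliac markers flank the pelvis midline
    ref_markers = {
        "RPSI": pos["pelvis"] + np.array([0.0, -psi_half_width, 0.0]),
        "LPSI": pos["pelvis"] + np.array([0.0, psi_half_width, 0.0]),
    }
    for joint, marker in _REFERENCE_MARKER_OF.items():
        ref_markers[marker] = pos[joint]
    names = list(ref_markers)
    ref = SkeletonSequence(
        system_id="reference",
        joint_names=names,
        timestamps=t_ref,
        positions=np.stack([ref_markers[m] for m in names], axis=1),
        nominal_rate=reference_rate,
        frame_id="reference",
    )
    devices = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(observers))
    for obs, child in zip(observers, children):
        if obs.seed is not None:
            child = np.random.SeedSequence(obs.seed)
        devices.append(_render_observer(world, obs, np.random.default_rng(child)))
    return ref, devices, _ground_truth(world, observers)


def random_rigid_transform(rng: np.random.Generator, translation_scale: float = 1000.0) -> RigidTransform:
    """Uniformly random proper rotation plus a Gaussian translation (mm)."""
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0.0, translation_scale, size=3)
    return RigidTransform(R, t)


def simulate_checkerboard_scene(
    truth_transform: RigidTransform,
    board: GridSpec,
    n_placements: int,
    noise_sd_mm: float,
    seed: int,
    reference_noise_sd_mm: float | None = None,
) -> list[CheckerboardObservation]:
    """Simulated calibration scene with a known device→reference transform.

    Each placement poses the board with a random rigid pose in the
    reference frame; the interior grid intersections are reported in the
    device frame (through the inverse of ``truth_transform``) with
    ``noise_sd_mm`` isotropic noise, and the four corner markers in the
    reference frame with smaller noise (default one fifth of the device
    noise, the reference system being the more precise instrument).
    """
    if n_placements < 1:
        raise ValueError("n_placements must be >= 1")
    if reference_noise_sd_mm is None:
        reference_noise_sd_mm = 0.2 * noise_sd_mm
    rng = np.random.default_rng(seed)
    ref_to_device = truth_transform.inverse()
    grid = generate_grid(board).points
    out = []
    for _ in range(n_placements):
        pose = RigidTransform(
            Rotation.random(random_state=rng).as_matrix(),
            rng.uniform([-500.0, -500.0, 800.0], [500.0, 500.0, 2500.0]),
        )
        grid_ref = pose.apply(grid)
        corners_ref = pose.apply(board.corner_marker_offsets)
        device_pts = ref_to_device.apply(grid_ref)
        if noise_sd_mm > 0:
            device_pts = device_pts + rng.normal(0.0, noise_sd_mm, size=device_pts.shape)
        measured_corners = corners_ref
        if reference_noise_sd_mm > 0:
            measured_corners = corners_ref + rng.normal(
                0.0, reference_noise_sd_mm, size=corners_ref.shape
            )
        out.append(
            CheckerboardObservation(
                device_points=PointSet(device_pts, frame_id="device"),
                reference_corner_points=PointSet(measured_corners, frame_id="reference"),
                board=board,
            )
        )
    return out
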