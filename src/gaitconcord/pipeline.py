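"""End-to-end orchestration: simulate → calibrate → preprocess → sync →
events → parameters → compare, driven by one validated config.

Every stage writes its intermediate artifact (CSV/JSON) into the run
directory together with a manifest recording the package version, the
master seed and a hash of the resolved configuration, so a run is
reproducible bit for bit from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator
from scipy.signal import find_peaks

from gaitconcord import __version__
from gaitconcord.calibration import (
    GridSpec,
    RigidTransform,
    calibrate_device_to_reference,
    transform_sequence,
)
from gaitconcord.core import (
    AxisConvention,
    MarkerMapping,
    SkeletonSequence,
    apply_marker_mapping,
    write_sequence,
)
from gaitconcord.events import GaitEvent, GaitEventTable, detect_heel_strikes, detect_toe_offs, match_events, relative_ap_signal
from gaitconcord.parameters import compute_gait_parameters
from gaitconcord.preprocess import (
    butterworth_lowpass,
    fill_gaps_quadratic,
    resample_uniform,
    synchronize,
)
from gaitconcord.simulate import (
    TREADMILL_PRESETS,
    GaitWorldConfig,
    ObservationModelConfig,
    random_rigid_transform,
    simulate_checkerboard_scene,
    simulate_trial,
)
from gaitconcord.stats import build_agreement_report, zero_mean_shift

__all__ = ["PipelineConfig", "ObserverConfig", "run_pipeline", "segment_walking_window"]


class ObserverConfig(BaseModel):
    """Device observation model as configured (YAML-friendly)."""

    system_id: str = "device"
    nominal_rate: float = 30.0
    interframe_jitter_sd: float = 0.0
    gap_probability: float = 0.0
    gap_length_mean: float = 3.0
    position_noise_sd: float = 0.0
    temporal_lag: float = 0.0
    systematic_joint_offsets: dict[str, tuple[float, float, float]] = Field(default_factory=dict)
    random_frame: bool = True  # random world->device rigid transform
    frame_seed_offset: int = 0


class PipelineConfig(BaseModel):
    """One file drives the whole run."""

    out_dir: Path
    seed: int = 0
    preset: Literal["slow", "medium", "fast"] = "slow"
    world_overrides: dict = Field(default_factory=dict)
    observers: list[ObserverConfig] = Field(default_factory=lambda: [ObserverConfig()])
    working_rate: float = 100.0
    fill_max_gap_frames: int = 10
    lowpass: Literal["reference", "both", "none"] = "reference"
    lowpass_cutoff_hz: float = 5.0
    lowpass_order: int = 4
    board_w: int = 8
    board_h: int = 5
    board_square_mm: float = 50.0
    calibration_placements: int = 5
    calibration_noise_sd_mm: float = 0.5
    # must clear both the jump decay and the walk on/off transient (the
    # bout starts ~2 s after the last pre-trial jump)
    segment_margin_s: float = 3.0
    sync_ref_marker: str = "STRN"
    sync_dev_marker: str = "pelvis"
    step_length_mode: Literal["norm3d", "ap"] = "norm3d"
    reference_heel_joints: tuple[str, str] = ("heel_left", "heel_right")
    reference_toe_joints: tuple[str, str] = ("foot_left", "foot_right")
    device_heel_joints: tuple[str, str] = ("ankle_left", "ankle_right")
    device_toe_joints: tuple[str, str] = ("foot_left", "foot_right")

    @field_validator("working_rate")
    @classmethod
    def _positive_rate(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("working_rate must be positive")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def world(self) -> GaitWorldConfig:
        kw = dict(TREADMILL_PRESETS[self.preset])
        kw.update(self.world_overrides)
        return GaitWorldConfig(**kw)

    def resolved_hash(self) -> str:
        # out_dir is where results land, not what they are
        payload = json.dumps(self.model_dump(mode="json", exclude={"out_dir"}), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def segment_walking_window(
    seq: SkeletonSequence,
    marker: str,
    convention: AxisConvention | None = None,
    margin_s: float = 2.0,
    min_spike_mm: float = 120.0,
) -> tuple[float, float]:
    """Walking bout from the jump protocol: the span between the last
    pre-trial jump spike and the first post-trial spike, shrunk by a margin.

    Spikes are prominent peaks of the marker's vertical channel; the two
    jump bouts are split at the largest inter-spike gap.
    """
    convention = convention or AxisConvention()
    v = convention.component(seq.joint(marker), "v")
    v = np.nan_to_num(v, nan=float(np.nanmedian(v)))
    base = np.median(v)
    peaks, _ = find_peaks(v - base, height=min_spike_mm, prominence=min_spike_mm)
    if peaks.size < 2:
        raise ValueError("cannot segment: fewer than two jump spikes found")
    pt = seq.timestamps[peaks]
    split = int(np.argmax(np.diff(pt)))
    t0 = pt[split] + margin_s
    t1 = pt[split + 1] - margin_s
    if t1 <= t0:
        raise ValueError("cannot segment: margins leave no walking bout")
    return float(t0), float(t1)


def _detect_events(
    seq: SkeletonSequence,
    system_kind: str,
    heel_joints: tuple[str, str],
    toe_joints: tuple[str, str],
    window: tuple[float, float],
    working_rate: float,
    convention: AxisConvention | None = None,
    sacrum_joint: str = "pelvis",
) -> GaitEventTable:
    convention = convention or AxisConvention()
    seg = seq.slice_time(*window)
    sac = seg.joint(sacrum_joint)
    events: list[GaitEvent] = []
    for side, heel, toe in zip(("left", "right"), heel_joints, toe_joints):
        rel_heel = relative_ap_signal(seg.joint(heel), sac, convention)
        rel_toe = relative_ap_signal(seg.joint(toe), sac, convention)
        for t in detect_heel_strikes(rel_heel, seg.timestamps):
            events.append(GaitEvent("heel_strike", side, int(round(t * working_rate)), float(t)))
        for t in detect_toe_offs(rel_toe, seg.timestamps):
            events.append(GaitEvent("toe_off", side, int(round(t * working_rate)), float(t)))
    return GaitEventTable(events, working_rate)


@dataclass
class DeviceResult:
    system_id: str
    calibration: RigidTransform
    calibration_rms_mm: float
    sync_lag_s: float
    events: GaitEventTable
    event_match: dict
    parameters: dict
    agreement: dict


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    reference_events: GaitEventTable
    reference_parameters: dict
    devices: dict[str, DeviceResult]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow for one simulated trial."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conv = AxisConvention()
    world = config.world()
    rate = config.working_rate

    # --- stage 1: simulate world + device streams ------------------------
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0FFEE)))
    observers = []
    for i, oc in enumerate(config.observers):
        T = (
            random_rigid_transform(rng)
            if oc.random_frame
            else RigidTransform.identity()
        )
        observers.append(
            ObservationModelConfig(
                system_id=oc.system_id,
                frame_transform=T,
                nominal_rate=oc.nominal_rate,
                interframe_jitter_sd=oc.interframe_jitter_sd,
                gap_probability=oc.gap_probability,
                gap_length_mean=oc.gap_length_mean,
                position_noise_sd=oc.position_noise_sd,
                systematic_joint_offsets=oc.systematic_joint_offsets,
                temporal_lag=oc.temporal_lag,
            )
        )
    ref_raw, dev_raw, truth = simulate_trial(world, observers, seed=config.seed)
    write_sequence(ref_raw, out / "reference_raw.csv")
    truth.to_json(out / "ground_truth.json")

    # --- stage 2: per-device calibration ---------------------------------
    board = GridSpec(config.board_w, config.board_h, config.board_square_mm)
    mapping = MarkerMapping.default()

    # reference preprocessing is shared across devices
    ref100 = resample_uniform(ref_raw, rate)
    ref100, _ = fill_gaps_quadratic(ref100, config.fill_max_gap_frames)
    if config.lowpass in ("reference", "both"):
        ref100 = butterworth_lowpass(ref100, config.lowpass_order, config.lowpass_cutoff_hz)
    write_sequence(ref100, out / "reference_100hz.csv")
    window = segment_walking_window(
        ref100, config.sync_ref_marker, conv, config.segment_margin_s
    )
    ref_mapped = apply_marker_mapping(ref100, mapping)
    ref_events = _detect_events(
        ref_mapped,
        "reference",
        config.reference_heel_joints,
        config.reference_toe_joints,
        window,
        rate,
        conv,
    )
    ref_events.to_json(out / "reference_events.json")
    ref_params = compute_gait_parameters(
        ref_mapped, ref_events, convention=conv, step_length_mode=config.step_length_mode
    )

    devices: dict[str, DeviceResult] = {}
    for i, (obs, dev) in enumerate(zip(observers, dev_raw)):
        tag = obs.system_id
        write_sequence(dev, out / f"{tag}_raw.csv")
        scenes = simulate_checkerboard_scene(
            truth_transform=obs.frame_transform.inverse(),
            board=board,
            n_placements=config.calibration_placements,
            noise_sd_mm=config.calibration_noise_sd_mm,
            seed=int(np.random.SeedSequence((config.seed, 0xB0A2D, i)).generate_state(1)[0] % 2**31),
        )
        cal, cal_rms = calibrate_device_to_reference(scenes)
        cal.to_json(out / f"{tag}_calibration.json", rms_residual_mm=cal_rms)

        dev_ref_frame = transform_sequence(dev, cal, frame_id="reference")
        dev100 = resample_uniform(dev_ref_frame, rate)
        dev100, _ = fill_gaps_quadratic(dev100, config.fill_max_gap_frames)
        if config.lowpass == "both":
            dev100 = butterworth_lowpass(dev100, config.lowpass_order, config.lowpass_cutoff_hz)
        sync = synchronize(ref100, dev100, config.sync_ref_marker, config.sync_dev_marker, conv)
        aligned = dev100.copy()
        aligned.timestamps = aligned.timestamps - sync.lag_seconds
        # re-grid onto the reference timeline after the shift
        aligned = resample_uniform(aligned, rate)
        write_sequence(aligned, out / f"{tag}_aligned_100hz.csv")

        dev_events = _detect_events(
            aligned,
            "device",
            config.device_heel_joints,
            config.device_toe_joints,
            window,
            rate,
            conv,
        )
        dev_events.to_json(out / f"{tag}_events.json")
        ev_match = match_events(ref_events, dev_events).summary()
        dev_params = compute_gait_parameters(
            aligned, dev_events, convention=conv, step_length_mode=config.step_length_mode
        )

        # frame-level agreement on the common walking segment
        ref_seg = zero_mean_shift(ref_mapped.slice_time(*window))
        common = [j for j in ref_seg.joint_names if j in aligned.joint_names]
        dev_seg_full = aligned.select_joints(common).slice_time(*window)
        ref_seg = ref_seg.select_joints(common)
        # align frame grids (the shift re-grid keeps the same spacing)
        n = min(ref_seg.n_frames, dev_seg_full.n_frames)
        ref_seg = SkeletonSequence(
            ref_seg.system_id, common, np.round(ref_seg.timestamps[:n], 9),
            ref_seg.positions[:n], rate, ref_seg.frame_id,
        )
        dev_seg = SkeletonSequence(
            tag, common, np.round(ref_seg.timestamps, 9),
            dev_seg_full.positions[:n], rate, "reference",
        )
        dev_seg = zero_mean_shift(dev_seg)
        report = build_agreement_report(
            ref_seg,
            dev_seg,
            params_ref={
                "step_length_m": ref_params.step_length_m,
                "step_width_m": ref_params.step_width_m,
                "step_time_s": ref_params.step_time_s,
                "stride_time_s": ref_params.stride_time_s,
            },
            params_dev={
                "step_length_m": dev_params.step_length_m,
                "step_width_m": dev_params.step_width_m,
                "step_time_s": dev_params.step_time_s,
                "stride_time_s": dev_params.stride_time_s,
            },
            convention=conv,
            metadata={"device": tag, "working_rate": rate},
        )
        with open(out / f"{tag}_agreement.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2, default=float)
            fh.write("\n")
        devices[tag] = DeviceResult(
            system_id=tag,
            calibration=cal,
            calibration_rms_mm=cal_rms,
            sync_lag_s=sync.lag_seconds,
            events=dev_events,
            event_match=ev_match,
            parameters=dev_params.summary(),
            agreement=report.as_dict(),
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.resolved_hash(),
        "config": config.model_dump(mode="json"),
        "walking_window": list(window),
        "stages": {
            "reference_frames": int(ref100.n_frames),
            "reference_events": len(ref_events.events),
            "devices": {
                tag: {
                    "sync_lag_s": d.sync_lag_s,
                    "calibration_rms_mm": d.calibration_rms_mm,
                    "events": len(d.events.events),
                    "event_match": d.event_match,
                }
                for tag, d in devices.items()
            },
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        reference_events=ref_events,
        reference_parameters=ref_params.summary(),
        devices=devices,
    )
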