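"""Spatio-temporal gait parameters from event tables and ankle trajectories.

Parameters follow the standard treadmill definitions:

* step length — distance between the left and right ankle markers at each
  heel-strike event (full 3D norm by default; an AP-component-only variant
  is available, as conventions differ);
* step width — absolute medio-lateral separation of the ankles at each
  heel strike;
* step time — time between consecutive heel strikes of opposite feet;
* stride time — time between consecutive heel strikes of the same foot.

Lengths are returned in metres, times in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gaitconcord.core import AxisConvention, SkeletonSequence
from gaitconcord.events import GaitEventTable

__all__ = [
    "GaitParameterSet",
    "step_length",
    "step_width",
    "step_time",
    "stride_time",
    "compute_gait_parameters",
]

MM_PER_M = 1000.0


def _event_frames(
    heel_strikes: GaitEventTable, n_frames: int, frame_offset: int = 0
) -> np.ndarray:
    frames = np.concatenate(
        [heel_strikes.frames("heel_strike", "left"), heel_strikes.frames("heel_strike", "right")]
    )
    frames = np.sort(frames) - frame_offset
    if frames.size and (frames[0] < 0 or frames[-1] >= n_frames):
        raise IndexError(
            f"event frame outside series range [0, {n_frames}): {frames[[0, -1]]}"
        )
    return frames


def step_length(
    ankle_left: np.ndarray,
    ankle_right: np.ndarray,
    heel_strikes: GaitEventTable,
    mode: str = "norm3d",
    convention: AxisConvention | None = None,
    frame_offset: int = 0,
) -> np.ndarray:
    """Ankle-to-ankle distance at each heel strike, in metres.

    ``mode="norm3d"`` (default) uses the full Euclidean distance;
    ``mode="ap"`` uses the absolute anterio-posterior component only.
    ``frame_offset`` is the working-grid index of the series' first sample,
    for series that do not start at time zero.
    """
    al = np.asarray(ankle_left, float)
    ar = np.asarray(ankle_right, float)
    frames = _event_frames(heel_strikes, al.shape[0], frame_offset)
    diff = al[frames] - ar[frames]
    if mode == "norm3d":
        vals = np.linalg.norm(diff, axis=1)
    elif mode == "ap":
        convention = convention or AxisConvention()
        vals = np.abs(convention.component(diff, "ap"))
    else:
        raise ValueError(f"unknown step-length mode {mode!r}")
    return vals / MM_PER_M


def step_width(
    ankle_left: np.ndarray,
    ankle_right: np.ndarray,
    heel_strikes: GaitEventTable,
    convention: AxisConvention | None = None,
    frame_offset: int = 0,
) -> np.ndarray:
    """Absolute medio-lateral ankle separation at each heel strike (m)."""
    convention = convention or AxisConvention()
    al = np.asarray(ankle_left, float)
    ar = np.asarray(ankle_right, float)
    frames = _event_frames(heel_strikes, al.shape[0], frame_offset)
    ml = convention.component(al[frames] - ar[frames], "ml")
    return np.abs(ml) / MM_PER_M


def step_time(heel_strikes: GaitEventTable) -> np.ndarray:
    """Intervals between consecutive heel strikes of opposite feet (s).

    Consecutive same-side strikes (a missed contralateral event) are
    excluded with a warning rather than producing a spurious double-length
    step.
    """
    events = heel_strikes.heel_strikes_in_order()
    if len(events) < 2:
        return np.array([])
    out = []
    n_skipped = 0
    for prev, cur in zip(events[:-1], events[1:]):
        if prev.side == cur.side:
            n_skipped += 1
            continue
        out.append(cur.time - prev.time)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} same-side heel-strike interval(s) excluded from step time"
        )
    return np.array(out)


def stride_time(heel_strikes: GaitEventTable) -> np.ndarray:
    """Intervals between consecutive same-side heel strikes, pooled (s)."""
    out = []
    for side in ("left", "right"):
        t = heel_strikes.times("heel_strike", side)
        if t.size >= 2:
            out.append(np.diff(t))
    if not out:
        return np.array([])
    return np.concatenate(out)


def _summ(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan")}
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {"n": int(x.size), "mean": float(np.mean(x)), "sd": sd}


@dataclass
class GaitParameterSet:
    """Per-occurrence values plus mean ± sd for the four parameters."""

    step_length_m: np.ndarray
    step_width_m: np.ndarray
    step_time_s: np.ndarray
    stride_time_s: np.ndarray

    def summary(self) -> dict:
        return {
            "step_length_m": _summ(self.step_length_m),
            "step_width_m": _summ(self.step_width_m),
            "step_time_s": _summ(self.step_time_s),
            "stride_time_s": _summ(self.stride_time_s),
        }

    def means(self) -> dict[str, float]:
        return {k: v["mean"] for k, v in self.summary().items()}


def compute_gait_parameters(
    seq: SkeletonSequence,
    events: GaitEventTable,
    ankle_left: str = "ankle_left",
    ankle_right: str = "ankle_right",
    convention: AxisConvention | None = None,
    step_length_mode: str = "norm3d",
) -> GaitParameterSet:
    """All four spatio-temporal parameters for one synchronized sequence."""
    al = seq.joint(ankle_left)
    ar = seq.joint(ankle_right)
    offset = int(round(seq.timestamps[0] * events.working_rate)) if seq.n_frames else 0
    return GaitParameterSet(
        step_length_m=step_length(
            al, ar, events, mode=step_length_mode, convention=convention, frame_offset=offset
        ),
        step_width_m=step_width(al, ar, events, convention=convention, frame_offset=offset),
        step_time_s=step_time(events),
        stride_time_s=stride_time(events),
    )
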