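"""Kinematic gait-event detection and cross-system event comparison.

On a treadmill the anterio-posterior (AP) position of a foot marker
relative to the sacrum traces a near-sinusoidal curve: the belt pulls the
stance foot backwards after every contact.  Heel strikes are therefore the
maxima of the sacrum-relative AP heel signal and toe offs the minima of
the sacrum-relative AP toe signal.  The peak-detection threshold is the
signal's mean value, with a minimum inter-peak separation estimated from
the signal's dominant period to suppress near-duplicate peaks on noisy
device data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _signal

from gaitconcord.core import AxisConvention, SkeletonSequence

__all__ = [
    "GaitEvent",
    "GaitEventTable",
    "EventMatchReport",
    "relative_ap_signal",
    "detect_heel_strikes",
    "detect_toe_offs",
    "virtual_sacrum_channel",
    "match_events",
]

EventType = Literal["heel_strike", "toe_off"]
Side = Literal["left", "right"]


@dataclass(frozen=True)
class GaitEvent:
    type: EventType
    side: Side
    frame_index: int
    time: float


@dataclass
class GaitEventTable:
    """Typed, sided, time-stamped gait events at a common working rate."""

    events: list[GaitEvent]
    working_rate: float

    def __post_init__(self) -> None:
        for etype in ("heel_strike", "toe_off"):
            for side in ("left", "right"):
                ts = self.times(etype, side)
                if ts.size > 1 and not np.all(np.diff(ts) > 0):
                    raise ValueError(f"{etype}/{side} event times not strictly increasing")

    def times(self, etype: str, side: str | None = None) -> np.ndarray:
        return np.array(
            sorted(
                e.time
                for e in self.events
                if e.type == etype and (side is None or e.side == side)
            )
        )

    def frames(self, etype: str, side: str | None = None) -> np.ndarray:
        sel = sorted(
            (e.time, e.frame_index)
            for e in self.events
            if e.type == etype and (side is None or e.side == side)
        )
        return np.array([f for _, f in sel], dtype=int)

    def heel_strikes_in_order(self) -> list[GaitEvent]:
        return sorted(
            (e for e in self.events if e.type == "heel_strike"), key=lambda e: e.time
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "working_rate": self.working_rate,
            "events": [
                {"type": e.type, "side": e.side, "frame": e.frame_index, "time": e.time}
                for e in sorted(self.events, key=lambda e: e.time)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GaitEventTable":
        with open(path) as fh:
            d = json.load(fh)
        evs = [
            GaitEvent(e["type"], e["side"], int(e["frame"]), float(e["time"]))
            for e in d["events"]
        ]
        return cls(evs, float(d["working_rate"]))

    @classmethod
    def from_times(
        cls,
        working_rate: float,
        heel_strikes: dict[str, Sequence[float]] | None = None,
        toe_offs: dict[str, Sequence[float]] | None = None,
    ) -> "GaitEventTable":
        evs: list[GaitEvent] = []
        for etype, table in (("heel_strike", heel_strikes), ("toe_off", toe_offs)):
            for side, times in (table or {}).items():
                for t in times:
                    evs.append(GaitEvent(etype, side, int(round(t * working_rate)), float(t)))
        return cls(evs, working_rate)


def relative_ap_signal(
    marker_channel: np.ndarray,
    sacrum_channel: np.ndarray,
    convention: AxisConvention | None = None,
) -> np.ndarray:
    """Sacrum-relative AP component of a marker trajectory.

    Both inputs are (n, 3) position series sharing timestamps.
    """
    convention = convention or AxisConvention()
    m = np.asarray(marker_channel, dtype=float)
    s = np.asarray(sacrum_channel, dtype=float)
    if m.shape != s.shape:
        raise ValueError(f"channel length mismatch: {m.shape} vs {s.shape}")
    return convention.component(m, "ap") - convention.component(s, "ap")


def _estimate_min_separation(x: np.ndarray, default: int) -> int:
    """Half the dominant period, from the autocorrelation's first side peak."""
    x = x - x.mean()
    if x.size < 8 or np.allclose(x, 0):
        return default
    ac = _signal.correlate(x, x, mode="full")[x.size - 1 :]
    peaks, _ = _signal.find_peaks(ac)
    if peaks.size == 0:
        return default
    period = int(peaks[0])
    return max(default, period // 2)


def _detect_extrema(
    x: np.ndarray,
    times: np.ndarray,
    kind: str,
    min_separation: int | None,
    min_prominence_frac: float = 0.05,
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        idx = np.arange(x.size)
        ok = ~np.isnan(x)
        if ok.sum() < 3:
            warnings.warn("channel almost entirely missing; no events detected")
            return np.array([])
        x = np.interp(idx, idx[ok], x[ok])
    if np.ptp(x) == 0:
        warnings.warn("constant signal: no gait events detectable")
        return np.array([])
    sig = x if kind == "max" else -x
    thresh = sig.mean()
    if min_separation is None:
        min_separation = _estimate_min_separation(sig, default=1)
    # strict threshold at the mean; an interior sample with neighbours on
    # both sides is required (find_peaks never returns endpoints).  The
    # prominence floor (a small fraction of the channel's range) rejects
    # millimetre-scale ripples in rest segments next to the walking bout.
    peaks, _ = _signal.find_peaks(
        sig,
        height=np.nextafter(thresh, np.inf),
        distance=max(1, min_separation),
        prominence=min_prominence_frac * np.ptp(sig),
    )
    return times[peaks]


def detect_heel_strikes(
    rel_heel: np.ndarray,
    times: np.ndarray,
    min_separation: int | None = None,
    min_prominence_frac: float = 0.05,
) -> np.ndarray:
    """Times of heel strikes: local maxima of the sacrum-relative AP heel
    signal exceeding its mean value."""
    return _detect_extrema(
        rel_heel, np.asarray(times, float), "max", min_separation, min_prominence_frac
    )


def detect_toe_offs(
    rel_toe: np.ndarray,
    times: np.ndarray,
    min_separation: int | None = None,
    min_prominence_frac: float = 0.05,
) -> np.ndarray:
    """Times of toe offs: local minima of the sacrum-relative AP toe signal
    below its mean value."""
    return _detect_extrema(
        rel_toe, np.asarray(times, float), "min", min_separation, min_prominence_frac
    )


def virtual_sacrum_channel(
    seq: SkeletonSequence,
    system_kind: str = "reference",
    pelvis_joint: str = "pelvis",
    psi_markers: tuple[str, str] = ("RPSI", "LPSI"),
) -> np.ndarray:
    """(n, 3) sacrum series: mean of the two posterior superior iliac
    markers for reference systems, the pelvis joint passthrough for devices."""
    if system_kind == "reference":
        missing = [m for m in psi_markers if m not in seq.joint_names]
        if missing:
            raise KeyError(f"missing required markers: {missing}")
        stack = np.stack([seq.joint(m) for m in psi_markers])
        return stack.mean(axis=0)
    if system_kind == "device":
        return seq.joint(pelvis_joint)
    raise ValueError(f"unknown system kind {system_kind!r}")


@dataclass
class EventMatchReport:
    """Frame-level comparison of device events against reference events."""

    pairs: list[tuple[GaitEvent, GaitEvent, int]]  # (ref, dev, dev_frame - ref_frame)
    unmatched_reference: int
    unmatched_device: int
    working_rate: float

    @property
    def frame_differences(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], dtype=float)

    def summary(self) -> dict:
        d = self.frame_differences
        if d.size == 0:
            return {
                "n_matched": 0,
                "mean_frames": float("nan"),
                "sd_frames": float("nan"),
                "mean_ms": float("nan"),
                "sd_ms": float("nan"),
                "unmatched_reference": self.unmatched_reference,
                "unmatched_device": self.unmatched_device,
            }
        ms = 1000.0 / self.working_rate
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        return {
            "n_matched": int(d.size),
            "mean_frames": float(d.mean()),
            "sd_frames": sd,
            "mean_ms": float(d.mean() * ms),
            "sd_ms": sd * ms,
            "unmatched_reference": self.unmatched_reference,
            "unmatched_device": self.unmatched_device,
        }


def match_events(
    ref: GaitEventTable, dev: GaitEventTable, window_frames: int | None = None
) -> EventMatchReport:
    """Greedy nearest-neighbour matching per (type, side).

    ``frame_difference = dev_frame - ref_frame``; negative values mean the
    device detected the event earlier.  The default window is half the
    median reference stride estimated from heel-strike spacing, which
    prevents cross-cycle matches.
    """
    if not np.isclose(ref.working_rate, dev.working_rate):
        raise ValueError("event tables must share a working rate")
    if window_frames is None:
        spacings = []
        for side in ("left", "right"):
            t = ref.times("heel_strike", side)
            if t.size > 1:
                spacings.extend(np.diff(t))
        window_frames = (
            int(round(0.5 * float(np.median(spacings)) * ref.working_rate))
            if spacings
            else int(ref.working_rate)  # 1 s fallback
        )
    pairs: list[tuple[GaitEvent, GaitEvent, int]] = []
    n_unmatched_ref = 0
    n_unmatched_dev = 0
    for etype in ("heel_strike", "toe_off"):
        for side in ("left", "right"):
            revs = sorted(
                (e for e in ref.events if e.type == etype and e.side == side),
                key=lambda e: e.time,
            )
            devs = sorted(
                (e for e in dev.events if e.type == etype and e.side == side),
                key=lambda e: e.time,
            )
            cands = [
                (abs(de.frame_index - re.frame_index), i, j)
                for i, re in enumerate(revs)
                for j, de in enumerate(devs)
                if abs(de.frame_index - re.frame_index) <= window_frames
            ]
            cands.sort()
            used_r: set[int] = set()
            used_d: set[int] = set()
            for _, i, j in cands:
                if i in used_r or j in used_d:
                    continue
                used_r.add(i)
                used_d.add(j)
                pairs.append((revs[i], devs[j], devs[j].frame_index - revs[i].frame_index))
            n_unmatched_ref += len(revs) - len(used_r)
            n_unmatched_dev += len(devs) - len(used_d)
    pairs.sort(key=lambda p: p[0].time)
    return EventMatchReport(pairs, n_unmatched_ref, n_unmatched_dev, ref.working_rate)
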