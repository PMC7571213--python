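"""Canonical data model for multi-system 3D kinematic time series.

All positions are in millimetres.  A :class:`SkeletonSequence` stores one
camera system's view of a set of named joints over time; missing samples
are explicit NaN triplets so that gap filling can operate on a known grid.
The canonical interchange format is a wide CSV (``time`` plus
``<joint>_x/_y/_z`` columns); the TRC motion-capture text format is
supported read-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AxisConvention",
    "MarkerMapping",
    "SkeletonSequence",
    "SkeletonParseError",
    "apply_marker_mapping",
    "read_sequence",
    "write_sequence",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class SkeletonParseError(ValueError):
    """Raised when a trajectory file violates the format contract."""


def _parse_signed_axis(spec: str) -> tuple[int, float]:
    """``"+x" / "-z" / "x"`` -> (column index, sign)."""
    s = spec.strip().lower().replace("−", "-")
    sign = 1.0
    if s[0] in "+-":
        sign = -1.0 if s[0] == "-" else 1.0
        s = s[1:]
    if s not in _AXIS_INDEX:
        raise ValueError(f"invalid axis spec {spec!r}")
    return _AXIS_INDEX[s], sign


@dataclass(frozen=True)
class AxisConvention:
    """Assignment of gait axes (AP / ML / V) to signed coordinate axes.

    The canonical convention is x = anterio-posterior (direction of
    progression), y = medio-lateral, z = vertical (up); device frames may
    flip or permute axes, hence per-system overrides.
    """

    ap_axis: str = "+x"
    ml_axis: str = "+y"
    v_axis: str = "+z"

    def __post_init__(self) -> None:
        cols = [_parse_signed_axis(a)[0] for a in (self.ap_axis, self.ml_axis, self.v_axis)]
        if len(set(cols)) != 3:
            raise ValueError(
                f"axis convention must name three distinct axes, got "
                f"({self.ap_axis}, {self.ml_axis}, {self.v_axis})"
            )

    def component(self, positions: np.ndarray, which: str) -> np.ndarray:
        """Extract a signed gait-axis component from (..., 3) positions.

        ``which`` is one of ``"ap"``, ``"ml"``, ``"v"``.
        """
        spec = {"ap": self.ap_axis, "ml": self.ml_axis, "v": self.v_axis}[which]
        idx, sign = _parse_signed_axis(spec)
        return sign * np.asarray(positions)[..., idx]


@dataclass
class SkeletonSequence:
    """Time-stamped 3D joint positions for one camera system.

    Parameters
    ----------
    system_id:
        Label of the recording system (e.g. ``"reference"``, ``"device_a"``).
    joint_names:
        Ordered joint labels; column order of ``positions``.
    timestamps:
        Strictly increasing times in seconds, shape ``(n,)``.
    positions:
        Array of shape ``(n, n_joints, 3)`` in millimetres; missing samples
        are NaN triplets.
    nominal_rate:
        Nominal sampling rate in Hz, or ``None`` for an irregular stream.
    frame_id:
        Label of the coordinate frame the positions live in.
    """

    system_id: str
    joint_names: list[str]
    timestamps: np.ndarray
    positions: np.ndarray
    nominal_rate: float | None = None
    frame_id: str = "unknown"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.joint_names = list(self.joint_names)
        n, j = self.timestamps.shape[0], len(self.joint_names)
        if self.positions.shape != (n, j, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"({n} frames, {j} joints, 3)"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("non-monotone timestamps")
        if len(set(self.joint_names)) != j:
            raise ValueError("duplicate joint names")

    # -- accessors ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} not in sequence ({self.joint_names})") from None

    def joint(self, name: str) -> np.ndarray:
        """(n, 3) trajectory of one joint."""
        return self.positions[:, self.joint_index(name), :]

    def missing_mask(self) -> np.ndarray:
        """(n, n_joints) boolean mask: True where the sample is missing."""
        return np.isnan(self.positions).any(axis=2)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.n_frames < 2:
            return True
        dt = np.diff(self.timestamps)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-12))

    def median_dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        return float(np.median(np.diff(self.timestamps)))

    def copy(self, **changes) -> "SkeletonSequence":
        out = replace(
            self,
            timestamps=self.timestamps.copy(),
            positions=self.positions.copy(),
            joint_names=list(self.joint_names),
        )
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def select_joints(self, names: Sequence[str]) -> "SkeletonSequence":
        idx = [self.joint_index(n) for n in names]
        return SkeletonSequence(
            system_id=self.system_id,
            joint_names=list(names),
            timestamps=self.timestamps.copy(),
            positions=self.positions[:, idx, :].copy(),
            nominal_rate=self.nominal_rate,
            frame_id=self.frame_id,
        )

    def slice_time(self, t_start: float, t_end: float) -> "SkeletonSequence":
        """Frames with t_start <= t <= t_end (inclusive)."""
        keep = (self.timestamps >= t_start) & (self.timestamps <= t_end)
        return SkeletonSequence(
            system_id=self.system_id,
            joint_names=list(self.joint_names),
            timestamps=self.timestamps[keep],
            positions=self.positions[keep],
            nominal_rate=self.nominal_rate,
            frame_id=self.frame_id,
        )


@dataclass(frozen=True)
class MarkerMapping:
    """Map reference markers onto device joint labels.

    Each entry assigns one target joint the per-frame arithmetic mean of one
    or more source markers (e.g. a virtual sacrum from the two posterior
    superior iliac markers).
    """

    entries: tuple[tuple[str, tuple[str, ...]], ...]

    def __init__(self, entries: Iterable[tuple[str, Sequence[str]]] | dict):
        if isinstance(entries, dict):
            items = [(t, tuple(s)) for t, s in entries.items()]
        else:
            items = [(t, tuple(s)) for t, s in entries]
        targets = [t for t, _ in items]
        if len(set(targets)) != len(targets):
            raise ValueError("each target joint may appear at most once")
        for t, srcs in items:
            if len(srcs) < 1:
                raise ValueError(f"target {t!r} has no source markers")
        object.__setattr__(self, "entries", tuple(items))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerMapping":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({t: list(s) for t, s in self.entries}, fh, indent=2)
            fh.write("\n")

    @classmethod
    def default(cls) -> "MarkerMapping":
        """Shipped default reference-marker -> device-joint mapping.

        This is a reconstruction for the synthetic marker set used here (the
        full correspondence table of the original device skeletons is study
        configuration, not code): ankles from the ANK markers, feet from the
        TOE markers, pelvis from the mean of RPSI and LPSI, sternum from STRN.
        """
        res = Path(__file__).parent / "resources" / "default_marker_mapping.json"
        return cls.from_json(res)


def apply_marker_mapping(seq: SkeletonSequence, mapping: MarkerMapping) -> SkeletonSequence:
    """Build target joints as per-frame arithmetic means of source markers.

    Frames where any source marker is missing yield a missing target sample.
    """
    missing = sorted(
        {m for _, srcs in mapping.entries for m in srcs if m not in seq.joint_names}
    )
    if missing:
        raise KeyError(f"unknown source markers: {missing}")
    targets = [t for t, _ in mapping.entries]
    n = seq.n_frames
    out = np.full((n, len(targets), 3), np.nan)
    for k, (_, srcs) in enumerate(mapping.entries):
        idx = [seq.joint_index(m) for m in srcs]
        block = seq.positions[:, idx, :]  # (n, n_src, 3)
        any_missing = np.isnan(block).any(axis=(1, 2))
        vals = block.mean(axis=1)
        vals[any_missing] = np.nan
        out[:, k, :] = vals
    return SkeletonSequence(
        system_id=seq.system_id,
        joint_names=targets,
        timestamps=seq.timestamps.copy(),
        positions=out,
        nominal_rate=seq.nominal_rate,
        frame_id=seq.frame_id,
    )


# -- file I/O --------------------------------------------------------------

def _sequence_to_frame(seq: SkeletonSequence) -> pd.DataFrame:
    data = {"time": seq.timestamps}
    for j, name in enumerate(seq.joint_names):
        for a, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = seq.positions[:, j, a]
    return pd.DataFrame(data)


def write_sequence(seq: SkeletonSequence, path: str | Path, dialect: str = "wide_csv") -> None:
    """Write a sequence to disk; only the wide-CSV dialect is writable."""
    if dialect != "wide_csv":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    df = _sequence_to_frame(seq)
    # repr-based float formatting keeps the round trip at full precision and
    # the output byte-stable across writes
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def _read_wide_csv(path: Path) -> SkeletonSequence:
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.columns[0] != "time":
        raise SkeletonParseError(f"{path}: first column must be 'time', got {list(df.columns[:1])}")
    cols = list(df.columns[1:])
    joints: list[str] = []
    for c in cols:
        if "_" not in c or c.rsplit("_", 1)[1] not in ("x", "y", "z"):
            raise SkeletonParseError(f"{path}: column {c!r} is not of the form <joint>_x/_y/_z")
        base = c.rsplit("_", 1)[0]
        if base not in joints:
            joints.append(base)
    for j in joints:
        expected = [f"{j}_{ax}" for ax in "xyz"]
        if not all(e in cols for e in expected):
            raise SkeletonParseError(f"{path}: incomplete column triplet for joint {j!r}")
    t = df["time"].to_numpy(dtype=float)
    if np.isnan(t).any():
        row = int(np.flatnonzero(np.isnan(t))[0])
        raise SkeletonParseError(f"{path}: missing timestamp at row {row}")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SkeletonParseError(f"{path}: non-monotone timestamps at row {row}")
    pos = np.full((t.size, len(joints), 3), np.nan)
    for k, j in enumerate(joints):
        for a, ax in enumerate("xyz"):
            pos[:, k, a] = df[f"{j}_{ax}"].to_numpy(dtype=float)
    return SkeletonSequence(
        system_id=path.stem,
        joint_names=joints,
        timestamps=t,
        positions=pos,
    )


def _read_trc(path: Path) -> SkeletonSequence:
    """Read the TRC motion-capture text format (tab separated).

    Only the subset of the header needed to recover marker names, units and
    the data rate is interpreted.  Positions are converted to mm.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise SkeletonParseError(f"{path}: truncated TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    units = meta.get("Units", "mm").strip()
    scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if scale is None:
        raise SkeletonParseError(f"{path}: unsupported units {units!r}")
    try:
        rate = float(meta.get("DataRate", "nan"))
    except ValueError:
        rate = float("nan")
    header = lines[3].split("\t")
    markers = [h.strip() for h in header[2:] if h.strip()]
    rows = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        rows.append(ln.split("\t"))
    t = np.array([float(r[1]) for r in rows])
    if t.size > 1 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SkeletonParseError(f"{path}: non-monotone timestamps at row {row}")
    pos = np.full((t.size, len(markers), 3), np.nan)
    for i, r in enumerate(rows):
        vals = r[2 : 2 + 3 * len(markers)]
        for k in range(len(markers)):
            triple = vals[3 * k : 3 * k + 3]
            if len(triple) < 3 or any(v.strip() == "" for v in triple):
                continue
            pos[i, k, :] = [float(v) * scale for v in triple]
    return SkeletonSequence(
        system_id=path.stem,
        joint_names=markers,
        timestamps=t,
        positions=pos,
        nominal_rate=None if np.isnan(rate) else rate,
    )


def read_sequence(path: str | Path, dialect: str = "wide_csv") -> SkeletonSequence:
    """Read a trajectory file into a validated :class:`SkeletonSequence`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide_csv":
        return _read_wide_csv(path)
    if dialect == "trc":
        return _read_trc(path)
    raise ValueError(f"unknown dialect {dialect!r}")
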