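"""Resampling, gap filling, low-pass filtering and temporal synchronization.

The device cameras sample at a nominally constant but jittery ~30 Hz with
occasional dropout gaps, while the reference system runs at a clean 100 Hz.
All streams are brought onto a common uniform grid (default 100 Hz), short
gaps are filled with a local quadratic, the reference data are smoothed
with a zero-phase 4th-order Butterworth low-pass (5 Hz cut-off), and the
streams are aligned in time by cross-correlating the second derivative of
a central marker's vertical channel over the jump protocol (three jumps
before and after each walking bout give the correlation sharp peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from gaitconcord.core import AxisConvention, SkeletonSequence

__all__ = [
    "SyncResult",
    "resample_uniform",
    "fill_gaps_quadratic",
    "butterworth_lowpass",
    "second_derivative",
    "synchronize",
]


@dataclass(frozen=True)
class SyncResult:
    """Estimated lag of a device stream relative to the reference.

    ``lag_samples`` is an integer at ``working_rate``; positive means the
    device stream's content is delayed relative to the reference (the same
    event carries a later timestamp in the device stream), so advancing the
    device timeline by ``lag_seconds`` aligns the two.
    """

    lag_samples: int
    working_rate: float
    peak_correlation: float

    @property
    def lag_seconds(self) -> float:
        return self.lag_samples / self.working_rate


def resample_uniform(
    seq: SkeletonSequence,
    target_rate: float,
    max_gap_seconds: float | None = None,
    method: str = "linear",
) -> SkeletonSequence:
    """Resample onto a uniform grid at ``target_rate`` Hz.

    Values are interpolated (piecewise linear by default, ``method="cubic"``
    optional) per joint axis from the non-missing samples.  Grid points that
    fall inside a source gap longer than ``max_gap_seconds`` stay missing so
    that :func:`fill_gaps_quadratic` can treat them explicitly; the default
    threshold is 1.5 source sampling periods (from ``nominal_rate`` when
    known, else the median interval).
    """
    if seq.n_frames < 2:
        raise ValueError("need at least two frames to resample")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t = seq.timestamps
    if max_gap_seconds is None:
        period = 1.0 / seq.nominal_rate if seq.nominal_rate else seq.median_dt()
        max_gap_seconds = 1.5 * period
    dt = 1.0 / target_rate
    n_out = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + dt * np.arange(n_out)
    n_j = len(seq.joint_names)
    out = np.full((n_out, n_j, 3), np.nan)
    for j in range(n_j):
        ok = ~np.isnan(seq.positions[:, j, :]).any(axis=1)
        if ok.sum() < 2:
            continue
        tj = t[ok]
        for a in range(3):
            vals = seq.positions[ok, j, a]
            if method == "linear":
                out[:, j, a] = np.interp(grid, tj, vals)
            elif method == "cubic":
                from scipy.interpolate import CubicSpline

                cs = CubicSpline(tj, vals)
                out[:, j, a] = cs(np.clip(grid, tj[0], tj[-1]))
            else:
                raise ValueError(f"unknown interpolation method {method!r}")
        # mask grid points outside the observed span or inside long gaps
        outside = (grid < tj[0]) | (grid > tj[-1])
        out[outside, j, :] = np.nan
        gaps = np.diff(tj)
        for g in np.flatnonzero(gaps > max_gap_seconds):
            inside = (grid > tj[g]) & (grid < tj[g + 1])
            out[inside, j, :] = np.nan
    return SkeletonSequence(
        system_id=seq.system_id,
        joint_names=list(seq.joint_names),
        timestamps=grid,
        positions=out,
        nominal_rate=target_rate,
        frame_id=seq.frame_id,
    )


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    runs = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps_quadratic(
    seq: SkeletonSequence,
    max_gap_frames: int = 10,
    support: int = 3,
) -> tuple[SkeletonSequence, list[tuple[str, int, int]]]:
    """Fill interior missing runs of length <= ``max_gap_frames``.

    Each short run is replaced by a quadratic fitted to up to ``support``
    non-missing frames on either flank.  Runs at the sequence edges and runs
    longer than the threshold are left missing and reported as
    ``(joint, start_index, stop_index)``; no extrapolation is performed.
    """
    if not seq.is_uniform():
        raise ValueError("fill_gaps_quadratic requires uniform timestamps")
    out = seq.copy()
    unfilled: list[tuple[str, int, int]] = []
    t = seq.timestamps
    for j, name in enumerate(seq.joint_names):
        miss = np.isnan(out.positions[:, j, :]).any(axis=1)
        for start, stop in _missing_runs(miss):
            interior = start > 0 and stop < seq.n_frames
            if not interior or (stop - start) > max_gap_frames:
                unfilled.append((name, start, stop))
                continue
            left = np.arange(max(0, start - support), start)
            right = np.arange(stop, min(seq.n_frames, stop + support))
            sup = np.concatenate([left, right])
            sup = sup[~miss[sup]]
            if sup.size < 3:
                unfilled.append((name, start, stop))
                continue
            ts = t[sup] - t[start]  # local origin for conditioning
            hole = t[start:stop] - t[start]
            for a in range(3):
                coef = np.polyfit(ts, out.positions[sup, j, a], 2)
                out.positions[start:stop, j, a] = np.polyval(coef, hole)
    return out, unfilled


def butterworth_lowpass(
    seq: SkeletonSequence, order: int = 4, cutoff_hz: float = 5.0
) -> SkeletonSequence:
    """Zero-phase Butterworth low-pass on every joint-axis channel.

    The filter is applied forward and backward (zero net phase); channels
    must be uniformly sampled and gap-free.
    """
    if not seq.is_uniform():
        raise ValueError("butterworth_lowpass requires uniform timestamps")
    fs = 1.0 / seq.median_dt()
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs:.1f} Hz must exceed twice the cut-off {cutoff_hz} Hz")
    if np.isnan(seq.positions).any():
        raise ValueError("butterworth_lowpass requires gap-free data; fill gaps first")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    out = seq.copy()
    flat = out.positions.reshape(seq.n_frames, -1)
    out.positions = signal.sosfiltfilt(sos, flat, axis=0).reshape(out.positions.shape)
    return out


def second_derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """Second finite difference of a uniform scalar series (1/dt² scaled).

    Central differences in the interior, one-sided second differences at the
    endpoints; exact for quadratics.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d2 = np.empty_like(x)
    d2[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    d2[0] = (x[2] - 2 * x[1] + x[0]) / dt**2
    d2[-1] = (x[-1] - 2 * x[-2] + x[-3]) / dt**2
    return d2


def synchronize(
    ref: SkeletonSequence,
    dev: SkeletonSequence,
    ref_marker: str,
    dev_marker: str,
    convention: AxisConvention | None = None,
    max_lag_seconds: float = 10.0,
    prefilter_cutoff_hz: float | None = 10.0,
) -> SyncResult:
    """Estimate the device-vs-reference lag from the jump protocol.

    Both sequences must already be on the same uniform working rate.  The
    vertical channel of a central marker (sternum for the reference, pelvis
    for devices) is twice differentiated and the integer-sample lag with the
    maximum cross-correlation inside ``±max_lag_seconds`` is returned.
    Positive lag means the device content is delayed relative to the
    reference.

    Differentiating twice amplifies sensor noise quadratically with the
    working rate, so both channels are smoothed with a zero-phase
    Butterworth low-pass (default 10 Hz, well above the jump spikes'
    bandwidth) before differentiation; zero-phase filtering adds no lag
    bias.  Set ``prefilter_cutoff_hz=None`` to disable.
    """
    convention = convention or AxisConvention()
    for s, label in ((ref, "reference"), (dev, "device")):
        if not s.is_uniform():
            raise ValueError(f"{label} sequence must be uniformly sampled")
    dt_r, dt_d = ref.median_dt(), dev.median_dt()
    if not np.isclose(dt_r, dt_d, rtol=1e-6):
        raise ValueError("sequences must share the same working rate")
    rate = 1.0 / dt_r

    def channel(seq: SkeletonSequence, marker: str) -> np.ndarray:
        v = convention.component(seq.joint(marker), "v")
        v = np.asarray(v, dtype=float)
        # interpolate across any residual missing samples; sync must not
        # choke on a stray gap
        bad = np.isnan(v)
        if bad.all():
            raise ValueError(f"channel {marker!r} is entirely missing")
        if bad.any():
            idx = np.arange(v.size)
            v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
        return v

    a = channel(ref, ref_marker)
    b = channel(dev, dev_marker)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("no synchronizable structure: flat vertical channel")
    if prefilter_cutoff_hz is not None and rate > 2 * prefilter_cutoff_hz:
        sos = signal.butter(4, prefilter_cutoff_hz, btype="low", fs=rate, output="sos")
        a = signal.sosfiltfilt(sos, a)
        b = signal.sosfiltfilt(sos, b)
    d2a = second_derivative(a, dt_r)
    d2b = second_derivative(b, dt_r)
    d2a = d2a - d2a.mean()
    d2b = d2b - d2b.mean()
    corr = signal.correlate(d2b, d2a, mode="full")
    lags = signal.correlation_lags(d2b.size, d2a.size, mode="full")
    max_lag = int(round(max_lag_seconds * rate))
    window = (lags >= -max_lag) & (lags <= max_lag)
    if not window.any():
        raise ValueError("search window contains no admissible lag")
    corr_w = corr[window]
    lags_w = lags[window]
    k = int(lags_w[np.argmax(corr_w)])
    denom = np.sqrt(np.sum(d2a**2) * np.sum(d2b**2))
    peak = float(corr_w.max() / denom) if denom > 0 else float("nan")
    return SyncResult(lag_samples=k, working_rate=rate, peak_correlation=peak)


def apply_lag(dev: SkeletonSequence, lag_seconds: float) -> SkeletonSequence:
    """Shift a device stream's timestamps by ``-lag_seconds`` to align it
    with the reference timeline (inverse of the estimated content delay)."""
    out = dev.copy()
    out.timestamps = out.timestamps - lag_seconds
    return out
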