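"""Method-agreement statistics between a device and the reference system.

Device skeletons estimate joint centres inside the body while reference
markers sit on the skin, so corresponding trajectories carry a constant
offset.  That systematic bias is removed by zero-mean shifting (subtracting
each joint-axis channel's mean over the analysed walking segment) before
computing per-joint Euclidean distance statistics and per-axis Pearson
correlations.  Gait-parameter agreement uses the absolute error
``e_a = |device - reference|``, the signed relative error
``e_r = device - reference`` (negative when the device underestimates),
the RMSE, a paired Wilcoxon signed-rank test on per-trial means, and an
ordinary least-squares regression of device on reference values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from gaitconcord.core import AxisConvention, SkeletonSequence

__all__ = [
    "ErrorMetrics",
    "AgreementReport",
    "zero_mean_shift",
    "joint_distance_stats",
    "pearson_by_axis",
    "classify_agreement",
    "wilcoxon_paired",
    "error_metrics",
    "regression_summary",
]


def zero_mean_shift(seq: SkeletonSequence) -> SkeletonSequence:
    """Subtract each joint-axis channel's mean (missing samples ignored)."""
    out = seq.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channels
        means = np.nanmean(out.positions, axis=0, keepdims=True)
    if np.isnan(means).any():
        bad = [
            seq.joint_names[j]
            for j in range(len(seq.joint_names))
            if np.isnan(means[0, j]).any()
        ]
        raise ValueError(f"all-missing channel(s): {bad}")
    out.positions = out.positions - means
    return out


def _common_check(a: SkeletonSequence, b: SkeletonSequence) -> None:
    if a.joint_names != b.joint_names:
        raise ValueError("sequences must share the same joints in the same order")
    if a.n_frames != b.n_frames or not np.allclose(a.timestamps, b.timestamps, atol=1e-9):
        raise ValueError("sequences must share timestamps")


def joint_distance_stats(a: SkeletonSequence, b: SkeletonSequence) -> dict[str, dict]:
    """Per-joint mean ± sd of the per-frame 3D Euclidean distance (mm).

    Frames where either system's sample is missing are excluded for that
    joint; the count of frames used is reported.
    """
    _common_check(a, b)
    out: dict[str, dict] = {}
    for j, name in enumerate(a.joint_names):
        diff = a.positions[:, j, :] - b.positions[:, j, :]
        d = np.linalg.norm(diff, axis=1)
        d = d[~np.isnan(d)]
        if d.size == 0:
            out[name] = {"mean_mm": float("nan"), "sd_mm": float("nan"), "n": 0}
            continue
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        out[name] = {"mean_mm": float(d.mean()), "sd_mm": sd, "n": int(d.size)}
    return out


def pearson_by_axis(
    a: SkeletonSequence,
    b: SkeletonSequence,
    convention: AxisConvention | None = None,
) -> dict[str, dict[str, float]]:
    """Per-joint, per-gait-axis (AP/ML/V) Pearson correlation.

    Zero-variance channels yield NaN with a warning rather than an error.
    """
    convention = convention or AxisConvention()
    _common_check(a, b)
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(a.joint_names):
        row: dict[str, float] = {}
        for axis in ("ap", "ml", "v"):
            x = convention.component(a.positions[:, j, :], axis)
            y = convention.component(b.positions[:, j, :], axis)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"undefined correlation for {name}/{axis} (constant channel)")
                row[axis] = float("nan")
                continue
            row[axis] = float(_scipy_stats.pearsonr(x, y).statistic)
        out[name] = row
    return out


def classify_agreement(r: float) -> str | None:
    """Qualitative agreement level for a Pearson correlation.

    poor (r < 0.4), moderate (0.4 <= r < 0.7), good (0.7 <= r < 0.9),
    excellent (r >= 0.9).  ``None`` for a missing (NaN) correlation.
    """
    if r is None or (isinstance(r, float) and np.isnan(r)):
        return None
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"correlation out of range: {r}")
    if r < 0.4:
        return "poor"
    if r < 0.7:
        return "moderate"
    if r < 0.9:
        return "good"
    return "excellent"


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties get mid-ranks.  The null distribution
    of the positive-rank sum W+ is computed exactly for n <= 25 (dynamic
    programming over all 2^n sign assignments, which handles mid-ranks) and
    by the normal approximation with tie correction above.  Returns
    ``(W_min, p)`` where ``W_min = min(W+, W-)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    ranks = _scipy_stats.rankdata(np.abs(d))  # mid-ranks on ties
    w_plus = float(ranks[d > 0].sum())
    w_total = float(ranks.sum())  # = n(n+1)/2
    w_minus = w_total - w_plus
    w_min = min(w_plus, w_minus)
    if n <= 25:
        # exact: distribution of W+ over the 2^n equally likely sign vectors,
        # via a DP on doubled ranks (mid-ranks are half-integers)
        r2 = np.round(2 * ranks).astype(int)
        total2 = int(r2.sum())
        counts = np.zeros(total2 + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w_min))
        p = float(counts[: w2 + 1].sum() * 2.0)  # symmetry of W+ about total/2
        p = min(1.0, p)
    else:
        mean = w_total / 2.0
        # variance with tie correction
        var = float(np.sum(ranks**2)) / 4.0
        z = (w_min - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * _scipy_stats.norm.cdf(z)))
    return w_min, p


@dataclass(frozen=True)
class ErrorMetrics:
    """Paired-parameter agreement: e_a = |dev - ref|, e_r = dev - ref, RMSE."""

    absolute_error_mean: float
    absolute_error_sd: float
    relative_error_mean: float
    relative_error_sd: float
    rmse: float
    n: int

    def as_dict(self) -> dict:
        return {
            "absolute_error_mean": self.absolute_error_mean,
            "absolute_error_sd": self.absolute_error_sd,
            "relative_error_mean": self.relative_error_mean,
            "relative_error_sd": self.relative_error_sd,
            "rmse": self.rmse,
            "n": self.n,
        }


def error_metrics(dev_values: Sequence[float], ref_values: Sequence[float]) -> ErrorMetrics:
    """Absolute/relative error summaries and RMSE over paired values."""
    dev = np.asarray(dev_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if dev.shape != ref.shape or dev.size < 1:
        raise ValueError("paired value lists must have equal, non-zero length")
    e_r = dev - ref
    e_a = np.abs(e_r)
    sd_a = float(e_a.std(ddof=1)) if e_a.size > 1 else 0.0
    sd_r = float(e_r.std(ddof=1)) if e_r.size > 1 else 0.0
    return ErrorMetrics(
        absolute_error_mean=float(e_a.mean()),
        absolute_error_sd=sd_a,
        relative_error_mean=float(e_r.mean()),
        relative_error_sd=sd_r,
        rmse=float(np.sqrt(np.mean(e_r**2))),
        n=int(dev.size),
    )


def regression_summary(
    dev_values: Sequence[float], ref_values: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit of device on reference values: (slope, intercept, R²)."""
    dev = np.asarray(dev_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if dev.shape != ref.shape or dev.size < 2:
        raise ValueError("need at least two paired values")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate regression: constant reference values")
    res = _scipy_stats.linregress(ref, dev)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class AgreementReport:
    """Full agreement summary between one device and the reference."""

    joint_distances: dict[str, dict]
    correlations: dict[str, dict[str, float]]
    correlation_levels: dict[str, dict[str, str | None]]
    parameter_errors: dict[str, ErrorMetrics]
    wilcoxon: dict[str, dict]
    regressions: dict[str, dict]
    metadata: dict

    def as_dict(self) -> dict:
        return {
            "joint_distances": self.joint_distances,
            "correlations": self.correlations,
            "correlation_levels": self.correlation_levels,
            "parameter_errors": {k: v.as_dict() for k, v in self.parameter_errors.items()},
            "wilcoxon": self.wilcoxon,
            "regressions": self.regressions,
            "metadata": self.metadata,
        }


def build_agreement_report(
    ref: SkeletonSequence,
    dev: SkeletonSequence,
    params_ref: dict[str, np.ndarray],
    params_dev: dict[str, np.ndarray],
    convention: AxisConvention | None = None,
    metadata: dict | None = None,
) -> AgreementReport:
    """Assemble the full report from aligned, zero-mean-shifted sequences
    and per-parameter paired value lists (trial means or per-occurrence).

    Parameter pairs are truncated to the common length, the standard
    approach when the two systems detect slightly different event counts.
    """
    convention = convention or AxisConvention()
    distances = joint_distance_stats(ref, dev)
    corr = pearson_by_axis(ref, dev, convention)
    levels = {
        j: {ax: classify_agreement(r) for ax, r in row.items()} for j, row in corr.items()
    }
    errors: dict[str, ErrorMetrics] = {}
    wilc: dict[str, dict] = {}
    regs: dict[str, dict] = {}
    for key in params_ref:
        pr = np.asarray(params_ref[key], float)
        pd = np.asarray(params_dev.get(key, []), float)
        n = min(pr.size, pd.size)
        if n == 0:
            continue
        pr, pd = pr[:n], pd[:n]
        errors[key] = error_metrics(pd, pr)
        if n >= 1:
            stat, p = wilcoxon_paired(pd, pr)
            wilc[key] = {
                "statistic": stat,
                "p": p,
                "significant_0.05": bool(p < 0.05),
                "significant_0.01": bool(p < 0.01),
            }
        # regression is meaningless when the reference values barely vary
        # (e.g. a single perfectly periodic trial); require a 2% spread as
        # in pooled multi-speed comparisons
        if n >= 2 and np.ptp(pr) > 0.02 * max(1e-12, float(np.abs(pr).max())):
            slope, intercept, r2 = regression_summary(pd, pr)
            regs[key] = {"slope": slope, "intercept": intercept, "r_squared": r2}
    meta = {
        "zero_mean_shifted": True,
        "sd_denominator": "n-1",
        "multiple_testing_correction": "none",
        "correlation_aggregation": "per trial over frames",
        **(metadata or {}),
    }
    return AgreementReport(distances, corr, levels, errors, wilc, regs, meta)
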