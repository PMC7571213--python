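"""Agreement statistics: distances, correlations, Wilcoxon, error metrics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from gaitconcord.core import SkeletonSequence
from gaitconcord.stats import (
    classify_agreement,
    error_metrics,
    joint_distance_stats,
    pearson_by_axis,
    regression_summary,
    wilcoxon_paired,
    zero_mean_shift,
)


def seq_from(positions, joints=("j",), rate=100.0):
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    return SkeletonSequence("s", list(joints), np.arange(n) / rate, positions, rate)


class TestZeroMeanShift:
    def test_constant_channel_becomes_zero(self):
        pos = np.tile([1.0, 2.0, 3.0], (10, 1, 1))
        out = zero_mean_shift(seq_from(pos))
        np.testing.assert_allclose(out.positions, 0.0, atol=1e-12)

    def test_zero_mean_input_unchanged(self, rng):
        pos = rng.normal(size=(50, 2, 3))
        pos -= pos.mean(axis=0, keepdims=True)
        out = zero_mean_shift(seq_from(pos, joints=("a", "b")))
        np.testing.assert_allclose(out.positions, pos, atol=1e-12)

    def test_post_hoc_channel_means_vanish(self, rng):
        pos = rng.normal(5.0, 2.0, size=(200, 3, 3))
        out = zero_mean_shift(seq_from(pos, joints=("a", "b", "c")))
        assert np.abs(out.positions.mean(axis=0)).max() < 1e-12

    def test_missing_samples_ignored_not_poisoned(self, rng):
        pos = rng.normal(size=(30, 1, 3))
        pos[3] = np.nan
        out = zero_mean_shift(seq_from(pos))
        assert np.isnan(out.positions[3]).all()
        assert abs(np.nanmean(out.positions[:, 0, 0])) < 1e-12

    def test_all_missing_channel_rejected(self):
        pos = np.full((5, 1, 3), np.nan)
        with pytest.raises(ValueError, match="all-missing"):
            zero_mean_shift(seq_from(pos))


class TestJointDistanceStats:
    def test_identical_sequences_give_zero(self, rng):
        a = seq_from(rng.normal(size=(40, 2, 3)), joints=("a", "b"))
        out = joint_distance_stats(a, a)
        assert out["a"]["mean_mm"] == 0.0 and out["a"]["sd_mm"] == 0.0

    def test_constant_offset_removed_by_zero_mean_shift(self, rng):
        pos = rng.normal(size=(100, 1, 3))
        a = seq_from(pos)
        b = seq_from(pos + np.array([5.0, -3.0, 2.0]))
        out = joint_distance_stats(zero_mean_shift(a), zero_mean_shift(b))
        assert out["j"]["mean_mm"] < 1e-9

    def test_matches_per_frame_norm_oracle(self, rng):
        a = seq_from(rng.normal(size=(60, 2, 3)), joints=("a", "b"))
        b = seq_from(rng.normal(size=(60, 2, 3)), joints=("a", "b"))
        out = joint_distance_stats(a, b)
        for j, name in enumerate(("a", "b")):
            d = np.linalg.norm(a.positions[:, j] - b.positions[:, j], axis=1)
            assert np.isclose(out[name]["mean_mm"], d.mean())
            assert np.isclose(out[name]["sd_mm"], d.std(ddof=1))


class TestPearson:
    def test_perfect_and_inverted_correlation(self, rng):
        pos = rng.normal(size=(100, 1, 3))
        a = seq_from(pos)
        assert all(v == pytest.approx(1.0) for v in pearson_by_axis(a, a)["j"].values())
        b = seq_from(-pos)
        assert all(v == pytest.approx(-1.0) for v in pearson_by_axis(a, b)["j"].values())

    def test_affine_rescaling_invariance(self, rng):
        pos = rng.normal(size=(100, 1, 3))
        a = seq_from(pos)
        b = seq_from(3.0 * pos + 7.0)
        assert all(v == pytest.approx(1.0) for v in pearson_by_axis(a, b)["j"].values())

    def test_noise_attenuation_matches_analytic_value(self):
        # r between x and x+noise is 1/sqrt(1 + sigma_n^2/sigma_x^2)
        rng = np.random.default_rng(99)
        n = 20000
        x = rng.normal(0.0, 2.0, size=(n, 1, 3))
        noise = rng.normal(0.0, 1.0, size=(n, 1, 3))
        r = pearson_by_axis(seq_from(x), seq_from(x + noise))["j"]
        expected = 1.0 / np.sqrt(1 + (1.0 / 2.0) ** 2)
        for v in r.values():
            assert v == pytest.approx(expected, abs=0.01)

    def test_constant_channel_yields_nan_with_warning(self, rng):
        a = seq_from(rng.normal(size=(20, 1, 3)))
        b = seq_from(np.zeros((20, 1, 3)))
        with pytest.warns(UserWarning, match="undefined correlation"):
            out = pearson_by_axis(a, b)
        assert all(np.isnan(v) for v in out["j"].values())


class TestClassifyAgreement:
    @pytest.mark.parametrize(
        "r,level",
        [
            (0.39, "poor"),
            (0.4, "moderate"),
            (0.69, "moderate"),
            (0.7, "good"),
            (0.89, "good"),
            (0.9, "excellent"),
            (0.95, "excellent"),
            (-0.01, "poor"),
        ],
    )
    def test_threshold_boundaries(self, r, level):
        assert classify_agreement(r) == level

    def test_missing_passes_through(self):
        assert classify_agreement(float("nan")) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_agreement(1.5)


def brute_force_wilcoxon(x, y):
    """Exact two-sided signed-rank p by full 2^n enumeration."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return min(1.0, count / 2.0**n)


class TestWilcoxon:
    def test_equal_samples_give_p_one(self):
        with pytest.warns(UserWarning, match="all differences"):
            stat, p = wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_five_positive_differences_exact_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.0, 1.0, 2.0, 3.0, 4.0]
        stat, p = wilcoxon_paired(x, y)
        assert stat == 0.0
        assert p == pytest.approx(2.0 / 2**5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.8, size=n)
        if seed % 3 == 0:  # force ties in |d|
            y[: n // 2] = x[: n // 2] + 0.5
            y[n // 2 :] = x[n // 2 :] - 0.5
        _, p = wilcoxon_paired(x, y)
        assert p == pytest.approx(brute_force_wilcoxon(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_mode_without_ties(self, seed):
        rng = np.random.default_rng(seed + 1000)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        _, p = wilcoxon_paired(x, y)
        sp = sps.wilcoxon(x, y, mode="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(sp, rel=1e-10)

    def test_large_sample_normal_approximation_is_sane(self, rng):
        x = rng.normal(size=60)
        y = x + 0.8 + rng.normal(scale=0.3, size=60)
        _, p = wilcoxon_paired(x, y)
        assert p < 1e-6


class TestErrorMetrics:
    def test_constructed_pair(self):
        m = error_metrics([0.44], [0.48])
        assert m.absolute_error_mean == pytest.approx(0.04)
        assert m.relative_error_mean == pytest.approx(-0.04)
        assert m.rmse == pytest.approx(0.04)

    def test_equal_inputs_all_zero(self):
        m = error_metrics([1.0, 2.0], [1.0, 2.0])
        assert m.absolute_error_mean == m.relative_error_mean == m.rmse == 0.0

    def test_matches_elementwise_oracle(self, rng):
        dev, ref = rng.normal(size=(2, 40))
        m = error_metrics(dev, ref)
        e = dev - ref
        assert m.absolute_error_mean == pytest.approx(np.abs(e).mean(), abs=1e-12)
        assert m.absolute_error_sd == pytest.approx(np.abs(e).std(ddof=1), abs=1e-12)
        assert m.relative_error_mean == pytest.approx(e.mean(), abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt((e**2).mean()), abs=1e-12)

    def test_rmse_bounds(self, rng):
        for _ in range(20):
            dev, ref = rng.normal(size=(2, 15))
            m = error_metrics(dev, ref)
            n = 15
            assert m.rmse >= abs(m.relative_error_mean) - 1e-12
            assert m.rmse >= m.relative_error_sd * np.sqrt((n - 1) / n) - 1e-12


class TestRegression:
    def test_identity_fit(self):
        v = np.array([0.4, 0.5, 0.6, 0.7])
        slope, intercept, r2 = regression_summary(v, v)
        assert (slope, intercept, r2) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))

    def test_affine_noiseless_fit(self):
        ref = np.array([1.0, 2.0, 3.0])
        slope, intercept, r2 = regression_summary(2 * ref + 1, ref)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        ref = rng.normal(size=50)
        dev = 1.3 * ref + 0.2 + rng.normal(scale=0.1, size=50)
        slope, intercept, r2 = regression_summary(dev, ref)
        X = np.column_stack([ref, np.ones_like(ref)])
        beta = np.linalg.solve(X.T @ X, X.T @ dev)
        assert slope == pytest.approx(beta[0], abs=1e-12)
        assert intercept == pytest.approx(beta[1], abs=1e-12)
        assert r2 == pytest.approx(np.corrcoef(ref, dev)[0, 1] ** 2, abs=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            regression_summary([1.0, 2.0], [3.0, 3.0])
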