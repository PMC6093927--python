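import itertools

import numpy as np
import pytest

from eegmvpa.decode import DecodabilityCurve
from eegmvpa.timestats import (
    SignificanceTrace,
    fdr_correct,
    latency_peak,
    signed_rank_vs_baseline,
    sliding_correlation,
    subsample_category_curves,
)

from conftest import SHORT_BASELINE


def bh_oracle(p):
    """Brute-force step-up definition: q_i = min_{j: p_j >= p_i} p_j * m / rank_j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    ranked = p[order] * m / np.arange(1, m + 1)
    best = np.minimum.accumulate(ranked[::-1])[::-1]
    q[order] = np.minimum(best, 1.0)
    return q


def signed_rank_oracle_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = d.size
    stats_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    stats_all = np.asarray(stats_all)
    mean_w = ranks.sum() / 2
    extremity = abs(w_obs - mean_w)
    return float(np.mean(np.abs(stats_all - mean_w) >= extremity - 1e-12))


class TestFdr:
    def test_hand_example(self):
        q = fdr_correct([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_trivial_cases(self):
        assert fdr_correct([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 25))
            assert np.allclose(fdr_correct(p), bh_oracle(p), atol=1e-12)

    def test_nan_propagates_with_valid_rest(self):
        q = fdr_correct([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert not np.isnan(q[0]) and not np.isnan(q[2])

    def test_storey_variant_is_monotone_and_bounded(self, rng):
        p = np.sort(rng.uniform(size=50))
        q = fdr_correct(p, method="storey")
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))
        # with a signal-free uniform sample, Storey q should not exceed BH by much
        assert np.all(q <= fdr_correct(p) + 1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_correct([0.5], method="bonferroni-ish")


class TestSignedRank:
    def test_agrees_with_enumeration_oracle(self, rng):
        from eegmvpa.timestats import _wilcoxon_p
        for _ in range(25):
            d = rng.standard_normal(rng.integers(6, 11))
            assert _wilcoxon_p(d) == pytest.approx(signed_rank_oracle_p(d), abs=1e-9)

    def test_identical_pre_post_not_significant(self):
        t = np.arange(-100, 200, 5.0) + 2
        vals = np.tile(np.ones(t.size), (10, 1))
        curve = DecodabilityCurve(vals, t, "c", "pooled", ("O1",))
        trace = signed_rank_vs_baseline(curve, SHORT_BASELINE)
        assert not trace.significant.any()
        post = t > 0
        assert np.allclose(trace.p_values[post], 1.0)

    def test_strong_shift_detected(self, rng):
        t = np.arange(-100, 200, 5.0) + 2
        vals = rng.standard_normal((10, t.size)) * 0.05
        vals[:, t > 100] += 1.0
        curve = DecodabilityCurve(vals, t, "c", "pooled", ("O1",))
        trace = signed_rank_vs_baseline(curve, SHORT_BASELINE)
        assert trace.significant[t > 100].mean() > 0.9
        # FDR allows a small fraction of false discoveries among null bins
        assert trace.significant[(t > 0) & (t < 80)].mean() < 0.3

    def test_input_contracts(self):
        t = np.arange(-100, 200, 5.0) + 2
        small = DecodabilityCurve(np.zeros((3, t.size)), t, "c", "pooled", ("O1",))
        with pytest.raises(ValueError, match="5 subjects"):
            signed_rank_vs_baseline(small, SHORT_BASELINE)
        corrected = DecodabilityCurve(np.zeros((10, t.size)), t, "c", "pooled", ("O1",),
                                      baseline_corrected=True)
        with pytest.raises(ValueError, match="baseline"):
            signed_rank_vs_baseline(corrected, SHORT_BASELINE)


class TestLatencyPeak:
    def _curve_trace(self, t, values, sig):
        curve = DecodabilityCurve(values, t, "c", "pooled", ("O1",))
        trace = SignificanceTrace(t, np.where(sig, 0.01, 0.5),
                                  np.where(sig, 0.01, 0.5), sig)
        return curve, trace

    def test_first_significant_bin_is_latency(self):
        t = np.arange(-100, 200, 5.0) + 2
        sig = t >= 85
        curve, trace = self._curve_trace(t, np.where(t >= 85, 1.0, 0.0), sig)
        lp = latency_peak(curve, trace)
        assert lp.latency_ms == t[np.flatnonzero(sig)[0]]

    def test_monotone_curve_peaks_at_last_bin(self):
        t = np.arange(-100, 200, 5.0) + 2
        curve, trace = self._curve_trace(t, np.linspace(0, 1, t.size), t > 0)
        lp = latency_peak(curve, trace)
        assert lp.peak_ms == t[-1]

    def test_null_trace_has_no_latency(self):
        t = np.arange(-100, 200, 5.0) + 2
        curve, trace = self._curve_trace(t, np.zeros(t.size), np.zeros(t.size, bool))
        lp = latency_peak(curve, trace)
        assert lp.latency_ms is None
        assert lp.peak_ms is not None


class TestSlidingCorrelation:
    def _curve(self, t, vals):
        return DecodabilityCurve(vals, t, "c", "pooled", ("O1",))

    def test_affine_copies_correlate_perfectly(self, rng):
        t = np.arange(-100, 200, 5.0) + 2
        x = rng.standard_normal(t.size)
        a = self._curve(t, x)
        b = self._curve(t, 2 * x + 1)
        res = sliding_correlation(a, b, 50.0)
        defined = ~np.isnan(res.r)
        assert defined.sum() == t.size - 9
        assert np.allclose(res.r[defined], 1.0)
        res_neg = sliding_correlation(a, self._curve(t, -x), 50.0)
        assert np.allclose(res_neg.r[~np.isnan(res_neg.r)], -1.0)

    def test_self_correlation_is_one(self, rng):
        t = np.arange(-100, 200, 5.0) + 2
        x = rng.standard_normal(t.size)
        res = sliding_correlation(self._curve(t, x), self._curve(t, x), 50.0)
        assert np.allclose(res.r[~np.isnan(res.r)], 1.0)

    def test_window_must_be_bin_multiple(self, rng):
        t = np.arange(-100, 200, 5.0) + 2
        x = rng.standard_normal(t.size)
        with pytest.raises(ValueError, match="multiple"):
            sliding_correlation(self._curve(t, x), self._curve(t, x), 12.0)

    def test_phase_shifted_bumps_anticorrelate(self):
        t = np.arange(-100, 400, 5.0) + 2
        bump = lambda c: np.exp(-0.5 * ((t - c) / 20.0) ** 2)
        res = sliding_correlation(self._curve(t, bump(150.0)),
                                  self._curve(t, bump(190.0)), 50.0)
        span = (t > 150) & (t < 200)
        assert np.nanmin(res.r[span]) < -0.5


class TestSubsampleCurves:
    def test_full_size_equals_pooled_curve(self, null_dataset):
        from eegmvpa.decode import dimension_curve
        curves, report = subsample_category_curves(
            null_dataset, sizes=(144, 12), n_reps=2, seed=3,
            baseline_window=SHORT_BASELINE)
        full = dimension_curve(null_dataset, "category",
                               baseline_window=SHORT_BASELINE)
        assert np.allclose(curves[144].values, full.values, atol=1e-10)
        assert (144, 12) in report

    def test_determinism_and_size_error(self, null_dataset):
        a, _ = subsample_category_curves(null_dataset, sizes=(12,), n_reps=2, seed=3,
                                         baseline_window=SHORT_BASELINE)
        b, _ = subsample_category_curves(null_dataset, sizes=(12,), n_reps=2, seed=3,
                                         baseline_window=SHORT_BASELINE)
        assert np.array_equal(a[12].values, b[12].values)
        with pytest.raises(ValueError, match="exceeds"):
            subsample_category_curves(null_dataset, sizes=(200,), n_reps=1)
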