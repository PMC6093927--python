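import numpy as np
import pytest
from scipy import stats

from eegmvpa import decode
from eegmvpa.decode import (
    DecodabilityCurve,
    average_pairs,
    dimension_curve,
    dprime,
    random_subsample_curve,
    scalp_map,
    timecourse,
)
from eegmvpa.design import PERI_FRONTAL, PERI_OCCIPITAL
from eegmvpa.synth import EffectSpec, SynthConfig, generate_group

from conftest import SHORT_BASELINE, SHORT_WINDOW


def closed_form_1d(a, b):
    """Classic univariate sensitivity index, the 1-D oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return abs(a.mean() - b.mean()) / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)


class TestDprime:
    def test_univariate_example(self):
        # means 1 and 5, both sample variances 2 -> 4/sqrt(2)
        assert dprime([0, 2], [4, 6]) == pytest.approx(4 / np.sqrt(2), abs=1e-12)

    def test_projection_example(self):
        a = np.array([[0.0, 0.0], [0.0, 2.0]])
        b = np.array([[3.0, 1.0], [5.0, 1.0]])
        # projection onto the x axis: {0,0} vs {3,5}
        assert dprime(a, b) == pytest.approx(4.0, abs=1e-12)

    def test_identical_clusters_give_zero(self, rng):
        pts = rng.standard_normal((10, 4))
        assert dprime(pts, pts.copy()) == 0.0

    def test_zero_variance_with_distinct_means_errors(self):
        a = np.tile([0.0, 1.0], (3, 1))
        b = np.tile([2.0, 1.0], (3, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            dprime(a, b)

    def test_small_clusters_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            dprime([1.0], [2.0, 3.0])

    def test_matches_1d_closed_form(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 30, size=2)
            a = rng.standard_normal(n1) * rng.uniform(0.5, 3)
            b = rng.standard_normal(n2) + rng.uniform(-2, 2)
            assert dprime(a, b) == pytest.approx(closed_form_1d(a, b), abs=1e-12)

    def test_invariances(self, rng):
        """Rotation, translation and positive scaling leave d' unchanged."""
        for _ in range(200):
            d = int(rng.integers(2, 8))
            a = rng.standard_normal((int(rng.integers(3, 15)), d))
            b = rng.standard_normal((int(rng.integers(3, 15)), d)) + rng.uniform(-1, 1)
            base = dprime(a, b)
            q, _ = np.linalg.qr(rng.standard_normal((d, d)))
            shift = rng.standard_normal(d)
            c = rng.uniform(0.1, 10)
            assert dprime(a @ q + shift, b @ q + shift) == pytest.approx(base, rel=1e-9)
            assert dprime(c * a, c * b) == pytest.approx(base, rel=1e-9)

    def test_vectorized_bins_match_scalar_path(self, rng):
        X = rng.standard_normal((5, 7, 20))
        ia, ib = np.arange(8), np.arange(8, 20)
        vec = decode._dprime_bins(X, ia, ib)
        for j in range(7):
            assert vec[j] == pytest.approx(dprime(X[:, j, ia].T, X[:, j, ib].T), abs=1e-12)


class TestTimecourse:
    def test_baseline_window_mean_is_zero(self, null_dataset):
        curve = timecourse(null_dataset, ("category", "car", "face"),
                           baseline_window=SHORT_BASELINE)
        pre = (curve.time_ms >= SHORT_BASELINE[0]) & (curve.time_ms < SHORT_BASELINE[1])
        assert abs(curve.values[pre].mean()) < 1e-10
        assert curve.baseline_corrected

    def test_planted_effect_peaks_at_onset(self, planted_dataset):
        curve = dimension_curve(planted_dataset, "category",
                                baseline_window=SHORT_BASELINE, condition="car")
        post = curve.time_ms > 0
        peak_t = curve.time_ms[post][np.argmax(curve.values[post])]
        assert abs(peak_t - 105.0) <= 10.0  # within two 5 ms bins

    def test_per_condition_agrees_with_pooled_on_uniform_effect(self, design):
        # the category effect applies to every variation condition, so the
        # stratified and pooled curves should agree up to sampling error
        eff = EffectSpec("category", "car", "global", onset_ms=100.0,
                         width_ms=5.0, amplitude=25.0)
        cfg = SynthConfig(n_subjects=3, epoch_window=SHORT_WINDOW,
                          effects=(eff,), seed=33)
        curves = {}
        for scheme in ("pooled", "per_condition"):
            group = [
                dimension_curve(ds, "category", scheme,
                                baseline_window=SHORT_BASELINE, condition="car")
                for ds in generate_group(cfg)
            ]
            curves[scheme] = np.mean([c.values for c in group], axis=0)
        t = np.arange(len(curves["pooled"]))
        peak_pooled = int(np.argmax(curves["pooled"]))
        peak_strat = int(np.argmax(curves["per_condition"]))
        assert abs(peak_pooled - peak_strat) <= 2
        ratio = curves["per_condition"][peak_strat] / curves["pooled"][peak_pooled]
        assert 0.5 < ratio < 2.0

    def test_unknown_scheme_and_missing_condition(self, null_dataset):
        with pytest.raises(ValueError, match="scheme"):
            timecourse(null_dataset, ("category", "car", "face"), scheme="magic")
        with pytest.raises(ValueError, match="no trials"):
            timecourse(null_dataset, ("category", "car", "boat"))

    def test_monotone_in_planted_amplitude(self, design):
        """Stronger planted effects never reduce the peak group d'."""
        amps = [0.0, 5.0, 10.0, 20.0, 40.0]
        peaks = []
        for amp in amps:
            eff = EffectSpec("category", "car", "occipital", onset_ms=100.0,
                             width_ms=5.0, amplitude=amp)
            cfg = SynthConfig(n_subjects=2, epoch_window=SHORT_WINDOW,
                              effects=(eff,), seed=77)  # same noise seed each time
            vals = np.mean([
                dimension_curve(ds, "category", baseline_window=SHORT_BASELINE,
                                condition="car").values
                for ds in generate_group(cfg)
            ], axis=0)
            peaks.append(vals.max())
        rho = stats.spearmanr(amps, peaks).statistic
        assert rho > 0.95


class TestAveragePairs:
    def test_arithmetic_mean(self, null_dataset):
        t = null_dataset.time_ms
        mk = lambda v: DecodabilityCurve(np.full(t.size, v), t, f"c{v}", "pooled", ("O1",))
        avg = average_pairs([mk(1.0), mk(2.0), mk(3.0)])
        assert np.allclose(avg.values, 2.0)

    def test_identical_inputs(self, null_dataset):
        c = timecourse(null_dataset, ("category", "car", "face"))
        avg = average_pairs([c, c, c])
        assert np.allclose(avg.values, c.values)

    def test_mismatched_axes_error(self):
        a = DecodabilityCurve(np.zeros(3), [0, 5, 10], "a", "pooled", ("O1",))
        b = DecodabilityCurve(np.zeros(4), [0, 5, 10, 15], "b", "pooled", ("O1",))
        with pytest.raises(ValueError, match="time axes"):
            average_pairs([a, b])


class TestScalpMap:
    def test_shape_and_window_error(self, null_dataset):
        m = scalp_map(null_dataset, ("category", "car", "face"), center_ms=100.0,
                      baseline_window=SHORT_BASELINE)
        assert m.values.shape == (31,)
        with pytest.raises(ValueError, match="window"):
            scalp_map(null_dataset, ("category", "car", "face"), center_ms=190.0,
                      baseline_window=SHORT_BASELINE)

    def test_null_map_near_zero(self, null_dataset):
        m = scalp_map(null_dataset, ("category", "car", "face"), center_ms=100.0,
                      baseline_window=SHORT_BASELINE)
        assert abs(m.values.mean()) < 0.3

    def test_planted_occipital_effect_ranks_occipital_first(self, planted_dataset):
        m = scalp_map(planted_dataset, ("category", "car", "face"), center_ms=105.0,
                      baseline_window=SHORT_BASELINE)
        assert set(m.top_channels(9)) == set(PERI_OCCIPITAL)
        occ = [m.values[list(m.channel_names).index(c)] for c in PERI_OCCIPITAL]
        fro = [m.values[list(m.channel_names).index(c)] for c in PERI_FRONTAL]
        assert np.mean(occ) > np.mean(fro) + 1.0


class TestRandomSubsample:
    def test_determinism_and_errors(self, null_dataset):
        c1 = random_subsample_curve(null_dataset, 100, n_reps=3, seed=4,
                                    baseline_window=SHORT_BASELINE)
        c2 = random_subsample_curve(null_dataset, 100, n_reps=3, seed=4,
                                    baseline_window=SHORT_BASELINE)
        assert np.array_equal(c1.values, c2.values)
        with pytest.raises(ValueError, match="trials"):
            random_subsample_curve(null_dataset, 300)

    def test_null_post_stimulus_matches_baseline(self, null_dataset):
        c = random_subsample_curve(null_dataset, 144, n_reps=20, seed=4,
                                   baseline_window=SHORT_BASELINE)
        post = c.time_ms > 0
        assert abs(c.values[post].mean()) < 0.1
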