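"""Group-level significance and temporal statistics for decodability curves.

Per time bin, subjects' d' values are tested against each subject's own
pre-stimulus average with a two-sided Wilcoxon signed-rank test; p-values
are corrected across bins with Benjamini-Hochberg FDR (Storey's pFDR is
available as an option).  Latency is the first significant post-stimulus
bin; the peak is the maximum of the group-mean curve.  Sliding-window
Pearson correlation compares two curves' temporal profiles within trailing
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decode import (
    DEFAULT_BASELINE_MS,
    DecodabilityCurve,
    _baseline_bins,
    average_pairs,
    baseline_correct,
    pair_contrasts,
    timecourse,
    stack_curves,
)

logger = logging.getLogger(__name__)


@dataclass
class SignificanceTrace:
    """Per-bin p/q values; bins outside the tested span carry NaN."""

    time_ms: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray  # boolean, q < alpha
    alpha: float = 0.05


@dataclass
class LatencyPeak:
    latency_ms: float | None   # first significant post-stimulus bin (None if none)
    peak_ms: float
    peak_value: float


@dataclass
class SlidingCorrelation:
    time_ms: np.ndarray
    r: np.ndarray              # per-subject (subjects x bins) or 1-D
    r_group_mean: np.ndarray   # correlation of the group-mean curves
    trace: SignificanceTrace
    window_ms: float


def fdr_correct(p_values, alpha: float = 0.05, method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values (Benjamini-Hochberg step-up by default).

    ``method="storey"`` applies Storey's pFDR with a lambda=0.5 null-
    proportion estimate (the Matlab ``mafdr`` default family).  NaN inputs
    propagate as NaN with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any(~ok):
        logger.warning("%d NaN p-values propagate as NaN q-values", int((~ok).sum()))
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    if method == "bh":
        q[ok] = multipletests(pv, alpha=alpha, method="fdr_bh")[1]
    elif method == "storey":
        lam = 0.5
        pi0 = min(1.0, float((pv > lam).sum()) / (m * (1.0 - lam))) if m else 1.0
        pi0 = max(pi0, 1.0 / m)
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * pi0 * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]   # monotone step-up
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        q[ok] = out
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return q


def _wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p; all-zero differences give p = 1."""
    if np.all(diffs == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    except ValueError:
        return 1.0


def signed_rank_vs_baseline(curve: DecodabilityCurve,
                            baseline_window=DEFAULT_BASELINE_MS,
                            alpha: float = 0.05, method: str = "bh") -> SignificanceTrace:
    """Wilcoxon signed-rank of each post-stimulus bin against the subjects'
    pre-stimulus averages, FDR-corrected across bins.

    ``curve`` must be a group curve (subjects x bins) of raw (not baseline-
    subtracted) d' values: the baseline reference is each subject's mean d'
    over ``baseline_window``.
    """
    if curve.values.ndim != 2:
        raise ValueError("group curve (subjects x bins) required")
    if curve.baseline_corrected:
        raise ValueError("curve must not be baseline-corrected (reference is the raw baseline)")
    n_subj = curve.values.shape[0]
    if n_subj < 5:
        raise ValueError("signed-rank test needs >= 5 subjects")
    sel = _baseline_bins(curve.time_ms, baseline_window)
    base = curve.values[:, sel].mean(axis=1)
    post = curve.time_ms > 0
    p = np.full(curve.time_ms.shape, np.nan)
    for j in np.flatnonzero(post):
        p[j] = _wilcoxon_p(curve.values[:, j] - base)
    q = np.full_like(p, np.nan)
    q[post] = fdr_correct(p[post], alpha=alpha, method=method)
    significant = np.zeros(p.shape, dtype=bool)
    significant[post] = q[post] < alpha
    return SignificanceTrace(curve.time_ms, p, q, significant, alpha)


def latency_peak(curve: DecodabilityCurve, trace: SignificanceTrace,
                 min_run: int = 2) -> LatencyPeak:
    """Latency of the first sustained significant post-stimulus response, and
    the group-curve peak.

    Latency is the first post-stimulus bin opening a run of at least
    ``min_run`` consecutive significant bins.  The default of 2 guards
    against isolated false-positive bins: under FDR correction a curve with
    many strongly significant bins relaxes the per-bin threshold, so single
    spurious early bins are expected at a non-trivial rate, while two
    consecutive false positives are rare.  ``min_run=1`` recovers the plain
    first-significant-bin rule.
    """
    if not np.allclose(curve.time_ms, trace.time_ms):
        raise ValueError("trace is not aligned to the curve")
    post = curve.time_ms > 0
    sig = trace.significant & post
    latency = None
    run = 0
    for j in range(sig.size):
        run = run + 1 if sig[j] else 0
        if run >= min_run:
            latency = float(curve.time_ms[j - min_run + 1])
            break
    mean = curve.mean
    post_idx = np.flatnonzero(post)
    k = post_idx[int(np.argmax(mean[post_idx]))]   # argmax ties break earliest
    return LatencyPeak(latency_ms=latency, peak_ms=float(curve.time_ms[k]),
                       peak_value=float(mean[k]))


def _windowed_corr(x: np.ndarray, y: np.ndarray, wbins: int) -> np.ndarray:
    """Trailing-window Pearson r of two 1-D series; NaN where undefined."""
    n = x.shape[0]
    r = np.full(n, np.nan)
    for j in range(wbins - 1, n):
        xs = x[j - wbins + 1:j + 1]
        ys = y[j - wbins + 1:j + 1]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        r[j] = float(np.corrcoef(xs, ys)[0, 1])
    return r


def sliding_correlation(curve_a: DecodabilityCurve, curve_b: DecodabilityCurve,
                        window_ms: float = 50.0, alpha: float = 0.05,
                        method: str = "bh") -> SlidingCorrelation:
    """Pearson correlation of two curves within trailing windows.

    The window ends at each bin t (no future samples).  With group curves,
    correlations are computed per subject and group-tested (signed-rank of
    subjects' r against zero, FDR-corrected); the correlation of the
    group-mean curves is reported alongside.  With single-subject curves the
    per-window Pearson p-values are FDR-corrected directly.
    """
    if not np.allclose(curve_a.time_ms, curve_b.time_ms):
        raise ValueError("curves have mismatched time axes")
    t = curve_a.time_ms
    bin_ms = float(t[1] - t[0])
    wbins = int(round(window_ms / bin_ms))
    if abs(wbins * bin_ms - window_ms) > 1e-9 or wbins < 2:
        raise ValueError(f"window_ms must be a multiple (>=2 bins) of the {bin_ms} ms bin width")

    va = np.atleast_2d(curve_a.values)
    vb = np.atleast_2d(curve_b.values)
    if va.shape[0] != vb.shape[0]:
        raise ValueError("curves have different numbers of subjects")
    r = np.vstack([_windowed_corr(va[i], vb[i], wbins) for i in range(va.shape[0])])
    r_mean = _windowed_corr(va.mean(0), vb.mean(0), wbins)

    p = np.full(t.shape, np.nan)
    if va.shape[0] > 1:
        for j in range(wbins - 1, t.shape[0]):
            col = r[:, j]
            if np.any(np.isnan(col)):
                continue
            p[j] = _wilcoxon_p(col)
    else:
        for j in range(wbins - 1, t.shape[0]):
            if np.isnan(r[0, j]):
                continue
            xs = va[0, j - wbins + 1:j + 1]
            ys = vb[0, j - wbins + 1:j + 1]
            rr = r[0, j]
            if abs(rr) >= 1.0:
                p[j] = 0.0
            else:
                p[j] = float(stats.pearsonr(xs, ys).pvalue)
    defined = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if defined.any():
        q[defined] = fdr_correct(p[defined], alpha=alpha, method=method)
    significant = np.zeros(p.shape, dtype=bool)
    significant[defined] = q[defined] < alpha
    trace = SignificanceTrace(t, p, q, significant, alpha)
    return SlidingCorrelation(t, r if r.shape[0] > 1 else r[0], r_mean, trace, window_ms)


def subsample_category_curves(dataset, sizes=(144, 100, 48, 12, 3), n_reps: int = 100,
                              seed: int = 0, electrodes=None,
                              window_ms: float = 50.0,
                              baseline_window=DEFAULT_BASELINE_MS):
    """Category decodability at down-sampled cluster sizes, plus pairwise
    sliding correlations between the size-specific curves.

    For each size, every repetition draws that many trials per category
    cluster (without replacement), computes the pair-averaged pooled
    category curve, and repetitions are averaged.  Returns
    ``(curves_by_size, correlations_by_size_pair)``.
    """
    from .decode import _dprime_bins, condition_mask, resolve_electrodes
    from .dataset import EpochedDataset

    assert isinstance(dataset, EpochedDataset)
    names = resolve_electrodes(electrodes, dataset.channel_names)
    X = dataset.voltages[dataset.channel_indices(names)]
    pairs = pair_contrasts("category")
    cluster_idx = {
        lev: np.flatnonzero(condition_mask(dataset.trials, "category", lev))
        for lev in {p for _, a, b in pairs for p in (a, b)}
    }
    n_avail = min(len(v) for v in cluster_idx.values())
    rng = np.random.default_rng(seed)
    curves: dict[int, DecodabilityCurve] = {}
    for size in sizes:
        if size > n_avail:
            raise ValueError(f"size {size} exceeds available {n_avail} trials per category")
        reps = 1 if size == n_avail else n_reps
        acc = np.zeros(dataset.n_timebins)
        for _ in range(reps):
            sub = {lev: rng.choice(idx, size=size, replace=False)
                   for lev, idx in cluster_idx.items()}
            pair_vals = [_dprime_bins(X, sub[a], sub[b]) for _, a, b in pairs]
            acc += np.mean(pair_vals, axis=0)
        curve = DecodabilityCurve(
            values=acc / reps, time_ms=dataset.time_ms,
            contrast=f"category:subsample-n={size}", scheme="pooled",
            electrode_set=names,
        )
        curves[size] = baseline_correct(curve, baseline_window)
    report = {}
    ordered = list(curves)
    for i, s1 in enumerate(ordered):
        for s2 in ordered[i + 1:]:
            report[(s1, s2)] = sliding_correlation(curves[s1], curves[s2], window_ms)
    return curves, report


def group_signed_rank(datasets, dimension: str, scheme: str = "pooled", electrodes=None,
                      baseline_window=DEFAULT_BASELINE_MS, alpha: float = 0.05,
                      method: str = "bh"):
    """Convenience: group dimension curve (raw), its significance trace, and
    latency/peak statistics, in one call."""
    raw_curves = []
    for ds in datasets:
        pair_cs = [timecourse(ds, p, scheme, electrodes, baseline=False)
                   for p in pair_contrasts(dimension)]
        raw_curves.append(average_pairs(pair_cs))
    group_raw = stack_curves(raw_curves)
    trace = signed_rank_vs_baseline(group_raw, baseline_window, alpha, method)
    corrected = baseline_correct(group_raw, baseline_window)
    lp = latency_peak(corrected, trace)
    return corrected, trace, lp
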