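"""Projection-based d' decodability.

The decodability index between two trial clusters is computed by projecting
every trial's multichannel voltage vector onto the line joining the two
cluster means, then forming the univariate sensitivity index

    d' = (mu1 - mu2) / sqrt((sigma1^2 + sigma2^2) / 2),   mu1 > mu2,

with sample variances (n-1).  The cluster with the larger projected mean is
labelled 1, so d' is non-negative by construction; identical cluster means
give d' = 0 (the information-free limit).

Operations here cover time-resolved curves (pooled or per-condition
stratified), pair averaging, per-electrode scalp maps, and label-ignorant
random subsampling controls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import EpochedDataset
from .design import CATEGORIES, N_LEVELS, VARIATION_TYPES, resolve_electrodes

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_MS = (-200.0, 0.0)


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------

def dprime(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Projection d' between two clusters of d-dimensional points.

    ``points_a``/``points_b`` are ``(n, d)`` (1-D inputs are treated as
    ``(n, 1)``).  Requires at least two points per cluster.  Returns 0 when
    the cluster means coincide; raises if both projected variances vanish
    while the means differ.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[0] == 1 and a.ndim == 2 and np.asarray(points_a).ndim == 1:
        a = a.T
    if b.shape[0] == 1 and b.ndim == 2 and np.asarray(points_b).ndim == 1:
        b = b.T
    if a.shape[1] != b.shape[1]:
        raise ValueError("clusters must share dimensionality")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each cluster needs >= 2 points for a defined variance")
    ma, mb = a.mean(0), b.mean(0)
    diff = ma - mb
    norm = float(np.linalg.norm(diff))
    if norm == 0.0:
        return 0.0
    u = diff / norm
    pa, pb = a @ u, b @ u
    # projected mean difference equals ||ma - mb||, so cluster a is cluster 1
    va = pa.var(ddof=1)
    vb = pb.var(ddof=1)
    s = np.sqrt(0.5 * (va + vb))
    if s == 0.0:
        raise ValueError("zero-variance clusters")
    return norm / s


def _dprime_bins(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Vectorized projection d' per time bin; ``X`` is (channels, bins, trials)."""
    A = X[:, :, idx_a].astype(np.float64)
    B = X[:, :, idx_b].astype(np.float64)
    ma, mb = A.mean(2), B.mean(2)
    diff = ma - mb                                  # (ch, bins)
    norm = np.linalg.norm(diff, axis=0)             # (bins,)
    safe = np.where(norm > 0, norm, 1.0)
    u = diff / safe                                 # (ch, bins)
    pa = np.einsum("cb,cbt->bt", u, A)
    pb = np.einsum("cb,cbt->bt", u, B)
    va = pa.var(axis=1, ddof=1)
    vb = pb.var(axis=1, ddof=1)
    s = np.sqrt(0.5 * (va + vb))
    bad = (s == 0.0) & (norm > 0)
    if np.any(bad):
        raise ValueError("zero-variance clusters")
    out = np.where(norm > 0, norm / np.where(s > 0, s, 1.0), 0.0)
    return out


def _univariate_dprime_bins(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Per-channel (1-D space) d' per time bin; returns (channels, bins)."""
    A = X[:, :, idx_a].astype(np.float64)
    B = X[:, :, idx_b].astype(np.float64)
    diff = np.abs(A.mean(2) - B.mean(2))
    s = np.sqrt(0.5 * (A.var(axis=2, ddof=1) + B.var(axis=2, ddof=1)))
    bad = (s == 0.0) & (diff > 0)
    if np.any(bad):
        raise ValueError("zero-variance clusters")
    return np.where(diff > 0, diff / np.where(s > 0, s, 1.0), 0.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DecodabilityCurve:
    """Time-resolved d' values (one subject: 1-D; group: subjects x bins)."""

    values: np.ndarray
    time_ms: np.ndarray
    contrast: str
    scheme: str
    electrode_set: tuple[str, ...]
    baseline_corrected: bool = False
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_MS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.values.shape[-1] != self.time_ms.shape[0]:
            raise ValueError("values and time axis length mismatch")

    @property
    def mean(self) -> np.ndarray:
        return self.values if self.values.ndim == 1 else self.values.mean(0)

    @property
    def sem(self) -> np.ndarray:
        if self.values.ndim == 1:
            return np.zeros_like(self.values)
        return self.values.std(0, ddof=1) / np.sqrt(self.values.shape[0])

    @property
    def n_subjects(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[0]


@dataclass
class ScalpMap:
    """Per-electrode d' at one time point, averaged over +/-25 ms."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    center_ms: float
    averaging_window: tuple[float, float]
    contrast: str
    scheme: str
    baseline_corrected: bool = False

    def top_channels(self, k: int = 5) -> tuple[str, ...]:
        order = np.argsort(self.values)[::-1][:k]
        return tuple(self.channel_names[i] for i in order)


# ---------------------------------------------------------------------------
# trial selection
# ---------------------------------------------------------------------------

def condition_mask(trials: pd.DataFrame, dimension: str, level) -> np.ndarray:
    """Boolean trial mask for one condition of one information dimension."""
    if dimension == "category":
        mask = (trials["category"] == level).to_numpy()
    elif dimension in VARIATION_TYPES:
        mask = (
            (trials["variation_type"] == dimension)
            & (trials["variation_level"] == level)
        ).to_numpy()
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    if not mask.any():
        raise ValueError(f"no trials for {dimension}={level!r}")
    return mask


def pair_contrasts(dimension: str) -> list[tuple[str, object, object]]:
    """All condition pairs of one dimension (6 category pairs, 3 level pairs)."""
    if dimension == "category":
        levels: tuple = CATEGORIES
    elif dimension in VARIATION_TYPES:
        levels = tuple(range(1, N_LEVELS + 1))
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    return [(dimension, a, b) for a, b in itertools.combinations(levels, 2)]


def _strata(trials: pd.DataFrame, dimension: str) -> list[np.ndarray]:
    """Per-condition strata: 12 variation conditions for category contrasts,
    16 objects (category x exemplar, within the contrast's variation type)
    for variation contrasts."""
    if dimension == "category":
        keys = trials.groupby(["variation_type", "variation_level"], sort=True).indices
    else:
        sub = trials[trials["variation_type"] == dimension]
        keys = sub.groupby(["category", "exemplar"], sort=True).indices
        keys = {k: sub.index.to_numpy()[v] for k, v in keys.items()}
        return [np.asarray(v) for _, v in sorted(keys.items())]
    return [np.asarray(v) for _, v in sorted(keys.items())]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _baseline_bins(time_ms: np.ndarray, window=DEFAULT_BASELINE_MS) -> np.ndarray:
    lo, hi = window
    sel = (time_ms >= lo) & (time_ms < hi)
    if not sel.any():
        raise ValueError(f"no time bins inside baseline window {window}")
    return sel


def baseline_correct(curve: DecodabilityCurve,
                     window=DEFAULT_BASELINE_MS) -> DecodabilityCurve:
    """Subtract the mean d' over the pre-stimulus window (per subject)."""
    sel = _baseline_bins(curve.time_ms, window)
    vals = curve.values - curve.values[..., sel].mean(axis=-1, keepdims=True)
    return replace(curve, values=vals, baseline_corrected=True, baseline_window=tuple(window))


def timecourse(dataset: EpochedDataset, contrast, scheme: str = "pooled",
               electrodes=None, baseline: bool = True,
               baseline_window=DEFAULT_BASELINE_MS) -> DecodabilityCurve:
    """Time-resolved d' for one condition pair.

    ``contrast`` is ``(dimension, level_a, level_b)`` with dimension
    ``"category"`` or a variation type.  ``scheme="pooled"`` uses all trials
    of each condition; ``scheme="per_condition"`` computes d' within each
    stratum (variation condition for categories, object for variations) and
    averages the strata.  Strata whose clusters have fewer than 2 trials are
    skipped with a warning.
    """
    dimension, lev_a, lev_b = contrast
    names = resolve_electrodes(electrodes, dataset.channel_names)
    X = dataset.voltages[dataset.channel_indices(names)]
    mask_a = condition_mask(dataset.trials, dimension, lev_a)
    mask_b = condition_mask(dataset.trials, dimension, lev_b)

    if scheme == "pooled":
        values = _dprime_bins(X, np.flatnonzero(mask_a), np.flatnonzero(mask_b))
    elif scheme == "per_condition":
        stratum_curves = []
        for stratum in _strata(dataset.trials, dimension):
            in_stratum = np.zeros(dataset.n_trials, dtype=bool)
            in_stratum[stratum] = True
            ia = np.flatnonzero(mask_a & in_stratum)
            ib = np.flatnonzero(mask_b & in_stratum)
            if len(ia) < 2 or len(ib) < 2:
                logger.warning(
                    "skipping stratum with <2 trials per cluster (%d vs %d)", len(ia), len(ib)
                )
                continue
            stratum_curves.append(_dprime_bins(X, ia, ib))
        if not stratum_curves:
            raise ValueError("all per-condition strata were skipped")
        values = np.mean(stratum_curves, axis=0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    curve = DecodabilityCurve(
        values=values,
        time_ms=dataset.time_ms,
        contrast=f"{dimension}:{lev_a}-vs-{lev_b}",
        scheme=scheme,
        electrode_set=names,
    )
    return baseline_correct(curve, baseline_window) if baseline else curve


def average_pairs(curves: list[DecodabilityCurve]) -> DecodabilityCurve:
    """Pointwise mean of pair curves sharing a time axis."""
    if not curves:
        raise ValueError("need at least one curve")
    t0 = curves[0].time_ms
    for c in curves[1:]:
        if c.time_ms.shape != t0.shape or not np.allclose(c.time_ms, t0):
            raise ValueError("curves have mismatched time axes")
    values = np.mean([c.values for c in curves], axis=0)
    return replace(
        curves[0],
        values=values,
        contrast="mean(" + ", ".join(c.contrast for c in curves) + ")",
    )


def dimension_curve(dataset: EpochedDataset, dimension: str, scheme: str = "pooled",
                    electrodes=None, baseline: bool = True,
                    baseline_window=DEFAULT_BASELINE_MS,
                    condition=None) -> DecodabilityCurve:
    """Average d' curve across all pairs of one dimension.

    With ``condition`` set, averages only the pair curves involving that
    condition (one condition's information).
    """
    pairs = pair_contrasts(dimension)
    if condition is not None:
        pairs = [p for p in pairs if condition in p[1:]]
        if not pairs:
            raise ValueError(f"condition {condition!r} not in dimension {dimension!r}")
    curves = [
        timecourse(dataset, p, scheme, electrodes, baseline=False) for p in pairs
    ]
    avg = average_pairs(curves)
    return baseline_correct(avg, baseline_window) if baseline else avg


def variation_curve(dataset: EpochedDataset, scheme: str = "pooled", electrodes=None,
                    baseline: bool = True,
                    baseline_window=DEFAULT_BASELINE_MS) -> DecodabilityCurve:
    """Grand-average variation curve (mean over the four variation types)."""
    per_type = [
        dimension_curve(dataset, vt, scheme, electrodes, baseline=False)
        for vt in VARIATION_TYPES
    ]
    avg = average_pairs(per_type)
    avg.contrast = "variation:mean-of-4-types"
    return baseline_correct(avg, baseline_window) if baseline else avg


def scalp_map(dataset: EpochedDataset, contrast, scheme: str = "pooled",
              center_ms: float = 150.0, half_window_ms: float = 25.0,
              baseline: bool = True,
              baseline_window=DEFAULT_BASELINE_MS) -> ScalpMap:
    """Per-electrode (univariate) d' averaged over ``center +/- 25`` ms.

    Each electrode's value is the d' computed in that electrode's 1-D space,
    baseline-handled exactly like :func:`timecourse`, then averaged over the
    bins inside the window.
    """
    lo, hi = center_ms - half_window_ms, center_ms + half_window_ms
    if lo < dataset.time_ms[0] or hi > dataset.time_ms[-1]:
        raise ValueError(
            f"averaging window [{lo}, {hi}] ms exceeds epoch "
            f"[{dataset.time_ms[0]}, {dataset.time_ms[-1]}]"
        )
    dimension, lev_a, lev_b = contrast
    X = dataset.voltages
    mask_a = condition_mask(dataset.trials, dimension, lev_a)
    mask_b = condition_mask(dataset.trials, dimension, lev_b)
    if scheme == "pooled":
        curves = _univariate_dprime_bins(X, np.flatnonzero(mask_a), np.flatnonzero(mask_b))
    elif scheme == "per_condition":
        acc = []
        for stratum in _strata(dataset.trials, dimension):
            in_stratum = np.zeros(dataset.n_trials, dtype=bool)
            in_stratum[stratum] = True
            ia = np.flatnonzero(mask_a & in_stratum)
            ib = np.flatnonzero(mask_b & in_stratum)
            if len(ia) < 2 or len(ib) < 2:
                logger.warning("skipping stratum with <2 trials per cluster")
                continue
            acc.append(_univariate_dprime_bins(X, ia, ib))
        if not acc:
            raise ValueError("all per-condition strata were skipped")
        curves = np.mean(acc, axis=0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if baseline:
        sel = _baseline_bins(dataset.time_ms, baseline_window)
        curves = curves - curves[:, sel].mean(axis=1, keepdims=True)
    win = (dataset.time_ms >= lo) & (dataset.time_ms <= hi)
    return ScalpMap(
        values=curves[:, win].mean(axis=1),
        channel_names=dataset.channel_names,
        center_ms=center_ms,
        averaging_window=(lo, hi),
        contrast=f"{dimension}:{lev_a}-vs-{lev_b}",
        scheme=scheme,
        baseline_corrected=baseline,
    )


def random_subsample_curve(dataset: EpochedDataset, n_per_cluster: int,
                           n_reps: int = 1000, seed: int = 0, electrodes=None,
                           baseline: bool = True,
                           baseline_window=DEFAULT_BASELINE_MS) -> DecodabilityCurve:
    """Label-ignorant control: d' between two random disjoint trial clusters.

    Each repetition draws two disjoint clusters of ``n_per_cluster`` trials
    (ignoring all labels), computes the time-resolved d', and the reps are
    averaged.
    """
    if 2 * n_per_cluster > dataset.n_trials:
        raise ValueError(
            f"need 2x{n_per_cluster} trials, dataset has {dataset.n_trials}"
        )
    names = resolve_electrodes(electrodes, dataset.channel_names)
    X = dataset.voltages[dataset.channel_indices(names)]
    rng = np.random.default_rng(seed)
    acc = np.zeros(dataset.n_timebins)
    for _ in range(n_reps):
        perm = rng.permutation(dataset.n_trials)
        acc += _dprime_bins(X, perm[:n_per_cluster], perm[n_per_cluster:2 * n_per_cluster])
    curve = DecodabilityCurve(
        values=acc / n_reps,
        time_ms=dataset.time_ms,
        contrast=f"random-subsample:n={n_per_cluster}",
        scheme="pooled",
        electrode_set=names,
    )
    return baseline_correct(curve, baseline_window) if baseline else curve


# ---------------------------------------------------------------------------
# group helpers
# ---------------------------------------------------------------------------

def stack_curves(curves: list[DecodabilityCurve]) -> DecodabilityCurve:
    """Stack single-subject curves into one group curve (subjects x bins)."""
    if not curves:
        raise ValueError("need at least one curve")
    t0 = curves[0].time_ms
    for c in curves[1:]:
        if not np.allclose(c.time_ms, t0):
            raise ValueError("curves have mismatched time axes")
    return replace(curves[0], values=np.vstack([np.atleast_2d(c.values) for c in curves]))


def group_dimension_curve(datasets, dimension: str, scheme: str = "pooled",
                          electrodes=None, baseline: bool = True,
                          baseline_window=DEFAULT_BASELINE_MS,
                          condition=None) -> DecodabilityCurve:
    """Per-subject :func:`dimension_curve` stacked into a group curve."""
    return stack_curves([
        dimension_curve(ds, dimension, scheme, electrodes, baseline, baseline_window, condition)
        for ds in datasets
    ])
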