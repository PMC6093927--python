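"""Feed-forward / feedback information flow between electrode sets.

Representational similarity matrices (Pearson correlations between the
multi-electrode voltage vectors of all stimulus-presentation pairs at one
time bin) are computed separately for a posterior ("back", peri-occipital)
and an anterior ("front", peri-frontal) 9-electrode space.  A simplified
Granger causality then asks whether the front's present representational
geometry is explained by the back's past beyond the front's own past:

    FF(t) = pc( SM(front, t), SM(back, t-past) | SM(front, t-past) )
    FB(t) = pc( SM(back, t),  SM(front, t-past) | SM(back, t-past) )

where ``pc`` is the partial correlation of lower-triangle vectorized
matrices and ``t-past`` averages the matrices in the t-130..t-80 ms window.
Per-bin significance comes from a permutation null that shuffles the
vectorized entries of the time-t matrix only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import EpochedDataset
from .design import resolve_electrodes

logger = logging.getLogger(__name__)

PAST_WINDOW_MS = (130.0, 80.0)   # offsets before t: average t-130 .. t-80 ms


@dataclass
class SimilarityMatrix:
    stim_ids: np.ndarray          # trial ids of the presentations
    corr: np.ndarray              # n x n Pearson correlations
    electrode_set: tuple[str, ...]
    time_ms: float

    def vectorize(self) -> np.ndarray:
        """Lower-triangle (diagonal excluded) vectorization: n(n-1)/2 entries."""
        n = self.corr.shape[0]
        return self.corr[np.tril_indices(n, k=-1)]


@dataclass
class FlowResult:
    time_ms: np.ndarray
    ff: np.ndarray
    fb: np.ndarray
    diff: np.ndarray              # ff - fb
    ff_threshold: np.ndarray      # per-bin 95th percentile of permuted FF
    fb_threshold: np.ndarray
    diff_upper: np.ndarray        # 95th percentile of permuted FF - FB
    diff_lower: np.ndarray        # 5th percentile
    significant_ff: np.ndarray
    significant_fb: np.ndarray
    contrast: str = ""
    past_window_ms: tuple[float, float] = PAST_WINDOW_MS
    n_perm: int = 0


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def partial_corr(x, y, z) -> float:
    """First-order partial correlation rho_xy.z of equal-length vectors.

    Returns NaN (logged) when x or y is perfectly correlated with z.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1 or x.size < 3:
        raise ValueError("x, y, z must be equal-length 1-D vectors of length >= 3")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom <= 1e-12:
        logger.warning("partial correlation undefined: |r_xz| or |r_yz| = 1")
        return float("nan")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def similarity_matrix(dataset: EpochedDataset, electrodes, trial_indices,
                      time_ms: float) -> SimilarityMatrix:
    """Pearson correlations between the presentations' electrode-space vectors.

    Each presentation's representation is its voltage vector over the chosen
    electrodes at the bin nearest ``time_ms``.  Zero-variance representations
    yield NaN rows/columns (logged).
    """
    names = resolve_electrodes(electrodes, dataset.channel_names)
    ch = dataset.channel_indices(names)
    j = dataset.bin_index(time_ms)
    trial_indices = np.asarray(trial_indices, dtype=int)
    reps = dataset.voltages[np.ix_(ch, [j], trial_indices)][:, 0, :].T.astype(float)
    sd = reps.std(axis=1)
    n = reps.shape[0]
    corr = np.full((n, n), np.nan)
    ok = sd > 0
    if not ok.all():
        logger.warning("%d zero-variance representations: rows/cols set NaN", int((~ok).sum()))
    if ok.sum() >= 2:
        corr[np.ix_(ok, ok)] = np.corrcoef(reps[ok])
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(
        stim_ids=dataset.trials["trial_id"].to_numpy()[trial_indices],
        corr=corr,
        electrode_set=names,
        time_ms=float(dataset.time_ms[j]),
    )


def past_average(sm_series: list[SimilarityMatrix], t_ms: float,
                 past_window_ms=PAST_WINDOW_MS) -> SimilarityMatrix:
    """Entry-wise mean of the matrices in the t-130..t-80 ms window."""
    lo, hi = t_ms - past_window_ms[0], t_ms - past_window_ms[1]
    times = np.array([sm.time_ms for sm in sm_series])
    if lo < times.min() - 1e-9:
        raise ValueError(f"past window [{lo}, {hi}] ms starts before the series")
    sel = np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))
    if sel.size == 0:
        raise ValueError(f"no matrices inside past window [{lo}, {hi}] ms")
    mean = np.mean([sm_series[k].corr for k in sel], axis=0)
    return SimilarityMatrix(
        stim_ids=sm_series[sel[0]].stim_ids,
        corr=mean,
        electrode_set=sm_series[sel[0]].electrode_set,
        time_ms=t_ms,
    )


# ---------------------------------------------------------------------------
# stimulus subsets
# ---------------------------------------------------------------------------

def variation_condition_trials(trials, variation_type: str, level: int) -> np.ndarray:
    """Trial indices of one variation condition (16 objects x 3 presentations)."""
    mask = (trials["variation_type"] == variation_type) & (trials["variation_level"] == level)
    idx = np.flatnonzero(mask.to_numpy())
    if idx.size == 0:
        raise ValueError(f"no trials for {variation_type} level {level}")
    return idx


def category_flow_subsets(trials) -> list[np.ndarray]:
    """The 12 single-variation-condition subsets (48 presentations each)."""
    out = []
    for vt in sorted(trials["variation_type"].unique()):
        for lv in sorted(trials.loc[trials["variation_type"] == vt, "variation_level"].unique()):
            out.append(variation_condition_trials(trials, vt, lv))
    return out


def exemplar_flow_subsets(trials, variation_type: str) -> list[np.ndarray]:
    """Per-object subsets of one variation type (3 levels x 3 presentations)."""
    sub = trials[trials["variation_type"] == variation_type]
    # trial tables carry a RangeIndex, so index values are row positions
    return [grp.index.to_numpy() for _, grp in sub.groupby(["category", "exemplar"], sort=True)]


# ---------------------------------------------------------------------------
# vectorized series
# ---------------------------------------------------------------------------

def _sm_vec_series(dataset: EpochedDataset, ch: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Lower-triangle vectorized similarity matrices at every bin: (bins, pairs)."""
    R = dataset.voltages[np.ix_(ch, np.arange(dataset.n_timebins), subset)].astype(float)
    # standardize each (bin, presentation) vector across channels
    R = R - R.mean(axis=0, keepdims=True)
    sd = R.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, np.nan)
    Z = R / (sd * np.sqrt(R.shape[0]))
    corr = np.einsum("cbn,cbm->bnm", Z, Z)
    n = subset.size
    il, jl = np.tril_indices(n, k=-1)
    return corr[:, il, jl]


def _past_series(vecs: np.ndarray, time_ms: np.ndarray,
                 past_window_ms=PAST_WINDOW_MS) -> np.ndarray:
    """Trailing average of vectorized matrices over t-130..t-80 ms; NaN where
    the window leaves the epoch."""
    bin_ms = float(time_ms[1] - time_ms[0])
    back_lo = int(round(past_window_ms[0] / bin_ms))
    back_hi = int(round(past_window_ms[1] / bin_ms))
    out = np.full_like(vecs, np.nan)
    for j in range(vecs.shape[0]):
        if j - back_lo < 0:
            continue
        out[j] = vecs[j - back_lo:j - back_hi + 1].mean(axis=0)
    return out


def _pc_scalar(x, y, z) -> float:
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom <= 1e-12:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def _pc_perm(x: np.ndarray, y: np.ndarray, z: np.ndarray, rng, n_perm: int) -> np.ndarray:
    """Partial correlations of ``n_perm`` entry-shuffles of x against fixed y, z."""
    P = x.size
    X = np.tile(x, (n_perm, 1))
    X = rng.permuted(X, axis=1)
    Xc = X - x.mean()
    sx = x.std()
    yc = (y - y.mean()) / (y.std() * P)
    zc = (z - z.mean()) / (z.std() * P)
    r_xy = (Xc @ yc) / sx
    r_xz = (Xc @ zc) / sx
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    denom = np.where(denom > 0, denom, np.nan)
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def _threshold(null_values: np.ndarray, level: float = 0.95) -> float:
    """Value that ``level`` of the sorted null lies at or below (rank
    ceil(level * n), e.g. the 950th of 1000)."""
    srt = np.sort(null_values)
    k = int(np.ceil(level * srt.size)) - 1
    return float(srt[k])


def flow_curves(datasets, front="peri_frontal", back="peri_occipital",
                subsets=None, contrast: str = "category",
                past_window_ms=PAST_WINDOW_MS, n_perm: int = 1000, seed: int = 0,
                perm_bins=None) -> FlowResult:
    """FF(t), FB(t), their difference, and permutation significance.

    ``subsets`` is a list of trial-index arrays defining the stimulus sets of
    the similarity matrices (default: the 12 single-variation-condition
    subsets for category flow); curves are computed per subject and subset,
    then averaged.  ``perm_bins`` restricts the permutation null to selected
    time bins (ms values); elsewhere thresholds are NaN.
    """
    if isinstance(datasets, EpochedDataset):
        datasets = [datasets]
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    time_ms = datasets[0].time_ms
    if subsets is None:
        subsets = category_flow_subsets(datasets[0].trials)

    rng = np.random.default_rng(seed)
    units = []     # (front_t, back_t, front_past, back_past) per subject x subset
    for ds in datasets:
        if not np.allclose(ds.time_ms, time_ms):
            raise ValueError("datasets have mismatched time axes")
        fch = ds.channel_indices(resolve_electrodes(front, ds.channel_names))
        bch = ds.channel_indices(resolve_electrodes(back, ds.channel_names))
        for subset in subsets:
            fv = _sm_vec_series(ds, fch, np.asarray(subset, int))
            bv = _sm_vec_series(ds, bch, np.asarray(subset, int))
            units.append((fv, bv, _past_series(fv, time_ms, past_window_ms),
                          _past_series(bv, time_ms, past_window_ms)))

    n_bins = time_ms.size
    ff = np.full(n_bins, np.nan)
    fb = np.full(n_bins, np.nan)
    ff_thr = np.full(n_bins, np.nan)
    fb_thr = np.full(n_bins, np.nan)
    d_hi = np.full(n_bins, np.nan)
    d_lo = np.full(n_bins, np.nan)
    if perm_bins is None:
        perm_sel = np.ones(n_bins, dtype=bool)
    else:
        perm_sel = np.zeros(n_bins, dtype=bool)
        for t in perm_bins:
            perm_sel[int(np.argmin(np.abs(time_ms - t)))] = True

    for j in range(n_bins):
        if np.isnan(units[0][2][j]).any():
            continue   # past window not available
        ff_vals, fb_vals = [], []
        ff_null = np.zeros(n_perm)
        fb_null = np.zeros(n_perm)
        for fv, bv, fp, bp in units:
            ff_vals.append(_pc_scalar(fv[j], bp[j], fp[j]))
            fb_vals.append(_pc_scalar(bv[j], fp[j], bp[j]))
            if perm_sel[j]:
                ff_null += _pc_perm(fv[j], bp[j], fp[j], rng, n_perm)
                fb_null += _pc_perm(bv[j], fp[j], bp[j], rng, n_perm)
        ff[j] = np.nanmean(ff_vals)
        fb[j] = np.nanmean(fb_vals)
        if perm_sel[j]:
            ff_null /= len(units)
            fb_null /= len(units)
            ff_thr[j] = _threshold(ff_null)
            fb_thr[j] = _threshold(fb_null)
            d_null = ff_null - fb_null
            d_hi[j] = _threshold(d_null, 0.95)
            d_lo[j] = _threshold(d_null, 0.05)

    with np.errstate(invalid="ignore"):
        sig_ff = np.where(np.isnan(ff_thr), False, ff > ff_thr)
        sig_fb = np.where(np.isnan(fb_thr), False, fb > fb_thr)
    return FlowResult(
        time_ms=time_ms, ff=ff, fb=fb, diff=ff - fb,
        ff_threshold=ff_thr, fb_threshold=fb_thr,
        diff_upper=d_hi, diff_lower=d_lo,
        significant_ff=sig_ff.astype(bool), significant_fb=sig_fb.astype(bool),
        contrast=contrast, past_window_ms=tuple(past_window_ms), n_perm=n_perm,
    )
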