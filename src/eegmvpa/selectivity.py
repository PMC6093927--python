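"""Information selectivity: do the same electrodes carry different aspects?

An *aspect* is one decodable distinction, one-vs-rest: each category against
the other three (averaged pairwise), and each level of each variation type
against the other two levels -- 4 + 4x3 = 16 aspects.  For every aspect a
31-entry vector of per-electrode (univariate) d' values is computed at a
time bin; the information-selectivity matrix holds the pairwise Pearson
correlations of those vectors, and the selectivity index is

    mean(within-dimension off-diagonal correlation)
  - mean(between-dimension correlation),

high when distinct electrode sets carry distinct information dimensions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .dataset import EpochedDataset
from .decode import (
    DEFAULT_BASELINE_MS,
    _baseline_bins,
    _univariate_dprime_bins,
    condition_mask,
)
from .design import CATEGORIES, N_LEVELS, VARIATION_TYPES

logger = logging.getLogger(__name__)

#: ordered aspect identifiers: (dimension, condition)
ASPECTS: tuple[tuple[str, object], ...] = tuple(
    [("category", c) for c in CATEGORIES]
    + [(vt, lv) for vt in VARIATION_TYPES for lv in range(1, N_LEVELS + 1)]
)


@dataclass
class AspectVector:
    dimension: str
    condition: object
    values: np.ndarray   # one d' per analysis electrode


@dataclass
class SelectivityMatrix:
    aspects: tuple[tuple[str, object], ...]
    corr: np.ndarray     # aspects x aspects Pearson correlations
    time_ms: float


@dataclass
class SelectivityIndexTrace:
    time_ms: np.ndarray
    values: np.ndarray   # (n_subjects, n_bins) or (n_bins,)

    @property
    def mean(self) -> np.ndarray:
        return self.values if self.values.ndim == 1 else self.values.mean(0)

    @property
    def sem(self) -> np.ndarray:
        if self.values.ndim == 1:
            return np.zeros_like(self.values)
        return self.values.std(0, ddof=1) / np.sqrt(self.values.shape[0])


def _aspect_curves(dataset: EpochedDataset, baseline: bool = False,
                   baseline_window=DEFAULT_BASELINE_MS) -> np.ndarray:
    """Per-electrode d' timecourses for all 16 aspects: (aspects, ch, bins).

    Aspects are one-vs-rest via averaged pairwise d' (pooled trials).
    """
    X = dataset.voltages
    trials = dataset.trials
    idx = {}
    for dim, cond in ASPECTS:
        idx[(dim, cond)] = np.flatnonzero(condition_mask(trials, dim, cond))
    # cache pairwise curves so each unordered pair is computed once
    pair_cache: dict[tuple, np.ndarray] = {}

    def pair_curve(dim, a, b):
        key = (dim, a, b) if (str(a), ) <= (str(b),) else (dim, b, a)
        if key not in pair_cache:
            pair_cache[key] = _univariate_dprime_bins(X, idx[(dim, key[1])], idx[(dim, key[2])])
        return pair_cache[key]

    out = np.empty((len(ASPECTS), dataset.n_channels, dataset.n_timebins))
    for k, (dim, cond) in enumerate(ASPECTS):
        if dim == "category":
            others = [c for c in CATEGORIES if c != cond]
        else:
            others = [lv for lv in range(1, N_LEVELS + 1) if lv != cond]
        out[k] = np.mean([pair_curve(dim, cond, o) for o in others], axis=0)
    if baseline:
        sel = _baseline_bins(dataset.time_ms, baseline_window)
        out = out - out[:, :, sel].mean(axis=2, keepdims=True)
    return out


def aspect_vectors(dataset: EpochedDataset, time_ms: float, baseline: bool = False,
                   baseline_window=DEFAULT_BASELINE_MS) -> list[AspectVector]:
    """The 16 per-electrode decodability vectors at one time bin."""
    j = dataset.bin_index(time_ms)
    curves = _aspect_curves(dataset, baseline, baseline_window)
    return [
        AspectVector(dim, cond, curves[k, :, j])
        for k, (dim, cond) in enumerate(ASPECTS)
    ]


def selectivity_matrix(vectors: list[AspectVector], time_ms: float = np.nan) -> SelectivityMatrix:
    """Pairwise Pearson correlations of per-electrode decodability vectors.

    Zero-variance vectors get NaN correlations (logged); the diagonal is 1.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two aspect vectors")
    lengths = {v.values.shape[0] for v in vectors}
    if len(lengths) != 1:
        raise ValueError("aspect vectors have unequal lengths")
    V = np.vstack([v.values for v in vectors]).astype(float)
    sd = V.std(axis=1)
    corr = np.full((len(vectors), len(vectors)), np.nan)
    ok = sd > 0
    if not ok.all():
        logger.warning("%d zero-variance aspect vectors: correlations set NaN", int((~ok).sum()))
    if ok.any():
        corr_ok = np.corrcoef(V[ok])
        corr[np.ix_(ok, ok)] = corr_ok
    np.fill_diagonal(corr, 1.0)
    return SelectivityMatrix(
        aspects=tuple((v.dimension, v.condition) for v in vectors),
        corr=corr,
        time_ms=time_ms,
    )


def selectivity_index(matrix: SelectivityMatrix) -> float:
    """Mean within-dimension off-diagonal correlation minus mean
    between-dimension correlation (diagonal excluded; NaNs dropped)."""
    dims = np.array([a[0] for a in matrix.aspects])
    n = len(dims)
    within, between = [], []
    n_missing = 0
    for i, j in itertools.combinations(range(n), 2):
        v = matrix.corr[i, j]
        if np.isnan(v):
            n_missing += 1
            continue
        (within if dims[i] == dims[j] else between).append(v)
    if n_missing:
        logger.warning("%d missing entries excluded from the selectivity index", n_missing)
    if not within or not between:
        raise ValueError("selectivity index needs both within- and between-dimension entries")
    return float(np.mean(within) - np.mean(between))


def _index_from_curves(curves: np.ndarray, j: int) -> float:
    V = curves[:, :, j]
    sd = V.std(axis=1)
    if np.any(sd == 0):
        vecs = [AspectVector(d, c, V[k]) for k, (d, c) in enumerate(ASPECTS)]
        return selectivity_index(selectivity_matrix(vecs))
    corr = np.corrcoef(V)
    dims = np.array([a[0] for a in ASPECTS])
    same = dims[:, None] == dims[None, :]
    triu = np.triu(np.ones_like(corr, dtype=bool), k=1)
    return float(corr[same & triu].mean() - corr[~same & triu].mean())


def selectivity_index_trace(datasets, baseline: bool = False,
                            baseline_window=DEFAULT_BASELINE_MS) -> SelectivityIndexTrace:
    """Time-resolved selectivity index, per subject."""
    if isinstance(datasets, EpochedDataset):
        datasets = [datasets]
    rows = []
    for ds in datasets:
        curves = _aspect_curves(ds, baseline, baseline_window)
        rows.append([_index_from_curves(curves, j) for j in range(ds.n_timebins)])
    values = np.asarray(rows)
    return SelectivityIndexTrace(
        time_ms=datasets[0].time_ms,
        values=values[0] if values.shape[0] == 1 else values,
    )
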