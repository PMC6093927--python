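"""Layer-wise decodability of arbitrary feature matrices.

The same projection d' used on electrode-space voltages applies unchanged
to per-layer feature matrices (stimuli x units), e.g. the outputs of a
hierarchical vision model.  A synthetic "layer cascade" generator produces
feature matrices with a configurable per-layer schedule of category and
variation separability, so the two-regime pattern (category and variation
decodability first rising together, then diverging) can be reproduced
without bundling any trained network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import dprime, pair_contrasts
from .design import VARIATION_TYPES, generate_design

#: representational dimensionalities of a 7-layer reference cascade
REFERENCE_LAYER_DIMS: tuple[int, ...] = (69987, 43264, 64896, 64896, 9216, 4096, 4096)


@dataclass
class LayerFeatures:
    layer_id: int
    features: np.ndarray     # (n_stimuli, n_units)
    labels: pd.DataFrame     # stimulus design rows aligned with axis 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.labels):
            raise ValueError("features and label table length mismatch")


def layer_dprime(layer: LayerFeatures, contrast, scheme: str = "pooled") -> float:
    """Projection d' between two conditions in one layer's feature space.

    Identical statistic to the electrode-space decoder (single code path via
    :func:`eegmvpa.decode.dprime`).  ``scheme="per_condition"`` stratifies
    category contrasts by variation condition and variation contrasts by
    object, averaging strata with >= 2 samples per cluster.
    """
    dimension, lev_a, lev_b = contrast
    labels = layer.labels
    if dimension == "category":
        mask_a = (labels["category"] == lev_a).to_numpy()
        mask_b = (labels["category"] == lev_b).to_numpy()
        strata_keys = ["variation_type", "variation_level"]
    elif dimension in VARIATION_TYPES:
        sel = (labels["variation_type"] == dimension).to_numpy()
        mask_a = sel & (labels["variation_level"] == lev_a).to_numpy()
        mask_b = sel & (labels["variation_level"] == lev_b).to_numpy()
        strata_keys = ["category", "exemplar"]
    else:
        raise ValueError(f"unknown dimension {dimension!r}")

    if scheme == "pooled":
        return dprime(layer.features[mask_a], layer.features[mask_b])
    if scheme != "per_condition":
        raise ValueError(f"unknown scheme {scheme!r}")
    vals = []
    for _, grp in labels.groupby(strata_keys, sort=True):
        rows = grp.index.to_numpy()
        ia = rows[mask_a[rows]]
        ib = rows[mask_b[rows]]
        if len(ia) < 2 or len(ib) < 2:
            continue
        vals.append(dprime(layer.features[ia], layer.features[ib]))
    if not vals:
        raise ValueError("all per-condition strata were skipped")
    return float(np.mean(vals))


def layer_profile(layers: list[LayerFeatures], dimension: str,
                  scheme: str = "pooled") -> np.ndarray:
    """Pair-averaged d' per layer for one information dimension."""
    pairs = pair_contrasts(dimension)
    return np.array([
        np.mean([layer_dprime(layer, p, scheme) for p in pairs]) for layer in layers
    ])


def mean_variation_profile(layers: list[LayerFeatures], scheme: str = "pooled") -> np.ndarray:
    """Average of the four variation-type profiles."""
    return np.mean([layer_profile(layers, vt, scheme) for vt in VARIATION_TYPES], axis=0)


def layer_sliding_correlation(category_profile, variation_profile,
                              window: int = 3) -> np.ndarray:
    """Pearson r over each run of ``window`` consecutive layers.

    Zero-variance windows yield NaN.  Returns one value per window
    (``n_layers - window + 1``).
    """
    x = np.asarray(category_profile, float)
    y = np.asarray(variation_profile, float)
    if x.shape != y.shape:
        raise ValueError("profiles have different lengths")
    if x.size < window:
        raise ValueError(f"need >= {window} layers")
    out = np.full(x.size - window + 1, np.nan)
    for k in range(out.size):
        xs, ys = x[k:k + window], y[k:k + window]
        if xs.std() == 0 or ys.std() == 0:
            continue
        out[k] = float(np.corrcoef(xs, ys)[0, 1])
    return out


def dimension_correlation(profile, layer_dims=REFERENCE_LAYER_DIMS) -> float:
    """Pearson r between per-layer decodability and layer dimensionality."""
    p = np.asarray(profile, float)
    d = np.asarray(layer_dims, float)
    if p.shape != d.shape:
        raise ValueError(f"profile length {p.size} != layer_dims length {d.size}")
    return float(np.corrcoef(p, d)[0, 1])


def synthetic_layer_cascade(category_separation, variation_separation,
                            n_units: int = 50, noise_sd: float = 1.0,
                            seed: int = 0, design: pd.DataFrame | None = None,
                            ) -> list[LayerFeatures]:
    """Generate feature matrices with planted per-layer separability.

    ``category_separation`` / ``variation_separation`` are per-layer scalars
    controlling the distance between condition centroids (in units of
    ``noise_sd``).  Each category and each variation level gets a fixed
    random unit direction in feature space; layer k places condition
    centroids at ``separation[k]`` along those directions and adds isotropic
    Gaussian noise per stimulus.
    """
    cat_sep = np.asarray(category_separation, float)
    var_sep = np.asarray(variation_separation, float)
    if cat_sep.shape != var_sep.shape:
        raise ValueError("separation schedules have different lengths")
    if design is None:
        design = generate_design()
    rng = np.random.default_rng(seed)
    cats = sorted(design["category"].unique())
    cat_dirs = {c: _unit(rng.standard_normal(n_units)) for c in cats}
    var_dirs = {
        (vt, lv): _unit(rng.standard_normal(n_units))
        for vt in VARIATION_TYPES for lv in sorted(design["variation_level"].unique())
    }
    layers = []
    for k in range(cat_sep.size):
        F = noise_sd * rng.standard_normal((len(design), n_units))
        for i, row in enumerate(design.itertuples(index=False)):
            F[i] += cat_sep[k] * noise_sd * cat_dirs[row.category]
            F[i] += var_sep[k] * noise_sd * var_dirs[(row.variation_type, row.variation_level)]
        layers.append(LayerFeatures(layer_id=k + 1, features=F, labels=design))
    return layers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
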