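"""Synthetic epoched-EEG generator with planted, parameterized effects.

The generator emulates the statistical structure the decoding analyses
assume: per-channel AR(1) Gaussian noise (optionally with a shared
across-channel component) sampled at 1 kHz, plus additive condition-locked
evoked transients -- a spatial weight pattern times a temporal Gaussian
bump -- for each :class:`EffectSpec`.  Raw 1 ms traces are then reduced with
a 5-sample non-overlapping moving average, yielding 5 ms bins (201 bins for
the default -200..+804 ms epoch).

An optional lagged copy of each effect, carried by a second spatial
pattern, plants a known cross-region propagation delay for the information
flow analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .dataset import EpochedDataset
from .design import (
    CHANNELS,
    PERI_FRONTAL,
    PERI_OCCIPITAL,
    VARIATION_TYPES,
    generate_design,
)

PATTERN_PRESETS = {
    "occipital": PERI_OCCIPITAL,
    "frontal": PERI_FRONTAL,
    "global": None,  # all channels
}


def spatial_pattern(pattern, channel_names=CHANNELS) -> np.ndarray:
    """Resolve a spatial pattern to a per-channel weight vector.

    ``pattern`` may be an array of weights (one per channel), a preset name
    (``"occipital"``, ``"frontal"``, ``"global"``: weight 1 on the group's
    channels, 0 elsewhere) or a ``{channel: weight}`` mapping.
    """
    n = len(channel_names)
    if isinstance(pattern, str):
        if pattern not in PATTERN_PRESETS:
            raise ValueError(f"unknown pattern preset {pattern!r}")
        group = PATTERN_PRESETS[pattern]
        w = np.ones(n) if group is None else np.array(
            [1.0 if c in group else 0.0 for c in channel_names]
        )
        return w
    if isinstance(pattern, dict):
        w = np.zeros(n)
        for ch, val in pattern.items():
            if ch not in channel_names:
                raise ValueError(f"pattern channel {ch!r} not in montage")
            w[channel_names.index(ch)] = val
        return w
    w = np.asarray(pattern, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"pattern has shape {w.shape}, expected ({n},)")
    return w


@dataclass(frozen=True)
class EffectSpec:
    """One planted condition-locked evoked transient.

    ``dimension`` is ``"category"`` or a variation type (``"size"``,
    ``"position"``, ``"pose"``, ``"lighting"``); ``level`` names the
    condition carrying the effect (a category name, or a 1-based variation
    level).  The temporal kernel is a Gaussian bump centered at ``onset_ms``
    with standard deviation ``width_ms``; ``amplitude`` scales the bump in
    microvolts at the peak-weight channel.  When ``lag_ms`` is set, a copy
    of the bump delayed by ``lag_ms`` is added on ``lag_pattern``.
    """

    dimension: str
    level: object
    spatial_pattern: object = "global"
    onset_ms: float = 150.0
    width_ms: float = 5.0
    amplitude: float = 5.0
    lag_ms: float | None = None
    lag_pattern: object = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if self.lag_ms is not None and self.lag_ms < 0:
            raise ValueError("lag_ms must be >= 0 when present")
        if self.dimension != "category" and self.dimension not in VARIATION_TYPES:
            raise ValueError(
                f"dimension must be 'category' or one of {VARIATION_TYPES}, got {self.dimension!r}"
            )


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration (defaults mirror the emulated recording)."""

    n_subjects: int = 10
    channel_names: tuple[str, ...] = CHANNELS
    sfreq_raw: float = 1000.0
    epoch_window: tuple[float, float] = (-200.0, 804.0)  # inclusive endpoints, ms
    noise_sd: float = 5.0       # AR(1) innovation sd, microvolts
    ar_coeff: float = 0.5
    shared_noise: float = 0.0   # fraction of innovation variance shared across channels
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in [0, 1)")
        if not 0.0 <= self.shared_noise < 1.0:
            raise ValueError("shared_noise must be in [0, 1)")
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def with_effects(self, *effects: EffectSpec) -> "SynthConfig":
        return replace(self, effects=tuple(effects))


def generate_trial_table(design: pd.DataFrame, subject_id: int, rng: np.random.Generator,
                         n_repetitions: int = 3) -> pd.DataFrame:
    """Three repetitions of every image, with a random presentation order.

    Rows are kept in design order (image-major); ``presentation_order`` is a
    permutation of 1..n_trials recording when each trial was shown.
    """
    reps = pd.concat(
        [design.assign(repetition=r) for r in range(1, n_repetitions + 1)],
        ignore_index=True,
    )
    reps = reps.sort_values(["image_id", "repetition"], ignore_index=True)
    reps["subject_id"] = subject_id
    reps["presentation_order"] = rng.permutation(len(reps)) + 1
    reps.insert(0, "trial_id", np.arange(1, len(reps) + 1))
    return reps


def bin_epochs(raw: np.ndarray, sfreq_raw: float = 1000.0, t_start_ms: float = -200.0,
               n_avg: int = 5, pad: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping ``n_avg``-sample moving average along the time axis.

    ``raw`` is ``(channels, raw_samples, trials)``.  Returns the binned
    array and the bin-center time axis (first raw-sample time of each bin
    plus half the bin span).  If the sample count is not divisible by
    ``n_avg``, raises unless ``pad=True``, which edge-pads the final bin.
    """
    raw = np.asarray(raw)
    n_ch, n_s, n_tr = raw.shape
    rem = n_s % n_avg
    if rem:
        if not pad:
            raise ValueError(
                f"{n_s} samples not divisible by {n_avg}; pass pad=True to edge-pad"
            )
        extra = n_avg - rem
        raw = np.concatenate([raw, np.repeat(raw[:, -1:, :], extra, axis=1)], axis=1)
        n_s = raw.shape[1]
    n_bins = n_s // n_avg
    binned = raw.reshape(n_ch, n_bins, n_avg, n_tr).mean(axis=2)
    dt = 1000.0 / sfreq_raw
    time_ms = t_start_ms + dt * (n_avg * np.arange(n_bins) + (n_avg - 1) / 2.0)
    return binned.astype(raw.dtype, copy=False), time_ms


def _effect_mask(effect: EffectSpec, trials: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    if effect.dimension == "category":
        if effect.level not in set(design["category"]):
            raise ValueError(f"effect level {effect.level!r} not a category in the design")
        return (trials["category"] == effect.level).to_numpy()
    levels = set(design.loc[design["variation_type"] == effect.dimension, "variation_level"])
    if effect.level not in levels:
        raise ValueError(
            f"effect level {effect.level!r} not a {effect.dimension} level in the design"
        )
    return (
        (trials["variation_type"] == effect.dimension)
        & (trials["variation_level"] == effect.level)
    ).to_numpy()


def generate_subject(design: pd.DataFrame, cfg: SynthConfig, subject_id: int) -> EpochedDataset:
    """Simulate one subject's epoched recording.

    Bit-identical output for identical ``(design, cfg, subject_id)``.
    """
    rng = np.random.default_rng([int(cfg.seed), int(subject_id)])
    trials = generate_trial_table(design, subject_id, rng)
    n_tr = len(trials)
    n_ch = cfg.n_channels

    dt = 1000.0 / cfg.sfreq_raw
    t0, t1 = cfg.epoch_window
    n_s = int(round((t1 - t0) / dt)) + 1
    t_raw = t0 + dt * np.arange(n_s)

    a = cfg.ar_coeff
    # burn-in so the AR(1) process is stationary by the epoch start
    burn = 0 if a == 0 else int(np.clip(np.ceil(np.log(1e-6) / np.log(a)), 8, 256))
    # time on the last (contiguous) axis keeps the recursive filter fast
    innov = rng.standard_normal((n_ch, n_tr, n_s + burn), dtype=np.float32)
    if cfg.shared_noise > 0:
        common = rng.standard_normal((1, n_tr, n_s + burn), dtype=np.float32)
        c = np.float32(np.sqrt(cfg.shared_noise))
        innov = np.sqrt(np.float32(1.0) - c * c) * innov + c * common
    innov *= np.float32(cfg.noise_sd)
    if a > 0:
        raw = lfilter(np.array([1.0], dtype=np.float32),
                      np.array([1.0, -a], dtype=np.float32), innov, axis=-1)
        raw = raw[:, :, burn:]
    else:
        raw = innov
    raw = raw.transpose(0, 2, 1)   # (channels, samples, trials) view

    for effect in cfg.effects:
        mask = _effect_mask(effect, trials, design)
        if not mask.any():
            continue
        w = spatial_pattern(effect.spatial_pattern, cfg.channel_names)
        kern = np.exp(-0.5 * ((t_raw - effect.onset_ms) / effect.width_ms) ** 2)
        bump = (effect.amplitude * w[:, None] * kern[None, :]).astype(np.float32)
        raw[:, :, mask] += bump[:, :, None]
        if effect.lag_ms is not None:
            w2 = spatial_pattern(
                effect.lag_pattern if effect.lag_pattern is not None else effect.spatial_pattern,
                cfg.channel_names,
            )
            kern2 = np.exp(
                -0.5 * ((t_raw - effect.onset_ms - effect.lag_ms) / effect.width_ms) ** 2
            )
            bump2 = (effect.amplitude * w2[:, None] * kern2[None, :]).astype(np.float32)
            raw[:, :, mask] += bump2[:, :, None]

    binned, time_ms = bin_epochs(raw, cfg.sfreq_raw, t0)
    return EpochedDataset(
        voltages=binned,
        time_ms=time_ms,
        channel_names=cfg.channel_names,
        trials=trials,
        subject_id=subject_id,
        sfreq_raw=cfg.sfreq_raw,
    )


def generate_group(cfg: SynthConfig, design: pd.DataFrame | None = None) -> list[EpochedDataset]:
    """Simulate ``cfg.n_subjects`` subjects (subject ids 1..n)."""
    if design is None:
        design = generate_design()
    return [generate_subject(design, cfg, sid) for sid in range(1, cfg.n_subjects + 1)]
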