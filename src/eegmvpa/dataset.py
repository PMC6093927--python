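"""Epoched EEG container and on-disk format.

An :class:`EpochedDataset` holds a ``channels x timebins x trials`` voltage
array (microvolts, float32), the time axis in milliseconds, the channel
names, and a trial table joining the presentation log with the stimulus
design (category / exemplar / variation labels per trial).

On disk a dataset is a directory with three files:

``voltages.f32``
    little-endian float32 binary, channel-major ``(channels, timebins, trials)``
``meta.json``
    channel names, time axis (ms), units, raw sampling rate, subject id
``trials.tsv``
    one row per trial: ``trial_id image_id category exemplar variation_type
    variation_level repetition subject_id presentation_order``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = (
    "trial_id", "image_id", "category", "exemplar", "variation_type",
    "variation_level", "repetition", "subject_id", "presentation_order",
)


@dataclass
class EpochedDataset:
    """Single-subject epoched voltages with trial labels."""

    voltages: np.ndarray          # (n_channels, n_timebins, n_trials) float32, microvolts
    time_ms: np.ndarray           # (n_timebins,) bin-center times
    channel_names: tuple[str, ...]
    trials: pd.DataFrame          # one row per trial, aligned with axis 2
    subject_id: int = 0
    sfreq_raw: float = 1000.0

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.voltages.ndim != 3:
            raise ValueError("voltages must be (channels, timebins, trials)")
        n_ch, n_t, n_tr = self.voltages.shape
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for {n_ch} channels"
            )
        if self.time_ms.shape != (n_t,):
            raise ValueError("time_ms length does not match timebin axis")
        dt = np.diff(self.time_ms)
        if n_t > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time_ms must be strictly increasing and uniformly spaced")
        if len(self.trials) != n_tr:
            raise ValueError(
                f"trial table has {len(self.trials)} rows but voltage array has {n_tr} trials"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_timebins(self) -> int:
        return self.voltages.shape[1]

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[2]

    @property
    def bin_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0]) if self.n_timebins > 1 else np.nan

    def channel_indices(self, names) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ValueError(f"channels not in dataset: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def bin_index(self, t_ms: float) -> int:
        """Index of the bin whose center is nearest ``t_ms`` (must be in range)."""
        if t_ms < self.time_ms[0] or t_ms > self.time_ms[-1]:
            raise ValueError(f"time {t_ms} ms outside epoch [{self.time_ms[0]}, {self.time_ms[-1]}]")
        return int(np.argmin(np.abs(self.time_ms - t_ms)))


def write_epochs(dataset: EpochedDataset, path) -> None:
    """Write a dataset directory (binary float32 array + JSON + TSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(dataset.voltages, dtype="<f4")
    arr.tofile(path / "voltages.f32")
    meta = {
        "shape": list(arr.shape),
        "dtype": "<f4",
        "order": "channel-major (channels, timebins, trials)",
        "units": "microvolts",
        "channel_names": list(dataset.channel_names),
        "time_ms": [float(t) for t in dataset.time_ms],
        "sfreq_raw": dataset.sfreq_raw,
        "subject_id": int(dataset.subject_id),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    dataset.trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path / "trials.tsv", sep="\t", index=False)


def read_epochs(path) -> EpochedDataset:
    """Read a dataset directory written by :func:`write_epochs`.

    Round-trips bit-exactly for the voltage array.  Raises ``ValueError``
    naming the offending field on any shape or metadata mismatch.
    """
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    for key in ("shape", "channel_names", "time_ms"):
        if key not in meta:
            raise ValueError(f"meta.json missing required field {key!r}")
    shape = tuple(meta["shape"])
    arr = np.fromfile(path / "voltages.f32", dtype="<f4")
    if arr.size != int(np.prod(shape)):
        raise ValueError(
            f"voltages.f32 has {arr.size} values, metadata shape {shape} expects {int(np.prod(shape))}"
        )
    arr = arr.reshape(shape)
    if len(meta["channel_names"]) != shape[0]:
        raise ValueError(
            f"channel_names: {len(meta['channel_names'])} names for {shape[0]} channels; "
            f"expected a 10-20 montage list such as {meta['channel_names'][:5]}..."
        )
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials.tsv missing columns: {missing}")
    if len(trials) != shape[2]:
        raise ValueError(
            f"trials.tsv: {len(trials)} rows but voltage array has {shape[2]} trials"
        )
    return EpochedDataset(
        voltages=arr,
        time_ms=np.asarray(meta["time_ms"], dtype=float),
        channel_names=tuple(meta["channel_names"]),
        trials=trials,
        subject_id=int(meta.get("subject_id", 0)),
        sfreq_raw=float(meta.get("sfreq_raw", 1000.0)),
    )
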