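"""Stimulus design and electrode montage.

The stimulus set is a fully crossed factorial: 4 object categories x 4
exemplars per category x 4 variation types (size, position, in-depth pose,
lighting) x 3 levels per variation, i.e. 192 unique images.  Each image
manipulates exactly one variation type, so the 16 objects (category x
exemplar) each appear under 12 variation conditions.
"""

from __future__ import annotations

import itertools

import pandas as pd

CATEGORIES: tuple[str, ...] = ("animal", "car", "face", "plane")
VARIATION_TYPES: tuple[str, ...] = ("size", "position", "pose", "lighting")
N_EXEMPLARS = 4
N_LEVELS = 3

#: 31 analysis channels of the 10-20 montage (reference electrode excluded).
CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AFZ",
    "F7", "F3", "FZ", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "CZ", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "PZ", "P4", "P8",
    "POZ", "O1", "OZ", "O2",
)

#: Posterior electrode group used for the "back" representational space.
PERI_OCCIPITAL: tuple[str, ...] = ("P3", "P4", "P7", "P8", "PZ", "POZ", "O1", "O2", "OZ")
#: Anterior electrode group used for the "front" representational space.
PERI_FRONTAL: tuple[str, ...] = ("F3", "F4", "F7", "F8", "FZ", "AFZ", "FP1", "FP2", "FPZ")

ELECTRODE_PRESETS: dict[str, tuple[str, ...]] = {
    "all": CHANNELS,
    "global": CHANNELS,
    "peri_occipital": PERI_OCCIPITAL,
    "peri_frontal": PERI_FRONTAL,
}


def resolve_electrodes(electrodes, channel_names=CHANNELS) -> tuple[str, ...]:
    """Resolve a preset name or explicit channel list against a montage."""
    if electrodes is None:
        return tuple(channel_names)
    if isinstance(electrodes, str):
        try:
            names = ELECTRODE_PRESETS[electrodes]
        except KeyError:
            raise ValueError(
                f"unknown electrode preset {electrodes!r}; "
                f"choose from {sorted(ELECTRODE_PRESETS)}"
            ) from None
    else:
        names = tuple(electrodes)
    missing = [n for n in names if n not in channel_names]
    if missing:
        raise ValueError(f"electrodes not in montage: {missing}")
    return tuple(names)


def generate_design() -> pd.DataFrame:
    """Enumerate the 192-image factorial design.

    Returns a DataFrame with columns ``image_id`` (1-based), ``category``,
    ``exemplar`` (1-4), ``variation_type`` and ``variation_level`` (1-3),
    ordered by (category, exemplar, variation_type, level).
    """
    rows = [
        (cat, ex, vt, lv)
        for cat, ex, vt, lv in itertools.product(
            CATEGORIES, range(1, N_EXEMPLARS + 1), VARIATION_TYPES, range(1, N_LEVELS + 1)
        )
    ]
    design = pd.DataFrame(rows, columns=["category", "exemplar", "variation_type", "variation_level"])
    design.insert(0, "image_id", range(1, len(design) + 1))
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
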