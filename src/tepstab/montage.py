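"""Standard 64-channel 10-10 montage: labels and schematic 2-D scalp positions.

Only channel identity and relative scalp geometry are needed (for spatial
topographies and distance-dependent noise), so positions are laid out on a
schematic grid derived from the 10-10 naming convention rather than digitised
head coordinates: the row letter maps to an anterior-posterior coordinate and
the site number to a left-right coordinate (odd = left, even = right,
z = midline). One grid unit roughly corresponds to one 10-10 step.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MONTAGE_64", "channel_positions", "channel_distance"]

# Anterior (+y) to posterior (-y) row coordinate per 10-10 row prefix.
_ROW_Y = {
    "Fp": 4.0,
    "AF": 3.0,
    "F": 2.0,
    "FT": 1.0,
    "FC": 1.0,
    "T": 0.0,
    "C": 0.0,
    "TP": -1.0,
    "CP": -1.0,
    "P": -2.0,
    "PO": -3.0,
    "O": -4.0,
}

MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


def _parse_label(label: str) -> tuple[str, str]:
    """Split a 10-10 label into (row prefix, site suffix)."""
    i = len(label)
    while i > 0 and (label[i - 1].isdigit() or label[i - 1] == "z"):
        i -= 1
    prefix, suffix = label[:i], label[i:]
    if prefix not in _ROW_Y or not suffix:
        raise ValueError(f"cannot parse 10-10 channel label {label!r}")
    return prefix, suffix


def _position(label: str) -> tuple[float, float]:
    prefix, suffix = _parse_label(label)
    y = _ROW_Y[prefix]
    if suffix == "z":
        x = 0.0
    else:
        n = int(suffix)
        # odd numbers grow leftward, even numbers rightward
        x = -((n + 1) // 2) if n % 2 else (n // 2)
    return float(x), y


def channel_positions(channels: tuple[str, ...] | list[str] = MONTAGE_64) -> np.ndarray:
    """Return an (n_channels, 2) array of schematic scalp positions."""
    return np.array([_position(c) for c in channels], dtype=float)


def channel_distance(channels, center: str) -> np.ndarray:
    """Euclidean grid distance of every channel from ``center``."""
    pos = channel_positions(tuple(channels))
    c = np.array(_position(center))
    return np.linalg.norm(pos - c, axis=1)
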