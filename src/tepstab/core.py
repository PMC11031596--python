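"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BlockMetadata", "EpochedEEG"]


@dataclass
class BlockMetadata:
    """Per-block subject and acquisition covariates.

    ``suprathreshold`` must be consistent with ``rmt_pct_mso``: stimulation is
    delivered above threshold exactly when the resting motor threshold is
    below 100% of maximum stimulator output.
    """

    subject_id: str
    age_years: float
    hemisphere: str  # "left" | "right"
    day: int  # 1 | 2
    block_order: int  # 1-based within day
    rmt_pct_mso: float
    asm_use: bool
    n_pulses: int
    block_id: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day}")
        if self.block_order < 1:
            raise ValueError("block_order is 1-based")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be positive")
        if not self.block_id:
            self.block_id = f"{self.subject_id}_d{self.day}_b{self.block_order}"

    @property
    def suprathreshold(self) -> bool:
        return self.rmt_pct_mso < 100.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["suprathreshold"] = self.suprathreshold
        return d


@dataclass
class EpochedEEG:
    """Pulse-locked epochs: ``data`` is trials x channels x samples in µV.

    ``t0`` is the time of the first sample in ms relative to pulse onset.
    ``bad_channels`` / ``bad_trials`` mark data to exclude from averaging and
    referencing; the samples themselves are never deleted.
    """

    data: np.ndarray
    fs: float
    t0: float
    channels: tuple[str, ...]
    bad_channels: frozenset[str] = frozenset()
    bad_trials: frozenset[int] = frozenset()
    meta: BlockMetadata | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel count mismatch")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.bad_channels = frozenset(self.bad_channels)
        self.bad_trials = frozenset(int(i) for i in self.bad_trials)
        if not self.bad_channels <= set(self.channels):
            raise ValueError("bad_channels must be a subset of channels")
        if self.bad_trials and (min(self.bad_trials) < 0 or max(self.bad_trials) >= self.n_trials):
            raise ValueError("bad_trials out of range")
        # single-pass check: any NaN/inf makes the sum non-finite (µV-scale
        # data cannot overflow a float64 sum)
        if not np.isfinite(self.data.sum()):
            raise ValueError("data contains non-finite values")

    # -- shape helpers -----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to pulse onset."""
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.fs

    @property
    def good_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in self.bad_channels)

    @property
    def good_channel_idx(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c not in self.bad_channels], dtype=int)

    @property
    def good_trials(self) -> np.ndarray:
        return np.array([i for i in range(self.n_trials) if i not in self.bad_trials], dtype=int)

    def replace(self, **kw) -> "EpochedEEG":
        """Return a copy with the given fields overridden (stages stay pure)."""
        out = dataclasses.replace(self, **kw)
        out.extras = dict(self.extras, **kw.get("extras", {}))
        return out

    def select_trials(self, idx) -> "EpochedEEG":
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError("empty trial selection")
        if np.any(idx < 0) or np.any(idx >= self.n_trials):
            raise ValueError("trial selection out of range")
        remap = {int(old): new for new, old in enumerate(idx)}
        bad = frozenset(remap[i] for i in self.bad_trials if i in remap)
        return self.replace(data=self.data[idx].copy(), bad_trials=bad)
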