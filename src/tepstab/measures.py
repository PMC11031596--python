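"""Outcome waveforms: trial-averaged potentials, the 5-channel local average
over the stimulated motor cortex, the all-channel global mean field amplitude,
and early/late time-window slicing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EpochedEEG

__all__ = [
    "TEP",
    "ScalarWaveform",
    "AnalysisConfig",
    "average_tep",
    "local_tep",
    "gmfa",
    "window_slice",
]

LEFT_CHANNELS = ("C3", "C1", "C5", "FC3", "CP3")
RIGHT_CHANNELS = ("C4", "C2", "C6", "FC4", "CP4")


@dataclass
class AnalysisConfig:
    """Stability-analysis constants.

    The early window is half-open [15, 80) ms and the late window closed
    [80, 350] ms so that the shared 80 ms boundary is counted once.
    """

    ccc_threshold: float = 0.8
    start_pulses: int = 10
    step_pulses: int = 5
    early_window: tuple[float, float] = (15.0, 80.0)
    late_window: tuple[float, float] = (80.0, 350.0)
    left_channels: tuple[str, ...] = LEFT_CHANNELS
    right_channels: tuple[str, ...] = RIGHT_CHANNELS

    def __post_init__(self) -> None:
        if not -1.0 <= self.ccc_threshold <= 1.0:
            raise ValueError("ccc_threshold must be in [-1, 1]")
        if self.start_pulses < 2 or self.step_pulses < 1:
            raise ValueError("invalid pulse grid parameters")
        if len(self.left_channels) != 5 or len(self.right_channels) != 5:
            raise ValueError("hemisphere channel sets must have 5 channels")
        if self.early_window[1] != self.late_window[0]:
            raise ValueError("early and late windows must share their boundary")

    def window(self, name: str) -> tuple[float, float]:
        try:
            return {"early": self.early_window, "late": self.late_window}[name]
        except KeyError:
            raise ValueError(f"unknown window {name!r}") from None

    def hemisphere_channels(self, hemisphere: str) -> tuple[str, ...]:
        try:
            return {"left": self.left_channels, "right": self.right_channels}[hemisphere]
        except KeyError:
            raise ValueError(f"unknown hemisphere {hemisphere!r}") from None


@dataclass
class TEP:
    """Trial-averaged evoked potential: channels x samples, µV."""

    data: np.ndarray
    fs: float
    t0: float
    channels: tuple[str, ...]
    bad_channels: frozenset[str] = frozenset()
    n_pulses_used: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples")
        if self.n_pulses_used < 1:
            raise ValueError("n_pulses_used must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) * 1000.0 / self.fs

    @property
    def good_channel_idx(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c not in self.bad_channels], dtype=int)


@dataclass
class ScalarWaveform:
    """Single summary waveform: ``kind`` is ``local`` (signed µV) or ``gmfa``
    (nonnegative µV)."""

    values: np.ndarray
    fs: float
    t0: float
    kind: str
    hemisphere: str | None = None
    channels_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.kind not in ("local", "gmfa"):
            raise ValueError("kind must be 'local' or 'gmfa'")
        if self.kind == "gmfa" and np.any(self.values < -1e-12):
            raise ValueError("gmfa waveform must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * 1000.0 / self.fs


def average_tep(ep: EpochedEEG, pulses=None) -> TEP:
    """Arithmetic mean over the requested pulses, skipping bad trials.

    ``pulses=None`` averages every non-bad trial.
    """
    if pulses is None:
        idx = ep.good_trials
    else:
        idx = np.array([int(i) for i in pulses if int(i) not in ep.bad_trials], dtype=int)
    if idx.size == 0:
        raise ValueError("no usable pulses to average")
    return TEP(
        data=ep.data[idx].mean(axis=0),
        fs=ep.fs,
        t0=ep.t0,
        channels=ep.channels,
        bad_channels=ep.bad_channels,
        n_pulses_used=int(idx.size),
        provenance={"pulses": idx.tolist()},
    )


def local_tep(tep: TEP, hemisphere: str, cfg: AnalysisConfig | None = None) -> ScalarWaveform:
    """Mean over the available good channels of the hemisphere's 5-channel set."""
    cfg = cfg or AnalysisConfig()
    wanted = cfg.hemisphere_channels(hemisphere)
    avail = [c for c in wanted if c in tep.channels and c not in tep.bad_channels]
    if not avail:
        raise ValueError(f"no usable {hemisphere}-hemisphere channels among {wanted}")
    rows = [tep.channels.index(c) for c in avail]
    return ScalarWaveform(
        values=tep.data[rows].mean(axis=0),
        fs=tep.fs,
        t0=tep.t0,
        kind="local",
        hemisphere=hemisphere,
        channels_used=tuple(avail),
    )


def gmfa(tep: TEP) -> ScalarWaveform:
    """Global mean field amplitude over good channels.

    GMFA(t) = sqrt( sum_k (V_k(t) - Vbar(t))^2 / K ), the population spatial
    standard deviation across the K good channels; invariant under common
    average re-referencing.
    """
    idx = tep.good_channel_idx
    if idx.size < 2:
        raise ValueError("gmfa needs at least 2 good channels")
    v = tep.data[idx]
    return ScalarWaveform(
        values=v.std(axis=0, ddof=0),
        fs=tep.fs,
        t0=tep.t0,
        kind="gmfa",
        channels_used=tuple(tep.channels[i] for i in idx),
    )


def window_slice(w: ScalarWaveform, window: str, cfg: AnalysisConfig | None = None) -> ScalarWaveform:
    """Slice to the early ([15, 80) ms) or late ([80, 350] ms) analysis window."""
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.window(window)
    t = w.times
    eps = 1e-9
    if window == "early":
        m = (t >= lo - eps) & (t < hi - eps)
    else:
        m = (t >= lo - eps) & (t <= hi + eps)
    if not np.any(m):
        raise ValueError(f"{window} window {lo}-{hi} ms outside waveform span")
    if t[0] > lo + eps or t[-1] < hi - eps:
        raise ValueError(f"waveform span {t[0]:.1f}..{t[-1]:.1f} ms does not cover {lo}-{hi} ms")
    i = np.flatnonzero(m)
    return ScalarWaveform(
        values=w.values[i].copy(),
        fs=w.fs,
        t0=float(t[i[0]]),
        kind=w.kind,
        hemisphere=w.hemisphere,
        channels_used=w.channels_used,
    )
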