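"""Waveform stability: concordance of candidate averages with the
gold-standard all-pulse average, and the persistence-checked minimum number
of pulses (MNP).

A candidate average over the first ``n`` pulses (or a seeded random subset)
is compared against the gold standard with Lin's concordance correlation
coefficient over a fixed analysis window. The MNP is the smallest grid count
from which the concordance stays above threshold for every larger count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng

from .core import EpochedEEG
from .measures import AnalysisConfig, ScalarWaveform, average_tep, gmfa, local_tep, window_slice
from .preprocess import PreprocConfig, preprocess_block

__all__ = [
    "StabilityCurve",
    "MNPResult",
    "ccc",
    "pulse_grid",
    "stability_curve",
    "block_stability",
    "mnp",
    "compare_tep_pair",
]

log = logging.getLogger(__name__)

MEASURES = ("local", "gmfa")
WINDOWS = ("early", "late")


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    with population (1/n) moments. Unlike Pearson correlation it penalises
    scale and location differences; 1 only for exact agreement. If both
    series are constant the value is degenerate: 1 for equal constants, 0
    otherwise (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("ccc needs two equal-length 1-D series with >= 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ccc inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    if vx == 0.0 and vy == 0.0:
        log.warning("ccc of two constant series: degenerate case")
        return 1.0 if mx == my else 0.0
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


@dataclass
class StabilityCurve:
    """One concordance-vs-pulse-count curve for a (measure, window, mode)."""

    pulse_grid: np.ndarray
    ccc_values: np.ndarray
    measure: str
    window: str
    mode: str  # consecutive | random
    preprocess_mode: str  # per_subset | subset_only
    block_id: str = ""

    def __post_init__(self) -> None:
        self.pulse_grid = np.asarray(self.pulse_grid, dtype=int)
        self.ccc_values = np.asarray(self.ccc_values, dtype=float)
        if self.pulse_grid.size != self.ccc_values.size or self.pulse_grid.size == 0:
            raise ValueError("grid and ccc arrays must be equal-length, non-empty")
        if np.any(np.diff(self.pulse_grid) <= 0):
            raise ValueError("pulse grid must be strictly increasing")
        if np.any(self.ccc_values < -1 - 1e-9) or np.any(self.ccc_values > 1 + 1e-9):
            raise ValueError("ccc values must lie in [-1, 1]")


@dataclass
class MNPResult:
    """Persistence-checked minimum number of pulses for one curve."""

    mnp: int
    attained: bool
    threshold: float = 0.8
    persistence_verified: bool = True
    curve: StabilityCurve | None = field(default=None, repr=False)


def pulse_grid(n_total: int, cfg: AnalysisConfig) -> np.ndarray:
    """Counts start, start+step, ... plus the full count as final point."""
    if n_total < cfg.start_pulses:
        raise ValueError(f"block has {n_total} pulses; need at least {cfg.start_pulses}")
    grid = list(range(cfg.start_pulses, n_total + 1, cfg.step_pulses))
    if grid[-1] != n_total:
        grid.append(n_total)  # grid terminates at the usable pulse count
    return np.array(grid, dtype=int)


def mnp(curve: StabilityCurve, cfg: AnalysisConfig | None = None) -> MNPResult:
    """Smallest grid count from which every CCC strictly exceeds threshold.

    "Surpassed" means strictly greater than the threshold, and a count only
    qualifies when all larger counts qualify too (no local-minimum escapes).
    ``attained=False`` signals that no such count exists.
    """
    cfg = cfg or AnalysisConfig()
    ok = curve.ccc_values > cfg.ccc_threshold
    idx = None
    for i in range(ok.size - 1, -1, -1):
        if not ok[i]:
            break
        idx = i
    if idx is None:
        return MNPResult(mnp=int(curve.pulse_grid[-1]), attained=False,
                         threshold=cfg.ccc_threshold, curve=curve)
    return MNPResult(mnp=int(curve.pulse_grid[idx]), attained=True,
                     threshold=cfg.ccc_threshold, curve=curve)


# ---------------------------------------------------------------------------


def _subsets(n_total: int, grid: np.ndarray, mode: str, seed: int | None) -> list[np.ndarray]:
    """Nested pulse subsets per grid count: leading runs (consecutive) or a
    seeded nested random ordering (random; each larger subset contains the
    smaller, mirroring iterative addition of pulses)."""
    if mode == "consecutive":
        order = np.arange(n_total)
    elif mode == "random":
        order = default_rng(seed).permutation(n_total)
    else:
        raise ValueError("mode must be 'consecutive' or 'random'")
    return [np.sort(order[:n]) for n in grid]


def _incremental_averages(gold_ep: EpochedEEG, grid: np.ndarray, subsets, final=None):
    """Yield candidate sub-averages of the preprocessed block, one per grid
    count, via a single incremental pass (subsets are nested by construction).

    Matches averaging the subset directly up to float summation order; the
    final grid point yields ``final`` (the gold average itself) so the
    closing concordance is exactly 1.
    """
    from .measures import TEP

    order = np.concatenate([subsets[0]] + [
        np.setdiff1d(b, a, assume_unique=True) for a, b in zip(subsets, subsets[1:])
    ])
    bad = gold_ep.bad_trials
    acc = np.zeros(gold_ep.data.shape[1:])
    count = 0
    pos = 0
    for i, n in enumerate(grid):
        while pos < n:
            tr = int(order[pos])
            if tr not in bad:
                acc += gold_ep.data[tr]
                count += 1
            pos += 1
        if count == 0:
            raise ValueError(f"first {n} pulses are all rejected trials")
        if final is not None and i == len(grid) - 1:
            yield final
            return
        yield TEP(
            data=acc / count,
            fs=gold_ep.fs,
            t0=gold_ep.t0,
            channels=gold_ep.channels,
            bad_channels=gold_ep.bad_channels,
            n_pulses_used=count,
            provenance={"pulses_delivered": int(n), "pulses_retained": count},
        )


def _measure_waveform(tep, measure: str, hemisphere: str, cfg: AnalysisConfig) -> ScalarWaveform:
    if measure == "local":
        return local_tep(tep, hemisphere, cfg)
    if measure == "gmfa":
        return gmfa(tep)
    raise ValueError(f"unknown measure {measure!r}")


def block_stability(
    block_raw: EpochedEEG,
    cfg: AnalysisConfig | None = None,
    pp: PreprocConfig | None = None,
    mode: str = "consecutive",
    seed: int | None = None,
) -> dict[tuple[str, str], StabilityCurve]:
    """Compute all four stability curves (measure x window) for one block.

    The gold standard is the average of all pulses after full preprocessing.
    Candidates use the first ``n`` pulses (consecutive) or seeded nested
    random subsets. With ``pp.mode == 'per_subset'`` each subset is
    preprocessed independently from the raw data (mimicking a shorter
    experiment); with ``'subset_only'`` candidates are sub-averages of the
    gold-preprocessed block, which guarantees CCC = 1 at the final count.
    Preprocessing is shared across measures and windows, which is why curves
    come in one batch.
    """
    cfg = cfg or AnalysisConfig()
    pp = pp or PreprocConfig()
    if block_raw.meta is None:
        raise ValueError("block needs metadata (hemisphere) for the local measure")
    hemi = block_raw.meta.hemisphere

    gold_ep = preprocess_block(block_raw, pp, None)
    gold_tep = average_tep(gold_ep, None)
    grid = pulse_grid(block_raw.n_trials, cfg)
    subsets = _subsets(block_raw.n_trials, grid, mode, seed)

    gold_w = {
        (m, w): window_slice(_measure_waveform(gold_tep, m, hemi, cfg), w, cfg)
        for m in MEASURES
        for w in WINDOWS
    }

    curves: dict[tuple[str, str], list[float]] = {k: [] for k in gold_w}
    if pp.mode == "subset_only":
        candidates = _incremental_averages(gold_ep, grid, subsets, final=gold_tep)
    else:
        candidates = (
            average_tep(preprocess_block(block_raw, pp, sub), None) for sub in subsets
        )
    for tep_n in candidates:
        for m in MEASURES:
            cand = _measure_waveform(tep_n, m, hemi, cfg)
            for w in WINDOWS:
                curves[(m, w)].append(ccc(window_slice(cand, w, cfg).values, gold_w[(m, w)].values))

    bid = block_raw.meta.block_id
    return {
        (m, w): StabilityCurve(grid, np.array(curves[(m, w)]), m, w, mode, pp.mode, bid)
        for m in MEASURES
        for w in WINDOWS
    }


def stability_curve(
    block_raw: EpochedEEG,
    measure: str,
    window: str,
    cfg: AnalysisConfig | None = None,
    pp: PreprocConfig | None = None,
    mode: str = "consecutive",
    seed: int | None = None,
) -> StabilityCurve:
    """Single-curve convenience wrapper around :func:`block_stability`."""
    if measure not in MEASURES or window not in WINDOWS:
        raise ValueError(f"unknown measure/window {measure!r}/{window!r}")
    return block_stability(block_raw, cfg, pp, mode, seed)[(measure, window)]


def compare_tep_pair(
    w1: ScalarWaveform, w2: ScalarWaveform, cfg: AnalysisConfig | None = None
) -> tuple[float, float]:
    """CCC between two summary waveforms over the early and late windows,
    e.g. outputs of two preprocessing pipelines or with/without trial
    rejection."""
    cfg = cfg or AnalysisConfig()
    if w1.fs != w2.fs or abs(w1.t0 - w2.t0) > 1e-9 or w1.values.size != w2.values.size:
        raise ValueError("waveforms must share sampling rate, onset and length")
    if w1.kind != w2.kind:
        raise ValueError("waveforms must be of the same kind")
    return tuple(
        ccc(window_slice(w1, w, cfg).values, window_slice(w2, w, cfg).values)
        for w in WINDOWS
    )
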