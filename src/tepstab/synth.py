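"""Synthetic TMS-EEG block and cohort generation with known ground truth.

A generated block is an exact sum of independent components

    data = evoked + background + line + pulse_artifact + muscle + movement

each drawn from its own seeded random stream, so disabling one component
(e.g. ``noise_sd=0``) leaves every other component bit-identical. The
noise-free evoked part, the per-trial gain factors and the indices of
movement-contaminated trials are recorded in ``EpochedEEG.extras`` for use as
test oracles.

Background EEG is 1/f-shaped Gaussian noise, band-limited to 0.5-200 Hz and
normalised so that the configured ``noise_sd`` is the time-domain standard
deviation on channels at the stimulation site; channels further away receive
up to ``distal_noise_gain`` times that (local averages over the stimulation
site are then cleaner than all-channel summaries, by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng

from .core import BlockMetadata, EpochedEEG
from .montage import MONTAGE_64, channel_distance

__all__ = [
    "PeakSpec",
    "SyntheticConfig",
    "CohortConfig",
    "default_peaks",
    "generate_block",
    "generate_cohort",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian evoked component: a deflection of ``amplitude_uv`` (signed,
    negative for N-peaks) peaking at ``latency_ms`` with temporal FWHM
    ``width_ms``, spatially centred on ``topo_center`` and decaying over scalp
    distance with Gaussian scale ``topo_spread`` (montage grid units)."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float
    topo_center: str = "C3"
    topo_spread: float = 2.0

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("peak width must be positive")
        if self.topo_spread <= 0:
            raise ValueError("topo_spread must be positive")
        if self.topo_center not in MONTAGE_64:
            raise ValueError(f"{self.topo_center!r} is not a montage channel")


def default_peaks(hemisphere: str = "left", amp_scale: float = 1.0) -> tuple[PeakSpec, ...]:
    """Default pediatric-style evoked template over the stimulated motor cortex.

    Early deflections near 30 and 45 ms are small; the template is dominated
    by a large lateralised negativity near 100 ms followed by a positive
    rebound near 180 ms. Magnitudes are free parameters of the generator.
    """
    c = {"left": "C3", "right": "C4"}[hemisphere]
    a = amp_scale
    return (
        PeakSpec(30.0, 3.0 * a, 18.0, c, 1.8),
        PeakSpec(45.0, -4.0 * a, 22.0, c, 1.8),
        PeakSpec(100.0, -12.0 * a, 55.0, c, 2.2),
        PeakSpec(180.0, 6.0 * a, 80.0, c, 2.5),
    )


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic block. Amplitudes in µV, times in ms."""

    n_trials: int = 100
    fs_raw: float = 2000.0
    epoch_span: tuple[float, float] = (-1000.0, 1500.0)
    peaks: tuple[PeakSpec, ...] | None = None  # None -> default_peaks(meta.hemisphere)
    noise_sd: float = 6.0
    noise_exponent: float = 1.0
    noise_band: tuple[float, float] = (0.5, 200.0)
    line_amp: float = 2.0
    line_freq: float = 60.0
    pulse_artifact_amp: float = 500.0
    muscle_artifact_amp: float = 25.0
    p_movement_trial: float = 0.0
    movement_amp_uv: float = 1000.0
    trial_amp_jitter_sd: float = 0.1
    distal_noise_gain: float = 1.5
    seed: int = 0
    channels: tuple[str, ...] = MONTAGE_64

    def __post_init__(self) -> None:
        if self.fs_raw < 2000.0:
            raise ValueError("fs_raw must be at least 2 kHz")
        if not 0.0 <= self.p_movement_trial <= 1.0:
            raise ValueError("p_movement_trial must be a probability")
        if self.epoch_span[0] >= self.epoch_span[1]:
            raise ValueError("epoch_span must be increasing")
        for name in ("noise_sd", "line_amp", "pulse_artifact_amp",
                     "muscle_artifact_amp", "movement_amp_uv",
                     "trial_amp_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.distal_noise_gain <= 0:
            raise ValueError("distal_noise_gain must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")

    def validated_peaks(self, hemisphere: str) -> tuple[PeakSpec, ...]:
        peaks = self.peaks if self.peaks is not None else default_peaks(hemisphere)
        lo, hi = self.epoch_span
        for p in peaks:
            if not lo <= p.latency_ms <= hi:
                raise ValueError(
                    f"peak at {p.latency_ms} ms outside epoch span {self.epoch_span}"
                )
        return peaks


@dataclass
class CohortConfig:
    """Parameters of a simulated cohort.

    ``schedule`` lists (day-1 blocks, day-2 blocks) per subject; ``None``
    gives every subject two 4-block days except the last three subjects, who
    attend a single day (mirroring incomplete pediatric attendance).
    ``age_snr_slope`` multiplies evoked amplitude by (1 + slope * years above
    the lower age bound); ``within_subject_corr`` sets the spread of a shared
    log-normal subject gain that induces correlation of downstream outcomes.
    """

    n_subjects: int = 18
    age_range: tuple[float, float] = (7.0, 13.0)
    schedule: tuple[tuple[int, int], ...] | None = None
    age_snr_slope: float = 0.0
    supra_amp_factor: float = 1.0
    asm_effect: float = 1.0
    within_subject_corr: float = 0.0
    p_asm: float = 0.44
    rmt_mean: float = 87.0
    rmt_sd: float = 14.0
    block: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for name in ("supra_amp_factor", "asm_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ValueError("within_subject_corr must be in [0, 1)")

    def resolved_schedule(self) -> tuple[tuple[int, int], ...]:
        if self.schedule is not None:
            if len(self.schedule) != self.n_subjects:
                raise ValueError("schedule length must equal n_subjects")
            return self.schedule
        n_single = min(3, max(0, self.n_subjects - 1))
        return tuple(
            (4, 0) if i >= self.n_subjects - n_single else (4, 4)
            for i in range(self.n_subjects)
        )


# ---------------------------------------------------------------------------
# component builders


def _topo_weights(channels, center: str, spread: float) -> np.ndarray:
    d = channel_distance(channels, center)
    return np.exp(-(d ** 2) / (2.0 * spread ** 2))


def _evoked_template(cfg: SyntheticConfig, hemisphere: str, t: np.ndarray) -> np.ndarray:
    """Noise-free evoked part, channels x samples."""
    out = np.zeros((len(cfg.channels), t.size))
    for p in cfg.validated_peaks(hemisphere):
        sigma = p.width_ms / 2.3548200450309493  # FWHM -> SD
        wave = p.amplitude_uv * np.exp(-((t - p.latency_ms) ** 2) / (2 * sigma ** 2))
        out += np.outer(_topo_weights(cfg.channels, p.topo_center, p.topo_spread), wave)
    return out


def _oneoverf_filter(cfg: SyntheticConfig, n_samples: int) -> np.ndarray:
    """rfft-domain gain normalised so filtered unit white noise has SD 1."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / cfg.fs_raw)
    h = np.zeros_like(freqs)
    lo, hi = cfg.noise_band
    band = (freqs >= lo) & (freqs <= min(hi, cfg.fs_raw / 2))
    h[band] = freqs[band] ** (-cfg.noise_exponent / 2.0)
    # Parseval: var of irfft(H * rfft(white)) = (H0^2 + Hny^2 + 2*sum mid) / N^2 * N
    w = np.full_like(h, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    var = float(np.sum(w * h ** 2)) / n_samples ** 2 * n_samples
    if var > 0:
        h /= np.sqrt(var)
    return h


def _background_noise(cfg: SyntheticConfig, rng, n_samples: int,
                      noise_gain: np.ndarray) -> np.ndarray:
    """1/f noise, trials x channels x samples, per-channel SD = noise_sd * gain."""
    if cfg.noise_sd == 0:
        return np.zeros((cfg.n_trials, len(cfg.channels), n_samples))
    h = _oneoverf_filter(cfg, n_samples)
    out = np.empty((cfg.n_trials, len(cfg.channels), n_samples))
    for i in range(cfg.n_trials):  # chunked to bound FFT memory
        white = rng.standard_normal((len(cfg.channels), n_samples))
        out[i] = np.fft.irfft(np.fft.rfft(white, axis=-1) * h, n=n_samples, axis=-1)
    out *= cfg.noise_sd * noise_gain[None, :, None]
    return out


def _pulse_artifact_shape(t: np.ndarray) -> np.ndarray:
    """Unit-peak decaying transient occupying -2..12 ms."""
    m = (t >= -2.0) & (t < 12.0)
    shape = np.zeros_like(t)
    shape[m] = np.exp(-(t[m] + 2.0) / 3.0)
    return shape


def _muscle_shape(t: np.ndarray) -> np.ndarray:
    """Unit-scale damped oscillation in the 11-30 ms muscle-artifact window."""
    m = (t >= 11.0) & (t <= 30.0)
    shape = np.zeros_like(t)
    tau = t[m] - 11.0
    shape[m] = np.sin(2 * np.pi * 0.09 * tau) * np.exp(-tau / 6.0)
    return shape


def generate_block(cfg: SyntheticConfig, meta: BlockMetadata) -> EpochedEEG:
    """Generate one synthetic pulse-locked block.

    Deterministic given ``cfg.seed``: identical config and metadata produce
    bit-identical arrays. Component ground truth lands in ``extras``:
    ``evoked`` (channels x samples template), ``trial_gains``,
    ``movement_trials`` and ``noise_sd``.
    """
    if meta.n_pulses != cfg.n_trials:
        meta = replace(meta, n_pulses=cfg.n_trials)
    n_ch = len(cfg.channels)
    n_s = int(round((cfg.epoch_span[1] - cfg.epoch_span[0]) * cfg.fs_raw / 1000.0)) + 1
    t = cfg.epoch_span[0] + np.arange(n_s) * 1000.0 / cfg.fs_raw

    ss = SeedSequence([int(cfg.seed) & 0xFFFFFFFF])
    rng_jit, rng_noise, rng_line, rng_art, rng_move = (default_rng(s) for s in ss.spawn(5))

    stim = {"left": "C3", "right": "C4"}[meta.hemisphere]
    dist = channel_distance(cfg.channels, stim)
    dmax = float(dist.max()) or 1.0
    noise_gain = 1.0 + (cfg.distal_noise_gain - 1.0) * dist / dmax
    proximal = np.exp(-(dist ** 2) / (2 * 2.5 ** 2))  # artifact topography

    evoked = _evoked_template(cfg, meta.hemisphere, t)
    gains = 1.0 + cfg.trial_amp_jitter_sd * rng_jit.standard_normal(cfg.n_trials)
    data = gains[:, None, None] * evoked[None, :, :]

    data += _background_noise(cfg, rng_noise, n_s, noise_gain)

    if cfg.line_amp > 0:
        phase = rng_line.uniform(0, 2 * np.pi, cfg.n_trials)
        line = np.sin(2 * np.pi * cfg.line_freq * t / 1000.0 + phase[:, None])
        data += cfg.line_amp * line[:, None, :]

    if cfg.pulse_artifact_amp > 0:
        shape = _pulse_artifact_shape(t)
        amp = cfg.pulse_artifact_amp * (1.0 + 0.1 * rng_art.standard_normal(cfg.n_trials))
        data += amp[:, None, None] * proximal[None, :, None] * shape[None, None, :]
    if cfg.muscle_artifact_amp > 0:
        shape = _muscle_shape(t)
        amp = cfg.muscle_artifact_amp * (1.0 + 0.3 * rng_art.standard_normal(cfg.n_trials))
        data += amp[:, None, None] * proximal[None, :, None] * shape[None, None, :]

    movement = np.array([], dtype=int)
    if cfg.p_movement_trial > 0 and cfg.movement_amp_uv > 0:
        mask = rng_move.random(cfg.n_trials) < cfg.p_movement_trial
        movement = np.flatnonzero(mask)
        for i in movement:
            f = rng_move.uniform(0.2, 0.5)  # Hz
            phi = rng_move.uniform(0, 2 * np.pi)
            sgn = rng_move.choice([-1.0, 1.0])
            sway = np.sin(2 * np.pi * f * t / 1000.0 + phi)
            sway *= cfg.movement_amp_uv / max(np.abs(sway).max(), 1e-12) * sgn
            data[i] += sway[None, :]

    return EpochedEEG(
        data=data,
        fs=cfg.fs_raw,
        t0=cfg.epoch_span[0],
        channels=cfg.channels,
        meta=meta,
        extras={
            "evoked": evoked,
            "trial_gains": gains,
            "movement_trials": movement,
            "noise_sd": cfg.noise_sd,
            "amp_scale": 1.0,
        },
    )


def generate_cohort(cfg: CohortConfig) -> list[tuple[SyntheticConfig, BlockMetadata]]:
    """Lay out a cohort: one (block config, metadata) pair per block.

    Blocks are returned as configs rather than materialised arrays so a
    cohort can be generated lazily; call :func:`generate_block` on each pair.
    Evoked amplitude is scaled by age, stimulation intensity, ASM use and a
    shared subject-level gain; per-block seeds are fanned out from
    ``cfg.seed`` with a counter scheme so any block is independently
    reproducible.
    """
    schedule = cfg.resolved_schedule()
    root = default_rng(SeedSequence([int(cfg.seed) & 0xFFFFFFFF, 0xC04027]))
    ages = root.uniform(*cfg.age_range, cfg.n_subjects)
    asm = root.random(cfg.n_subjects) < cfg.p_asm
    subj_gain = np.exp(
        np.sqrt(cfg.within_subject_corr) * 0.5 * root.standard_normal(cfg.n_subjects)
    )
    rmt = {}  # (subject, hemisphere) -> % MSO, stable across days
    out: list[tuple[SyntheticConfig, BlockMetadata]] = []
    for si, (d1, d2) in enumerate(schedule):
        sid = f"S{si + 1:02d}"
        start_left = bool(root.integers(0, 2))
        for hemi in ("left", "right"):
            rmt[(sid, hemi)] = float(min(np.round(root.normal(cfg.rmt_mean, cfg.rmt_sd)), 100.0))
        counter = 0
        for day, n_blocks in ((1, d1), (2, d2)):
            for order in range(1, n_blocks + 1):
                hemi = ("left", "right")[(order - 1 + (0 if start_left else 1)) % 2]
                r = rmt[(sid, hemi)]
                meta = BlockMetadata(
                    subject_id=sid,
                    age_years=float(ages[si]),
                    hemisphere=hemi,
                    day=day,
                    block_order=order,
                    rmt_pct_mso=r,
                    asm_use=bool(asm[si]),
                    n_pulses=cfg.block.n_trials,
                )
                scale = (
                    (1.0 + cfg.age_snr_slope * (ages[si] - cfg.age_range[0]))
                    * (cfg.supra_amp_factor if meta.suprathreshold else 1.0)
                    * (cfg.asm_effect if meta.asm_use else 1.0)
                    * subj_gain[si]
                )
                if scale <= 0:
                    raise ValueError("evoked amplitude scale must stay positive")
                peaks = cfg.block.peaks if cfg.block.peaks is not None else default_peaks(hemi)
                peaks = tuple(replace(p, amplitude_uv=p.amplitude_uv * scale) for p in peaks)
                block_seed = (int(cfg.seed) * 100003 + si * 1009 + counter) & 0x7FFFFFFF
                bc = replace(cfg.block, peaks=peaks, seed=block_seed)
                out.append((bc, meta))
                counter += 1
    return out


def materialise_cohort(cfg: CohortConfig) -> list[tuple[EpochedEEG, BlockMetadata]]:
    """Eagerly generate every block of a cohort (convenience for small runs)."""
    blocks = []
    for bc, meta in generate_cohort(cfg):
        ep = generate_block(bc, meta)
        ep.extras["amp_scale"] = abs(bc.peaks[0].amplitude_uv) / abs(
            (default_peaks(meta.hemisphere)[0]).amplitude_uv
        )
        blocks.append((ep, meta))
    return blocks
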