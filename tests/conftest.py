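import numpy as np
import pytest

from tepstab.core import BlockMetadata, EpochedEEG
from tepstab.preprocess import PreprocConfig, preprocess_block
from tepstab.synth import SyntheticConfig, generate_block

# 8 valid montage labels for cheap preprocessing-stage tests
CH8 = ("C3", "C1", "C5", "FC3", "CP3", "Cz", "FC1", "CP1")

SMALL_SPAN = (-600.0, 500.0)  # covers baseline (-500..-10) and late window (..350)


def make_meta(hemisphere="left", **kw) -> BlockMetadata:
    defaults = dict(
        subject_id="S01",
        age_years=10.0,
        hemisphere=hemisphere,
        day=1,
        block_order=1,
        rmt_pct_mso=85.0,
        asm_use=False,
        n_pulses=100,
    )
    defaults.update(kw)
    return BlockMetadata(**defaults)


def make_epochs(data, fs=2000.0, t0=-100.0, channels=None, **kw) -> EpochedEEG:
    data = np.asarray(data, dtype=float)
    channels = channels or CH8[: data.shape[1]]
    return EpochedEEG(data=data, fs=fs, t0=t0, channels=channels, **kw)


def quiet_config(**kw) -> SyntheticConfig:
    """All stochastic components off unless overridden."""
    defaults = dict(
        n_trials=20,
        epoch_span=SMALL_SPAN,
        noise_sd=0.0,
        line_amp=0.0,
        pulse_artifact_amp=0.0,
        muscle_artifact_amp=0.0,
        trial_amp_jitter_sd=0.0,
        p_movement_trial=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_block():
    """One realistic 100-trial block with generator defaults."""
    cfg = SyntheticConfig(n_trials=100, epoch_span=SMALL_SPAN, seed=11)
    return generate_block(cfg, make_meta(n_pulses=100))


@pytest.fixture(scope="session")
def gold_preprocessed(default_block):
    return preprocess_block(default_block, PreprocConfig(), None)
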