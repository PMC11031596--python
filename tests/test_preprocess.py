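import logging

import numpy as np
import pytest
from dataclasses import replace

from tepstab.core import EpochedEEG
from tepstab.preprocess import (
    DataQualityError,
    PreprocConfig,
    baseline_correct,
    detect_bad_channels,
    filter_epochs,
    interpolate_pulse_artifact,
    preprocess_block,
    reject_bad_trials,
    rereference_common_average,
    resample_epochs,
)
from tepstab.synth import generate_block

from conftest import CH8, make_epochs, make_meta, quiet_config

PP = PreprocConfig()


def trace_epochs(trace, fs=2000.0, t0=-100.0, n_ch=8):
    """One trial, n_ch identical copies of a 1-D trace."""
    return make_epochs(np.tile(trace, (1, n_ch, 1)), fs=fs, t0=t0)


class TestInterpolatePulseArtifact:
    def test_constant_trace_exact(self):
        n = 400
        ep = trace_epochs(np.full(n, 5.0))
        out = interpolate_pulse_artifact(ep, PP)
        assert np.allclose(out.data, 5.0, atol=1e-8)

    def test_linear_ramp_exact(self):
        t = -100 + np.arange(400) * 0.5
        ep = trace_epochs(3.0 + 0.25 * t)
        out = interpolate_pulse_artifact(ep, PP)
        assert np.abs(out.data - (3.0 + 0.25 * t)).max() < 1e-6

    def test_sine_with_spike_recovered(self):
        fs = 2000.0
        t = -100 + np.arange(400) * 1000 / fs
        clean = 50.0 * np.sin(2 * np.pi * 20.0 * t / 1000.0)
        dirty = clean.copy()
        dirty[(t >= 2) & (t <= 10)] += 1000.0
        out = interpolate_pulse_artifact(trace_epochs(dirty, fs=fs), PP)
        win = (t >= -2) & (t < 12)
        assert np.abs(out.data[0, 0, win] - clean[win]).max() < 0.1 * 50.0

    def test_outside_window_untouched(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((2, 8, 400)))
        out = interpolate_pulse_artifact(ep, PP)
        t = ep.times
        outside = (t < -2) | (t >= 12)
        assert np.array_equal(out.data[:, :, outside], ep.data[:, :, outside])
        assert not np.array_equal(out.data, ep.data)

    def test_input_not_mutated(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((1, 8, 400)))
        before = ep.data.copy()
        interpolate_pulse_artifact(ep, PP)
        assert np.array_equal(ep.data, before)

    def test_epoch_too_short(self):
        ep = make_epochs(np.zeros((1, 8, 60)), t0=-10.0)
        with pytest.raises(ValueError, match="too short"):
            interpolate_pulse_artifact(ep, PP)


class TestResample:
    def test_sine_analytic(self):
        fs = 25000.0
        n = int(fs) + 1
        t = -500 + np.arange(n) * 1000 / fs
        sine = np.sin(2 * np.pi * 2.0 * t / 1000.0)
        ep = trace_epochs(sine, fs=fs, t0=-500.0)
        out = resample_epochs(ep, 1000.0)
        tt = out.times
        mid = (tt > -400) & (tt < 400)
        ref = np.sin(2 * np.pi * 2.0 * tt / 1000.0)
        assert np.abs(out.data[0, 0, mid] - ref[mid]).max() < 1e-3

    def test_identity(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((2, 8, 100)))
        out = resample_epochs(ep, ep.fs)
        assert np.array_equal(out.data, ep.data)
        assert out.data is not ep.data

    def test_constant_preserved(self):
        ep = trace_epochs(np.full(2000, 7.0))
        out = resample_epochs(ep, 1000.0)
        mid = out.data[0, 0, 10:-10]
        assert np.allclose(mid, 7.0, atol=1e-6)

    def test_upsampling_rejected(self):
        ep = make_epochs(np.zeros((1, 8, 100)))
        with pytest.raises(ValueError):
            resample_epochs(ep, 2 * ep.fs)


class TestBaseline:
    WINDOW = (-80.0, -10.0)

    def test_constant_goes_to_zero(self):
        ep = trace_epochs(np.full(400, 7.0))
        out = baseline_correct(ep, self.WINDOW)
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_in_window(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((3, 8, 400)))
        out = baseline_correct(ep, self.WINDOW)
        t = out.times
        m = (t >= self.WINDOW[0]) & (t <= self.WINDOW[1])
        assert np.abs(out.data[:, :, m].mean(axis=-1)).max() < 1e-12

    def test_idempotent(self):
        ep = make_epochs(np.random.default_rng(1).standard_normal((2, 8, 400)))
        once = baseline_correct(ep, self.WINDOW)
        twice = baseline_correct(once, self.WINDOW)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_empty_window(self):
        ep = make_epochs(np.zeros((1, 8, 400)))
        with pytest.raises(ValueError):
            baseline_correct(ep, (900.0, 950.0))


class TestFilters:
    def test_bandstop_60hz_attenuation(self):
        # narrow 4 Hz notch rings for ~250 ms; evaluate well away from edges
        fs = 1000.0
        n = 2501
        t = -1000 + np.arange(n)
        sine = np.sin(2 * np.pi * 60.0 * t / 1000.0)
        out = filter_epochs(trace_epochs(sine, fs=fs, t0=-1000.0), "bandstop", (58.0, 62.0))
        mid = slice(700, -700)
        atten = 20 * np.log10(
            np.sqrt(np.mean(sine[mid] ** 2)) / max(np.sqrt(np.mean(out.data[0, 0, mid] ** 2)), 1e-15)
        )
        assert atten >= 40.0

    def test_lowpass_preserves_dc(self):
        ep = trace_epochs(np.full(1101, 5.0), fs=1000.0, t0=-600.0)
        out = filter_epochs(ep, "lowpass", 200.0)
        assert np.allclose(out.data, 5.0, atol=1e-6)

    def test_highpass_kills_slow_drift(self):
        fs = 1000.0
        n = 1101
        t = -600 + np.arange(n)
        drift = 10.0 * np.sin(2 * np.pi * 0.1 * t / 1000.0)
        out = filter_epochs(trace_epochs(drift, fs=fs, t0=-600.0), "highpass", 1.0)
        mid = slice(150, -150)
        assert np.sqrt(np.mean(out.data[0, 0, mid] ** 2)) < 0.1 * np.sqrt(np.mean(drift[mid] ** 2))

    def test_highpass_no_poststim_leakage_into_baseline(self):
        # a purely post-stimulus response must stay out of the pre-stimulus span
        fs = 1000.0
        n = 1101
        t = -600 + np.arange(n)
        resp = np.zeros(n)
        m = (t >= 80) & (t <= 250)
        resp[m] = -12.0 * np.hanning(m.sum())
        out = filter_epochs(trace_epochs(resp, fs=fs, t0=-600.0), "highpass", 1.0)
        pre = (t >= -500) & (t <= -10)
        assert np.abs(out.data[0, 0, pre]).max() < 0.02 * 12.0

    def test_invalid_cutoffs(self):
        ep = make_epochs(np.zeros((1, 8, 500)), fs=1000.0)
        with pytest.raises(ValueError):
            filter_epochs(ep, "lowpass", 600.0)
        with pytest.raises(ValueError):
            filter_epochs(ep, "bandstop", (62.0, 58.0))
        with pytest.raises(ValueError):
            filter_epochs(ep, "notch", 60.0)


class TestDetectBadChannels:
    def test_identical_channels_none_flagged(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal((3, 1, 500))
        ep = make_epochs(np.tile(trace, (1, 8, 1)) + 0.01 * rng.standard_normal((3, 8, 500)))
        assert detect_bad_channels(ep, PP) == frozenset()

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_channel_flagged(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((5, 16, 500))
        data[:, 3] *= 100.0
        channels = tuple(f"{c}" for c in (
            "C3", "C1", "C5", "FC3", "CP3", "Cz", "FC1", "CP1",
            "C4", "C2", "C6", "FC4", "CP4", "Pz", "Fz", "Oz"))
        ep = make_epochs(data, channels=channels)
        assert detect_bad_channels(ep, PP) == {channels[3]}

    def test_flat_channel_flagged(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 8, 500))
        data[:, 5] = 0.0
        ep = make_epochs(data)
        assert CH8[5] in detect_bad_channels(ep, PP)

    def test_too_many_bad_raises(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 8, 500))
        data[:, :3] = 0.0
        with pytest.raises(DataQualityError):
            detect_bad_channels(make_epochs(data), PP)

    def test_too_few_channels(self):
        ep = make_epochs(np.zeros((1, 4, 100)), channels=CH8[:4])
        with pytest.raises(ValueError, match="8 channels"):
            detect_bad_channels(ep, PP)


class TestRejectBadTrials:
    def test_clean_block_no_rejections(self):
        cfg = quiet_config(n_trials=10, noise_sd=5.0)
        ep = generate_block(cfg, make_meta())
        out = reject_bad_trials(ep, PP)
        assert out.bad_trials == frozenset()

    def test_injected_movement_trials_flagged_exactly(self):
        cfg = quiet_config(n_trials=100, noise_sd=5.0, seed=7)
        ep = generate_block(cfg, make_meta())
        data = ep.data.copy()
        hit = [4, 17, 42, 88]
        data[hit] += 1000.0
        out = reject_bad_trials(ep.replace(data=data), PP)
        assert out.bad_trials == frozenset(hit)
        assert np.array_equal(out.data, data)  # data unchanged

    def test_infinite_threshold_no_rejections(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(1e5 * rng.standard_normal((5, 8, 400)))
        out = reject_bad_trials(ep, replace(PP, bad_trial_abs_uv=np.inf))
        assert out.bad_trials == frozenset()

    def test_pulse_window_excluded_from_criterion(self):
        data = np.zeros((2, 8, 400))
        ep = make_epochs(data)
        t = ep.times
        data[0, :, (t >= 0) & (t < 10)] = 5000.0  # artifact span only
        out = reject_bad_trials(make_epochs(data), PP)
        assert out.bad_trials == frozenset()

    def test_all_rejected_raises(self):
        ep = make_epochs(np.full((3, 8, 400), 500.0))
        with pytest.raises(DataQualityError):
            reject_bad_trials(ep, PP)


class TestCommonAverage:
    def test_two_channels(self):
        data = np.zeros((1, 8, 4))
        data[0, 0] = [1.0, 2.0, 3.0, 4.0]
        data[0, 1] = [3.0, 2.0, 1.0, 0.0]
        ep = make_epochs(data[:, :2], channels=CH8[:2])
        out = rereference_common_average(ep)
        assert np.allclose(out.data[0, 0], (data[0, 0] - data[0, 1]) / 2)
        assert np.allclose(out.data[0, 1], (data[0, 1] - data[0, 0]) / 2)

    def test_uniform_signal_zeroed(self):
        ep = make_epochs(np.tile(np.sin(np.arange(100)), (2, 8, 1)))
        out = rereference_common_average(ep)
        assert np.abs(out.data).max() < 1e-12

    def test_channel_sum_zero(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((3, 8, 200)))
        out = rereference_common_average(ep)
        assert np.abs(out.data.sum(axis=1)).max() < 1e-9

    def test_bad_channels_left_alone(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((2, 8, 100)), bad_channels={CH8[0]})
        out = rereference_common_average(ep)
        assert np.array_equal(out.data[:, 0], ep.data[:, 0])
        good = out.good_channel_idx
        assert np.abs(out.data[:, good].sum(axis=1)).max() < 1e-9

    def test_too_few_good_channels(self):
        ep = make_epochs(np.zeros((1, 2, 10)), channels=CH8[:2], bad_channels={CH8[0]})
        with pytest.raises(ValueError):
            rereference_common_average(ep)


class TestPreprocessBlock:
    def test_subset_equals_direct_call(self, default_block):
        sub = list(range(10))
        a = preprocess_block(default_block, PP, sub)
        b = preprocess_block(default_block.select_trials(sub), PP, None)
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_input_unmodified(self, default_block):
        before = default_block.data.copy()
        preprocess_block(default_block, PP, list(range(10)))
        assert np.array_equal(default_block.data, before)

    def test_noiseless_template_recovered(self):
        # pipeline output (mid-window) matches an independently filtered template
        from scipy import signal as sg

        cfg = quiet_config(n_trials=10)
        ep = generate_block(cfg, make_meta())
        out = preprocess_block(ep, PP, None)
        tep = out.data[out.good_trials].mean(axis=0)

        # independent reference: template -> resample -> baseline -> filters -> CAR
        ref = ep.extras["evoked"]
        ref = sg.resample_poly(ref, 1, 2, axis=-1)
        t = out.times
        base = (t >= -500) & (t <= -10)
        ref = ref - ref[:, base].mean(axis=1, keepdims=True)
        for sos in (
            sg.butter(4, 1.0, "highpass", fs=1000.0, output="sos"),
            sg.butter(4, (58.0, 62.0), "bandstop", fs=1000.0, output="sos"),
            sg.butter(4, 200.0, "lowpass", fs=1000.0, output="sos"),
        ):
            ref = sg.sosfiltfilt(sos, ref, axis=-1, padtype="odd")
        good = out.good_channel_idx  # mirror the pipeline's good-channel CAR
        ref = ref - ref[good].mean(axis=0, keepdims=True)

        mid = (t >= 60) & (t <= 350)
        num = np.sqrt(np.mean((tep[good][:, mid] - ref[good][:, mid]) ** 2))
        den = np.sqrt(np.mean(ref[good][:, mid] ** 2))
        assert num / den < 0.02

    def test_pulse_span_tamed_on_noiseless_input(self):
        cfg = quiet_config(n_trials=4, pulse_artifact_amp=500.0)
        ep = generate_block(cfg, make_meta())
        out = preprocess_block(ep, PP, None)
        t = out.times
        win = (t >= -2) & (t < 12)
        ref = (t >= 20) & (t <= 60)
        assert np.abs(out.data[:, :, win]).max() < 5 * np.sqrt(np.mean(out.data[:, :, ref] ** 2)) + 1e-9

    def test_hook_is_called(self, default_block):
        calls = []

        def hook(ep):
            calls.append(ep.n_trials)
            return ep

        preprocess_block(default_block, replace(PP, artifact_hook=hook), list(range(10)))
        assert calls == [10]
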