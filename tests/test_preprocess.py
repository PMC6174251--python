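"""Filtering, epoching, artifact blanking/fill, baseline, averaging, SNR, peaks."""

import numpy as np
import pytest

from lcdyn.data import EEGData, EpochSet, ERP, ms_to_samples
from lcdyn.preprocess import (
    average_epochs,
    bandpass_downsample,
    baseline_correct,
    blank_and_fill,
    compute_snr,
    db_from_signal_percent,
    extract_epochs,
    find_p50_n100,
    signal_percent_from_db,
)


def _record(samples, fs=1024.0, events=()):
    n_ch = samples.shape[0]
    return EEGData(samples, fs, [f"EEG{i:03d}" for i in range(n_ch)], None, list(events))


def _epochs(data, fs=512.0, window=(50.0, 200.0)):
    return EpochSet(np.asarray(data, dtype=float), fs, window)


class TestBandpassDownsample:
    def test_dc_rejected_by_highpass(self):
        # filter-response oracle at 0 Hz: band-pass gain is ~0 there
        rec = _record(np.full((1, 8192), 3.0))
        out = bandpass_downsample(rec, (1.0, 30.0), 512.0)
        assert np.max(np.abs(out.samples)) < 0.03 * 3.0

    def test_passband_tone_preserved(self):
        # filter-response oracle at 10 Hz: inside the passband, gain ~1
        t = np.arange(8192) / 1024.0
        rec = _record(np.sin(2 * np.pi * 10.0 * t)[None, :])
        out = bandpass_downsample(rec, (1.0, 30.0), 512.0)
        mid = out.samples[0, 1000:-1000]
        assert abs(mid.max() - 1.0) < 0.05

    def test_halving_rate_halves_sample_count(self):
        rec = _record(np.random.default_rng(0).normal(size=(2, 4096)))
        out = bandpass_downsample(rec, (1.0, 30.0), 512.0)
        assert out.samples.shape[1] == 2048
        assert out.fs == 512.0

    def test_event_indices_rescaled(self):
        rec = _record(np.zeros((1, 4096)), events=[(1000, "stim")])
        out = bandpass_downsample(rec, (1.0, 30.0), 512.0)
        assert out.events == [(500, "stim")]

    def test_nyquist_violation_rejected(self):
        rec = _record(np.zeros((1, 4096)))
        with pytest.raises(ValueError):
            bandpass_downsample(rec, (1.0, 30.0), 50.0)


class TestExtractEpochs:
    def test_post_stimulus_segment_has_102_samples_at_512hz(self):
        # 0-200 ms at 512 Hz = 102 samples; full epoch = 26 + 102 = 128
        rec = _record(np.zeros((2, 2000)), fs=512.0, events=[(500, "stim"), (900, "stim")])
        ep = extract_epochs(rec, "stim", (50.0, 200.0))
        assert ep.n_times == 128
        assert ep.n_times - ep.pre_samples == 102
        assert ep.n_trials == 2

    def test_marker_count_equals_trial_count(self):
        events = [(100 + 200 * k, "stim") for k in range(8)]
        rec = _record(np.zeros((1, 2000)), fs=512.0, events=events)
        assert extract_epochs(rec, "stim").n_trials == 8

    def test_zero_events_empty_epochs_then_average_errors(self):
        rec = _record(np.zeros((1, 2000)), fs=512.0)
        ep = extract_epochs(rec, "stim")
        assert ep.n_trials == 0
        with pytest.raises(ValueError):
            average_epochs(ep)

    def test_edge_trial_dropped(self):
        rec = _record(np.zeros((1, 300)), fs=512.0, events=[(10, "stim"), (150, "stim")])
        ep = extract_epochs(rec, "stim")
        assert ep.n_trials == 1


class TestBlankAndFill:
    def test_constant_signal_continues_constant(self):
        ep = _epochs(np.full((1, 1, 128), 4.5))
        out = blank_and_fill(ep)
        np.testing.assert_allclose(out.epochs, 4.5, atol=1e-9)

    def test_noiseless_ar1_continues_exactly(self):
        # analytic AR continuation oracle: x(t) = 0.5 x(t-1)
        x = 10.0 * 0.5 ** (np.arange(128) / 4.0)
        ep = _epochs(x[None, None, :])
        out = blank_and_fill(ep)
        np.testing.assert_allclose(out.epochs[0, 0], x, atol=1e-9)

    def test_large_artifact_removed(self, rng):
        noise = rng.normal(0, 1.0, size=(6, 2, 128))
        ep0 = _epochs(noise)
        t = ep0.times_ms()
        gap = (t >= -10.0) & (t <= 10.0)
        data = noise.copy()
        data[:, :, gap] += 20.0 * np.abs(noise).max()
        out = blank_and_fill(_epochs(data))
        pre_rms = np.sqrt(np.mean(noise[:, :, : np.nonzero(gap)[0][0]] ** 2))
        assert np.abs(out.epochs[:, :, gap]).max() <= 2.0 * np.abs(noise).max()
        # no sample of the original artifact survives
        assert np.abs(out.epochs[:, :, gap]).max() < np.abs(data[:, :, gap]).min()

    def test_insufficient_pregap_history_rejected(self):
        ep = _epochs(np.zeros((1, 1, 128)))
        with pytest.raises(ValueError):
            blank_and_fill(ep, blank_ms=(-45.0, 10.0))


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        out = baseline_correct(_epochs(np.full((2, 3, 128), 5.0)))
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)

    def test_zero_baseline_epoch_unchanged(self, rng):
        data = rng.normal(size=(2, 2, 128))
        ep = _epochs(data)
        b0, b1 = ep.sample_range(-50.0, -10.0)
        data -= data[:, :, b0:b1].mean(axis=2, keepdims=True)
        out = baseline_correct(_epochs(data))
        np.testing.assert_allclose(out.epochs, data, atol=1e-12)

    def test_ramp_slope_preserved_baseline_zeroed(self):
        """Hand arithmetic on a ramp: subtracting the baseline mean keeps slope."""
        ramp = np.arange(128, dtype=float)
        out = baseline_correct(_epochs(ramp[None, None, :]))
        ep = _epochs(ramp[None, None, :])
        b0, b1 = ep.sample_range(-50.0, -10.0)
        assert abs(out.epochs[0, 0, b0:b1].mean()) < 1e-12
        np.testing.assert_allclose(np.diff(out.epochs[0, 0]), 1.0, atol=1e-12)
        # hand value: baseline window covers samples 1..20 (t in [-50,-10] ms),
        # whose ramp mean is 10.5
        assert out.epochs[0, 0, 0] == ramp[0] - 10.5


class TestAverageEpochs:
    def test_identical_trials_average_to_any_trial(self, rng):
        tr = rng.normal(size=(1, 2, 128))
        ep = _epochs(np.repeat(tr, 5, axis=0))
        np.testing.assert_allclose(average_epochs(ep).mean, tr[0], atol=1e-12)

    def test_opposite_trials_cancel(self, rng):
        x = rng.normal(size=(1, 2, 128))
        ep = _epochs(np.concatenate([x, -x], axis=0))
        np.testing.assert_allclose(average_epochs(ep).mean, 0.0, atol=1e-12)

    def test_noise_shrinks_like_sqrt_n(self, rng):
        """Monte-Carlo: ERP noise RMS ~ single-trial RMS / sqrt(N)."""
        n_rep, n_tr = 1000, 16
        noise = rng.normal(size=(n_rep, n_tr, 128))
        erp_rms = np.sqrt(np.mean(noise.mean(axis=1) ** 2))
        single_rms = np.sqrt(np.mean(noise[:, 0] ** 2))
        assert abs(erp_rms - single_rms / np.sqrt(n_tr)) < 0.05 * single_rms


class TestComputeSnr:
    def test_unit_ratio_is_zero_db_and_half_percent(self, rng):
        # construct epochs whose ERP RMS ~ residual RMS
        signal = np.sin(2 * np.pi * 8 * np.arange(128) / 512.0)
        n_tr = 4000
        noise = rng.normal(0, np.sqrt(np.mean(signal**2)), size=(n_tr, 1, 128))
        ep = _epochs(signal[None, None, :] + noise)
        rep = compute_snr(ep)
        assert abs(rep.snr_db) < 0.2
        assert abs(rep.signal_percent - 50.0) < 1.2

    @pytest.mark.parametrize(
        "percent,db",
        [(85.30, 7.64), (96.35, 14.22), (87.92, 8.62), (95.97, 13.76)],
    )
    def test_signal_percent_db_pairs_consistent(self, percent, db):
        """The printed (dB, %) pairs of evoked-SNR tables, to their precision."""
        assert db_from_signal_percent(percent) == pytest.approx(db, abs=0.015)
        assert signal_percent_from_db(db) == pytest.approx(percent, abs=0.05)

    def test_report_internally_consistent(self, rng):
        ep = _epochs(rng.normal(size=(10, 3, 128)) + np.sin(np.arange(128) / 5.0))
        rep = compute_snr(ep)
        r = 10 ** (rep.snr_db / 10.0)
        assert rep.signal_percent == pytest.approx(100 * r / (1 + r), abs=1e-9)

    def test_zero_noise_flagged_infinite(self):
        ep = _epochs(np.repeat(np.sin(np.arange(128) / 3.0)[None, None, :], 3, axis=0))
        rep = compute_snr(ep)
        assert rep.infinite and np.isinf(rep.snr_db) and rep.signal_percent == 100.0

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_snr(_epochs(rng.normal(size=(1, 1, 128))))


class TestFindPeaks:
    def _erp(self, trace):
        return ERP(np.asarray(trace, dtype=float)[None, :], 10, 512.0)

    def test_gaussian_bump_at_50ms_found(self):
        ep = _epochs(np.zeros((1, 1, 128)))
        t = ep.times_ms()
        erp = self._erp(np.exp(-0.5 * ((t - 50.0) / 8.0) ** 2))
        res = find_p50_n100(erp, 0)
        assert abs(res["latency_p50_ms"] - 50.0) <= 1000.0 / 512.0

    def test_negative_bump_at_100ms_found(self):
        ep = _epochs(np.zeros((1, 1, 128)))
        t = ep.times_ms()
        erp = self._erp(-np.exp(-0.5 * ((t - 100.0) / 10.0) ** 2))
        res = find_p50_n100(erp, 0)
        assert abs(res["latency_n100_ms"] - 100.0) <= 1000.0 / 512.0

    def test_flat_erp_reports_both_absent(self):
        res = find_p50_n100(self._erp(np.zeros(128)), 0)
        assert res["latency_p50_ms"] is None and res["latency_n100_ms"] is None

    def test_monotone_trace_reports_absent(self):
        res = find_p50_n100(self._erp(np.arange(128.0)), 0)
        assert res["latency_p50_ms"] is None


class TestPipelineRoundTrip:
    def test_snr_recovered_from_generator_target(self, small_config):
        """Round trip with the generator: realized SNR within 1 dB of target."""
        from lcdyn.synthetic import generate_dataset

        _, eeg = generate_dataset(small_config, artifact=False)
        ep = baseline_correct(extract_epochs(eeg, "stim"))
        rep = compute_snr(ep)
        assert abs(rep.snr_db - small_config.target_snr_db) < 1.0

    def test_full_stage_order_preserves_erp_baseline_invariant(self, small_dataset):
        _, eeg = small_dataset
        ep = baseline_correct(blank_and_fill(extract_epochs(eeg, "stim")))
        erp = average_epochs(ep)
        b0, b1 = erp.sample_range(-50.0, -10.0)
        scale = np.abs(erp.mean).max()
        assert np.abs(erp.mean[:, b0:b1].mean(axis=1)).max() < 1e-9 * scale
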