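"""Evoked-potential preprocessing and the RMS signal-to-noise metrics.

Stage order follows the acquisition pipeline: zero-phase band-pass (1–30 Hz)
-> anti-aliased downsampling (512 Hz) -> epoching (−50..+200 ms) -> stimulus
artifact blanking (±10 ms) with order-3 autoregressive fill -> baseline
correction (−50..−10 ms) -> trial averaging. Ocular-artifact ICA is delegated
to mne and off by default (synthetic records contain no ocular components).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sp_signal

from .data import EEGData, EpochSet, ERP, SNRReport, ms_to_samples, sample_var

logger = logging.getLogger(__name__)


def bandpass_downsample(
    rec: EEGData,
    band: tuple[float, float] = (1.0, 30.0),
    target_fs: float = 512.0,
    order: int = 4,
) -> EEGData:
    """Zero-phase Butterworth band-pass, then polyphase resampling.

    Zero-phase (forward-backward) filtering preserves component latencies, so
    the P50 stays at ~50 ms. Event sample indices are rescaled to the new rate
    and rounded.
    """
    if rec.fs < 2.0 * band[1]:
        raise ValueError("record sampling rate violates Nyquist for the band")
    if target_fs > rec.fs:
        raise ValueError("upsampling not supported")
    if target_fs < 2.0 * band[1]:
        raise ValueError("target_fs violates Nyquist for the upper band edge")

    sos = sp_signal.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, rec.samples, axis=1)

    if target_fs != rec.fs:
        from fractions import Fraction

        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        filtered = sp_signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
        scale = target_fs / rec.fs
        events = [(int(round(i * scale)), c) for i, c in rec.events]
        events = [(i, c) for i, c in events if i < filtered.shape[1]]
    else:
        events = list(rec.events)

    return EEGData(filtered, target_fs, list(rec.channel_names), rec.positions, events)


def extract_epochs(
    rec: EEGData,
    condition: str = "stim",
    window_ms: tuple[float, float] = (50.0, 200.0),
) -> EpochSet:
    """Cut stimulus-locked epochs for one condition.

    Epochs span ``[-pre, +post)`` ms; at 512 Hz with (50, 200) this is 26
    pre-stimulus + 102 post-stimulus = 128 samples. Events whose window falls
    off the record edge are dropped with a warning.
    """
    pre = ms_to_samples(window_ms[0], rec.fs)
    post = ms_to_samples(window_ms[1], rec.fs)
    n_t = rec.n_times
    trials = []
    for idx, label in rec.events:
        if label != condition:
            continue
        if idx - pre < 0 or idx + post > n_t:
            logger.warning("dropping trial at sample %d: window exceeds record", idx)
            continue
        trials.append(rec.samples[:, idx - pre : idx + post])
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.n_channels, pre + post))
    )
    return EpochSet(data, rec.fs, window_ms, condition, list(rec.channel_names))


def _stabilize_ar(coef: np.ndarray) -> np.ndarray:
    """Reflect AR poles outside the unit circle to its interior.

    A least-squares AR fit on a short noisy stretch can be explosive; an
    explosive extrapolation across the gap would inject artifacts of its own.
    Reflecting |z| > 1 roots to 1/conj(z) preserves the model's spectrum shape
    while guaranteeing a bounded forward prediction.
    """
    poly = np.concatenate(([1.0], -coef))  # 1 - a1 z^-1 - ... in z^-1
    roots = np.roots(poly)
    if roots.size and np.any(np.abs(roots) > 1.0):
        roots = np.where(np.abs(roots) > 1.0, 1.0 / np.conj(roots), roots)
        poly = np.real(np.poly(roots))
        coef = -poly[1:]
    return coef


def _ar_fit_predict(history: np.ndarray, order: int, n_ahead: int) -> np.ndarray:
    """Least-squares AR(order) fit on ``history``; forward-predict ``n_ahead``."""
    h = np.asarray(history, dtype=float)
    n = h.size
    X = np.column_stack([h[order - k - 1 : n - k - 1] for k in range(order)])
    y = h[order:]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef = _stabilize_ar(coef)
    buf = list(h[-order:])
    out = np.empty(n_ahead)
    for i in range(n_ahead):
        nxt = float(np.dot(coef, buf[::-1][:order]))
        out[i] = nxt
        buf.append(nxt)
    return out


def blank_and_fill(
    ep: EpochSet,
    blank_ms: tuple[float, float] = (-10.0, 10.0),
    ar_order: int = 3,
    fit_ms: float = 100.0,
) -> EpochSet:
    """Blank the stimulus artifact and fill the gap by AR extrapolation.

    Per trial and channel, an order-``ar_order`` autoregressive model is fit
    by least squares on up to ``fit_ms`` of signal immediately preceding the
    gap and its forward prediction replaces every blanked sample; no sample of
    the original artifact survives.
    """
    t = ep.times_ms()
    gap = np.nonzero((t >= blank_ms[0] - 1e-9) & (t <= blank_ms[1] + 1e-9))[0]
    if gap.size == 0:
        return ep.copy()
    g0, g1 = int(gap[0]), int(gap[-1] + 1)
    if g0 <= 0 or g1 >= ep.n_times:
        raise ValueError("blank window must lie strictly inside the epoch")
    if g0 < 3 * ar_order:
        raise ValueError(
            f"need >= {3 * ar_order} pre-gap samples to fit AR({ar_order}), have {g0}"
        )
    fit_samples = min(g0, max(3 * ar_order, ms_to_samples(fit_ms, ep.fs)))

    out = ep.epochs.copy()
    for tr in range(ep.n_trials):
        for ch in range(ep.n_channels):
            history = out[tr, ch, g0 - fit_samples : g0]
            out[tr, ch, g0:g1] = _ar_fit_predict(history, ar_order, g1 - g0)
    return EpochSet(out, ep.fs, ep.window_ms, ep.condition, ep.channel_names)


def baseline_correct(
    ep: EpochSet, baseline_ms: tuple[float, float] = (-50.0, -10.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    b0, b1 = ep.sample_range(*baseline_ms)
    out = ep.epochs - ep.epochs[:, :, b0:b1].mean(axis=2, keepdims=True)
    return EpochSet(out, ep.fs, ep.window_ms, ep.condition, ep.channel_names)


def average_epochs(ep: EpochSet) -> ERP:
    """Arithmetic mean across trials (the event-related potential)."""
    if ep.n_trials == 0:
        raise ValueError("cannot average an empty epoch set")
    return ERP(
        ep.epochs.mean(axis=0),
        ep.n_trials,
        ep.fs,
        ep.window_ms,
        ep.channel_names,
        ep.condition,
    )


def compute_snr(ep: EpochSet, window_ms: tuple[float, float] = (0.0, 200.0)) -> SNRReport:
    """RMS signal-to-noise of an epoch set at the single-epoch level.

    A_RMS,signal is the RMS of the trial average (ERP) over the post-stimulus
    window. A_RMS,noise is the RMS of the per-trial residuals (trial − ERP)
    rescaled by sqrt(N/(N−1)) to the single-epoch noise level (the residual
    of trial i removes 1/N of its own noise). RMS is taken without mean
    removal, pooled over channels and window samples.
    """
    if ep.n_trials < 2:
        raise ValueError("noise estimation requires at least 2 trials")
    w0, w1 = ep.sample_range(*window_ms)
    erp = ep.epochs.mean(axis=0)
    arms_signal = float(np.sqrt(np.mean(erp[:, w0:w1] ** 2)))
    resid = ep.epochs[:, :, w0:w1] - erp[None, :, w0:w1]
    n = ep.n_trials
    arms_noise = float(np.sqrt(np.mean(resid**2) * n / (n - 1)))
    if arms_noise <= 1e-12 * max(arms_signal, 1.0):
        return SNRReport(arms_signal, 0.0, np.inf, 100.0, infinite=True)
    r = arms_signal / arms_noise
    return SNRReport(
        arms_signal, arms_noise, 10.0 * np.log10(r), 100.0 * r / (1.0 + r)
    )


def signal_percent_from_db(snr_db: float) -> float:
    """P = 100·r/(1+r) with r = 10^(snr_db/10)."""
    r = 10.0 ** (snr_db / 10.0)
    return 100.0 * r / (1.0 + r)


def db_from_signal_percent(signal_percent: float) -> float:
    """Inverse of :func:`signal_percent_from_db`."""
    p = signal_percent / 100.0
    return 10.0 * np.log10(p / (1.0 - p))


def find_p50_n100(
    erp: ERP,
    channel: int | str = 0,
    p50_window_ms: tuple[float, float] = (30.0, 80.0),
    n100_window_ms: tuple[float, float] = (70.0, 140.0),
) -> dict:
    """Locate the positive ~50 ms and negative ~100 ms deflections.

    P50 is the maximum inside 30–80 ms, N100 the minimum inside 70–140 ms.
    A peak is reported absent when the extremum sits on the search-window
    boundary (monotone trace) or the trace is flat there.
    """
    if isinstance(channel, str):
        channel = (erp.channel_names or []).index(channel)
    trace = erp.mean[channel]
    t = erp.times_ms()
    out: dict = {}
    for name, (lo, hi), sign in (
        ("p50", p50_window_ms, +1),
        ("n100", n100_window_ms, -1),
    ):
        idx = np.nonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))[0]
        seg = sign * trace[idx]
        if np.ptp(seg) == 0.0:
            out[f"latency_{name}_ms"] = None
            out[f"amplitude_{name}"] = None
            continue
        k = int(np.argmax(seg))
        if k == 0 or k == seg.size - 1:  # no interior extremum
            out[f"latency_{name}_ms"] = None
            out[f"amplitude_{name}"] = None
            continue
        out[f"latency_{name}_ms"] = float(t[idx[k]])
        out[f"amplitude_{name}"] = float(trace[idx[k]])
    return out


def preprocess_pipeline(
    rec: EEGData,
    condition: str = "stim",
    band: tuple[float, float] | None = (1.0, 30.0),
    target_fs: float = 512.0,
    window_ms: tuple[float, float] = (50.0, 200.0),
    blank_ms: tuple[float, float] | None = (-10.0, 10.0),
    baseline_ms: tuple[float, float] = (-50.0, -10.0),
    ar_order: int = 3,
) -> tuple[EpochSet, ERP, SNRReport]:
    """Filter -> downsample -> epoch -> blank/fill -> baseline -> average."""
    if band is not None:
        rec = bandpass_downsample(rec, band, target_fs)
    ep = extract_epochs(rec, condition, window_ms)
    if blank_ms is not None:
        ep = blank_and_fill(ep, blank_ms, ar_order)
    ep = baseline_correct(ep, baseline_ms)
    erp = average_epochs(ep)
    snr = compute_snr(ep)
    return ep, erp, snr
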