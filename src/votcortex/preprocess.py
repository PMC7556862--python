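"""Raw voltage to analysis-ready arrays.

The chain mirrors standard ECoG practice: zero-phase notch filtering of line
noise (60 Hz and harmonics), common-average referencing, analytic-amplitude
high-gamma extraction by averaging eight logarithmically spaced Hilbert
sub-bands spanning 70-150 Hz, downsampling to 400 Hz, epoching around
stimulus onsets, baseline z-scoring, and 50 ms boxcar smoothing.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .containers import EPOCH_WINDOW_MS, EpochSet, RawRecording

__all__ = [
    "notch_and_reference",
    "extract_high_gamma",
    "epoch_and_normalize",
    "boxcar_smooth",
    "preprocess_raw",
]

HG_SFREQ = 400.0
BASELINE_MS = (-500.0, -200.0)
BOXCAR_MS = 50.0


def notch_and_reference(
    raw: RawRecording,
    car_mode: str = "grid",
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
    quality: float = 30.0,
) -> RawRecording:
    """Remove line noise and apply a common-average reference.

    Each notch is a zero-phase second-order IIR filter (applied forward and
    backward, so attenuation at the notch frequency far exceeds 40 dB).
    ``car_mode='grid'`` subtracts the mean of all non-bad electrodes at every
    sample; ``car_mode='row16'`` references within consecutive blocks of 16
    electrodes (the amplifier-row convention).
    """
    fs = raw.sfreq
    for f in notch_freqs:
        if fs <= 2 * f:
            raise ValueError(f"sampling rate {fs} too low for a {f} Hz notch")
    good = ~raw.bad_channels
    if not good.any():
        raise ValueError("all channels are marked bad; nothing to reference")

    data = raw.data.copy()
    for f in notch_freqs:
        b, a = spsig.iirnotch(f, quality, fs=fs)
        data = spsig.filtfilt(b, a, data, axis=1)

    if car_mode == "grid":
        groups = [np.arange(raw.n_electrodes)]
    elif car_mode == "row16":
        groups = [
            np.arange(i, min(i + 16, raw.n_electrodes))
            for i in range(0, raw.n_electrodes, 16)
        ]
    else:
        raise ValueError(f"unknown car_mode {car_mode!r}")
    for g in groups:
        g_good = g[good[g]]
        if g_good.size == 0:
            continue
        data[g] -= data[g_good].mean(axis=0, keepdims=True)

    return RawRecording(
        data=data,
        sfreq=fs,
        event_onsets=raw.event_onsets.copy(),
        electrodes=list(raw.electrodes),
        bad_channels=raw.bad_channels.copy(),
        bad_segments=raw.bad_segments.copy(),
    )


def _hg_bands(n_bands: int = 8, lo: float = 70.0, hi: float = 150.0):
    centers = np.geomspace(lo, hi, n_bands)
    # bandwidth proportional to center frequency (constant-Q Gaussians)
    sigmas = centers / 8.0
    return centers, sigmas


def extract_high_gamma(
    raw: RawRecording, target_sfreq: float = HG_SFREQ, n_bands: int = 8
) -> RawRecording:
    """Analytic-amplitude high-gamma, averaged over eight log-spaced bands.

    Per electrode, the analytic signal of each Gaussian frequency-domain
    band-pass (centers geometrically spaced over 70-150 Hz, bandwidth
    proportional to center frequency) is computed via the Hilbert
    construction, its magnitude averaged across bands, and the result
    polyphase-resampled to ``target_sfreq`` with event onsets rescaled.
    """
    fs = raw.sfreq
    n_s = raw.n_samples
    if n_s < int(0.5 * fs):
        raise ValueError("record too short for high-gamma filter warm-up")
    freqs = np.fft.fftfreq(n_s, d=1.0 / fs)
    spectra = np.fft.fft(raw.data, axis=1)
    # one-sided analytic-signal weights
    h = np.zeros(n_s)
    h[0] = 1.0
    if n_s % 2 == 0:
        h[n_s // 2] = 1.0
        h[1 : n_s // 2] = 2.0
    else:
        h[1 : (n_s + 1) // 2] = 2.0

    centers, sigmas = _hg_bands(n_bands)
    amp = np.zeros_like(raw.data)
    for cf, sg in zip(centers, sigmas):
        gauss = np.exp(-0.5 * ((np.abs(freqs) - cf) / sg) ** 2)
        analytic = np.fft.ifft(spectra * (gauss * h)[None, :], axis=1)
        amp += np.abs(analytic)
    amp /= n_bands

    frac = Fraction(target_sfreq / fs).limit_denominator(10000)
    if frac != 1:
        amp = spsig.resample_poly(amp, frac.numerator, frac.denominator, axis=1)
    scale = target_sfreq / fs
    onsets = np.round(raw.event_onsets * scale).astype(int)
    n_new = amp.shape[1]
    seg = raw.bad_segments
    if seg.any():
        idx = np.clip((np.arange(n_new) / scale).astype(int), 0, n_s - 1)
        bad = seg[idx]
    else:
        bad = np.zeros(n_new, dtype=bool)
    return RawRecording(
        data=amp,
        sfreq=target_sfreq,
        event_onsets=onsets,
        electrodes=list(raw.electrodes),
        bad_channels=raw.bad_channels.copy(),
        bad_segments=bad,
    )


def boxcar_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average along the last axis; truncated at the edges.

    For even ``width`` the window spans ``[k - width//2, k + width//2 - 1]``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    n = x.shape[-1]
    left = width // 2
    right = width - left - 1
    pad = [(0, 0)] * (x.ndim - 1) + [(left, right)]
    xp = np.pad(x, pad, mode="constant")
    csum = np.cumsum(xp, axis=-1)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    sums = csum[..., width:] - csum[..., :-width]
    ones = np.ones(n)
    op = np.pad(ones, (left, right), mode="constant")
    oc = np.concatenate([[0.0], np.cumsum(op)])
    counts = oc[width:] - oc[:-width]
    return sums / counts


def epoch_and_normalize(
    hg: RawRecording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    boxcar_ms: float = BOXCAR_MS,
    kind: str = "high-gamma-z",
    zscore: bool = True,
) -> EpochSet:
    """Cut epochs, drop masked trials, z-score by baseline, boxcar-smooth.

    Trials whose epoch window overlaps an excluded segment are dropped for
    all channels.  Per electrode, the z-score uses the mean and SD of the
    baseline window pooled over all surviving trials; the boxcar is applied
    per trial after z-scoring.  ``zscore=False`` skips normalization and
    smoothing (the raw-voltage convention).
    """
    fs = hg.sfreq
    if len(events) != len(hg.event_onsets):
        raise ValueError("events table does not match event onsets")
    i_pre = int(round(-window_ms[0] * fs / 1000.0))
    i_post = int(round(window_ms[1] * fs / 1000.0))
    n_s = i_pre + i_post
    times = window_ms[0] + np.arange(n_s) * 1000.0 / fs

    keep, epochs = [], []
    for i, onset in enumerate(hg.event_onsets):
        a, b = onset - i_pre, onset + i_post
        if a < 0 or b > hg.n_samples:
            continue
        if hg.bad_segments[a:b].any():
            continue
        keep.append(i)
        epochs.append(hg.data[:, a:b])
    if not epochs:
        raise ValueError("no trials survive epoching/exclusion")
    data = np.stack(epochs, axis=0)  # trials x electrodes x samples
    ev = events.iloc[keep].reset_index(drop=True)

    if zscore:
        bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
        base = data[:, :, bmask]
        mu = base.mean(axis=(0, 2), keepdims=True)
        sd = base.std(axis=(0, 2), keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero baseline variance; cannot z-score")
        data = (data - mu) / sd
        width = int(round(boxcar_ms * fs / 1000.0))
        if width > 1:
            data = boxcar_smooth(data, width)

    return EpochSet(
        data=data,
        sfreq=fs,
        times=times,
        events=ev,
        electrodes=list(hg.electrodes),
        kind=kind,
        info={"n_events": len(events), "n_dropped": len(events) - len(ev)},
    )


def preprocess_raw(
    raw: RawRecording, events: pd.DataFrame, car_mode: str = "grid"
) -> EpochSet:
    """Full chain: notch + CAR -> high-gamma -> epoched, z-scored, smoothed."""
    ref = notch_and_reference(raw, car_mode=car_mode)
    hg = extract_high_gamma(ref)
    return epoch_and_normalize(hg, events)
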