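"""Per-second log-PSD band features on occipital channels.

Each one-second epoch is transformed with a 128-point FFT (rectangular
window, zero-padded when the rate is 100 Hz), converted to log10 power, and
the bins falling in the theta (4-8 Hz), alpha (8-14 Hz) and beta (14-34 Hz)
rhythms are concatenated into one feature vector.  The feature at second t is
the element-wise mean over the previous b seconds and second t itself (b+1
epochs): drowsiness is a slowly varying state, so averaging trades latency
for a steadier, more discriminable spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import BANDS, EEGRecording

__all__ = [
    "NFFT",
    "BandFeature",
    "epoch_psd",
    "band_bins",
    "band_select",
    "history_average",
    "extract_features",
    "feature_table",
]

NFFT = 128
FEATURE_RATES = (128.0, 100.0)
LOG_FLOOR = 1e-12  # PSD floor before log10, avoids -inf on silent epochs


@dataclass
class BandFeature:
    """One feature vector: log-PSD over theta/alpha/beta bins at second ``t``."""

    vector: np.ndarray
    t: int
    b: int
    channel: str = "O1"


def epoch_psd(signal: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-second log10 PSD via a 128-point FFT of each 1 s epoch.

    Returns ``(psd, freqs)`` where ``psd`` has one row per full second and
    ``freqs`` are the FFT bin centers (spacing fs/128 Hz).  At 100 Hz the
    100-sample epoch is zero-padded to 128 points.
    """
    signal = np.asarray(signal, dtype=float)
    if fs not in FEATURE_RATES:
        raise ValueError(f"fs must be one of {FEATURE_RATES} (downsampled rates), got {fs}")
    step = int(fs)
    if signal.size < step:
        raise ValueError(f"signal shorter than one second ({signal.size} < {step})")
    n_sec = signal.size // step
    epochs = signal[: n_sec * step].reshape(n_sec, step)
    spectrum = np.fft.rfft(epochs, n=NFFT, axis=1)
    psd = np.abs(spectrum) ** 2 / (step * fs)  # periodogram scaling, one-sided
    psd[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(NFFT, d=1.0 / fs)
    return np.log10(np.maximum(psd, LOG_FLOOR)), freqs


def band_bins(fs: float) -> np.ndarray:
    """Indices of FFT bins whose center lies in theta, alpha then beta."""
    freqs = np.fft.rfftfreq(NFFT, d=1.0 / fs)
    idx = []
    for lo, hi in BANDS.values():
        idx.extend(np.nonzero((freqs >= lo) & (freqs < hi))[0])
    return np.asarray(idx, dtype=int)


def band_select(psd_rows: np.ndarray, fs: float) -> np.ndarray:
    """Rectangular-window band extraction: keep theta/alpha/beta bins in order."""
    psd_rows = np.asarray(psd_rows, dtype=float)
    return psd_rows[..., band_bins(fs)]


def history_average(features: np.ndarray, t: int, b: int) -> np.ndarray:
    """Mean feature over seconds t-b .. t inclusive (b+1 epochs)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if b < 0:
        raise ValueError("b must be >= 0")
    if t < b:
        raise ValueError(f"need t >= b, got t={t}, b={b}")
    if t >= features.shape[0]:
        raise ValueError(f"t={t} out of range for {features.shape[0]} epochs")
    return features[t - b : t + 1].mean(axis=0)


def extract_features(rec: EEGRecording, channel: str, b: int) -> tuple[np.ndarray, np.ndarray]:
    """Full feature path for one channel of a downsampled recording.

    Returns ``(times, X)``: epoch indices t = b .. n_seconds-1 and the matrix
    of history-averaged band features, one row per t.
    """
    psd, _ = epoch_psd(rec.channel(channel), rec.fs)
    bands = band_select(psd, rec.fs)
    n_sec = bands.shape[0]
    if n_sec <= b:
        raise ValueError(f"recording has {n_sec} s, need more than b={b}")
    times = np.arange(b, n_sec)
    # sliding mean over the trailing b+1 epochs
    csum = np.cumsum(bands, axis=0)
    window = np.empty((times.size, bands.shape[1]))
    for i, t in enumerate(times):
        lo = t - b
        window[i] = (csum[t] - (csum[lo - 1] if lo > 0 else 0)) / (b + 1)
    return times, window


def feature_table(rec: EEGRecording, channels, b: int):
    """Features plus aligned labels for several channels.

    Returns a dict ``channel -> (times, X, y)``; ``y`` is the recording's
    per-second label at each epoch t (None if the recording is unlabeled).
    """
    out = {}
    for ch in channels:
        times, X = extract_features(rec, ch, b)
        y = rec.labels[times] if rec.labels is not None else None
        out[ch] = (times, X, y)
    return out
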