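"""Synthetic alert/drowsy EEG with the spectral structure a band-power detector relies on.

The generator emulates the PSD-level signature of drowsiness on occipital
channels: elevated theta (4-8 Hz) and alpha (8-14 Hz) power with intermittent
alpha bursts, and reduced beta (14-34 Hz) power, on top of a 1/f pink
background.  Sub-3 Hz drift and >50 Hz interference are added so the wavelet
denoiser has realistic out-of-band energy to remove (the acquisition hardware
passband is 3-100 Hz).  No claim of physiological realism beyond the spectrum
is made: there is no dipole/forward model, no EOG/ECG, no artifact taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "EEGRecording",
    "SynthParams",
    "BANDS",
    "generate_recording",
    "generate_session",
]

#: EEG rhythm bands (Hz), half-open [low, high).
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 14.0), "beta": (14.0, 34.0)}

VALID_STATES = ("alert", "drowsy")
VALID_CHANNELS = ("O1", "O2", "C3", "Cz", "C4", "P3", "Pz", "P4")
VALID_FS = (512.0, 1000.0, 128.0, 100.0)


@dataclass
class EEGRecording:
    """Multichannel sampled EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in µV-like arbitrary units.
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        10-20 electrode labels, subset of ``VALID_CHANNELS``.
    device : str
        ``"HBS"`` (512 Hz wearable) or ``"BP"`` (1000 Hz lab amplifier).
    labels : ndarray of str or None
        Optional per-second vigilance label (``"alert"``/``"drowsy"``).
    """

    data: np.ndarray
    fs: float
    channels: tuple
    device: str = "HBS"
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channels = tuple(self.channels)
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows for {len(self.channels)} channels"
            )
        unknown = set(self.channels) - set(VALID_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples")
        if self.device not in ("HBS", "BP"):
            raise ValueError(f"device must be HBS or BP, got {self.device!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype="U6")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples by electrode label."""
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None


@dataclass
class SynthParams:
    """Generator parameters: mean band powers per state (µV²) and artifact levels.

    Defaults encode the drowsiness signature (theta and alpha rise, beta
    falls) at a contrast that leaves per-second features noisy enough that
    history averaging visibly helps, rather than saturating the classifier.
    """

    alert_theta: float = 8.0
    alert_alpha: float = 12.0
    alert_beta: float = 24.0
    drowsy_theta: float = 32.0
    drowsy_alpha: float = 48.0
    drowsy_beta: float = 6.0
    burst_rate: float = 4.0  #: alpha bursts per minute, drowsy state only
    burst_power: float = 40.0  #: extra alpha power (µV²) at a burst's peak
    pink_power: float = 15.0  #: broadband 1/f background power (µV²)
    drift_power: float = 80.0  #: sub-3 Hz drift power (µV²)
    hf_power: float = 20.0  #: >50 Hz interference power (µV²)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "alert_theta", "alert_alpha", "alert_beta",
            "drowsy_theta", "drowsy_alpha", "drowsy_beta",
            "burst_rate", "burst_power", "pink_power",
            "drift_power", "hf_power",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drowsy_theta < self.alert_theta or self.drowsy_alpha < self.alert_alpha:
            raise ValueError("drowsy theta/alpha power must exceed alert")
        if self.drowsy_beta > self.alert_beta:
            raise ValueError("drowsy beta power must be below alert")

    def band_power(self, state: str) -> dict:
        if state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}, got {state!r}")
        return {b: getattr(self, f"{state}_{b}") for b in BANDS}

    def with_seed(self, seed: int) -> "SynthParams":
        return replace(self, seed=seed)


def _band_noise(rng, n, fs, low, high, power):
    """Band-limited Gaussian noise with exact sample variance ``power``."""
    if power == 0.0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = _sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, x)
    s = x.std()
    return x * (np.sqrt(power) / s) if s > 0 else x


def _pink_noise(rng, n, fs, power):
    """1/f-shaped background, high-passed at 1 Hz so drift stays a separate knob."""
    if power == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    nz = f >= 1.0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(spec * shape, n)
    return x * (np.sqrt(power) / x.std())


def _drift(rng, n, fs, power):
    """Slow baseline wander: two sub-3 Hz sinusoids with random phase."""
    if power == 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for freq in (0.4, 1.1):
        # each tone carries half the power; sine amplitude a has power a^2/2
        out += np.sqrt(power) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return out


def _hf_interference(rng, n, fs, power):
    """>50 Hz interference: a 70 Hz tone plus 70-90 Hz noise."""
    if power == 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    tone = np.sqrt(power) * np.sin(2 * np.pi * 70.0 * t + rng.uniform(0, 2 * np.pi))
    noise = _band_noise(rng, n, fs, 70.0, min(90.0, 0.49 * fs), power / 2.0)
    return tone + noise


def _alpha_bursts(rng, n, fs, rate_per_min, peak_power):
    """Amplitude-modulated alpha epochs: Poisson arrivals, 1-3 s Hann envelopes."""
    if rate_per_min == 0.0 or peak_power == 0.0:
        return np.zeros(n)
    duration = n / fs
    n_bursts = rng.poisson(rate_per_min * duration / 60.0)
    envelope = np.zeros(n)
    for _ in range(n_bursts):
        dur = rng.uniform(1.0, 3.0)
        start = rng.uniform(0.0, max(duration - dur, 0.0))
        i0, i1 = int(start * fs), int((start + dur) * fs)
        envelope[i0:i1] = np.maximum(envelope[i0:i1], np.hanning(i1 - i0))
    carrier = _band_noise(rng, n, fs, *BANDS["alpha"], 1.0)
    return np.sqrt(peak_power) * envelope * carrier


def _generate_channel(rng, state, n, fs, params: SynthParams) -> np.ndarray:
    x = _pink_noise(rng, n, fs, params.pink_power)
    for band, (lo, hi) in BANDS.items():
        x += _band_noise(rng, n, fs, lo, hi, params.band_power(state)[band])
    if state == "drowsy":
        x += _alpha_bursts(rng, n, fs, params.burst_rate, params.burst_power)
    x += _drift(rng, n, fs, params.drift_power)
    x += _hf_interference(rng, n, fs, params.hf_power)
    return x


def _check_args(state, duration, fs):
    if state not in VALID_STATES:
        raise ValueError(f"state must be one of {VALID_STATES}, got {state!r}")
    if duration < 1:
        raise ValueError(f"duration must be >= 1 s, got {duration}")
    if fs not in (512, 1000):
        raise ValueError(f"fs must be 512 or 1000 Hz, got {fs}")


def generate_recording(
    state: str,
    duration: float,
    fs: float = 512,
    params: SynthParams | None = None,
    channels=("O1", "O2"),
) -> EEGRecording:
    """Generate one constant-state recording.

    Parameters
    ----------
    state : {"alert", "drowsy"}
    duration : float
        Length in seconds, >= 1.
    fs : {512, 1000}
        512 Hz for the wearable ("HBS") device mode, 1000 Hz for "BP".
    params : SynthParams, optional
    channels : sequence of str
        Electrode labels to synthesize (independent noise per channel).
    """
    _check_args(state, duration, fs)
    params = params or SynthParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF]))
    n = int(round(duration * fs))
    data = np.vstack([_generate_channel(rng, state, n, fs, params) for _ in channels])
    labels = np.full(int(np.ceil(duration)), state, dtype="U6")
    return EEGRecording(
        data=data,
        fs=float(fs),
        channels=tuple(channels),
        device="HBS" if fs == 512 else "BP",
        labels=labels,
    )


def generate_session(
    schedule,
    fs: float = 512,
    params: SynthParams | None = None,
    channels=("O1", "O2"),
) -> EEGRecording:
    """Concatenate constant-state segments into one labeled session.

    ``schedule`` is a non-empty list of ``(state, seconds)`` pairs; the
    returned recording carries one label per second matching the schedule.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    params = params or SynthParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF]))
    chunks, labels = [], []
    for state, seconds in schedule:
        _check_args(state, seconds, fs)
        n = int(round(seconds * fs))
        chunks.append(
            np.vstack([_generate_channel(rng, state, n, fs, params) for _ in channels])
        )
        labels.append(np.full(int(seconds), state, dtype="U6"))
    return EEGRecording(
        data=np.hstack(chunks),
        fs=float(fs),
        channels=tuple(channels),
        device="HBS" if fs == 512 else "BP",
        labels=np.concatenate(labels),
    )
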