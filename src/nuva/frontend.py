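"""Acoustic front-end: raw audio to per-frame MFCC+energy+delta features.

The verifier operates on phone posteriorgrams produced by an acoustic model
from a fixed 26-dimensional feature vector per frame: 12 liftered
mel-frequency cepstral coefficients, one log-energy term, and first-order
deltas of those 13 statics.  Frames are 30 ms every 10 ms, zero-padded to a
64 ms FFT, after whole-signal pre-emphasis with coefficient 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "AudioSignal",
    "FrameSpec",
    "FeatureSequence",
    "preemphasize",
    "frame_signal",
    "compute_deltas",
    "extract_features",
    "mel_filterbank",
]

ENERGY_FLOOR = 1e-10


@dataclass(frozen=True)
class AudioSignal:
    """Mono audio with amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D (mono) sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class FrameSpec:
    """Framing and feature-extraction parameters.

    Defaults give 30 ms windows every 10 ms, a 64 ms FFT, pre-emphasis 0.95,
    12 cepstra liftered with coefficient 23, and 13 deltas, for 26 features
    per frame.
    """

    window_ms: float = 30.0
    hop_ms: float = 10.0
    fft_ms: float = 64.0
    preemphasis: float = 0.95
    n_mfcc: int = 12
    lifter: float = 23.0
    n_delta: int = 13
    n_mels: int = 26
    delta_halfwidth: int = 2
    energy_floor: float = ENERGY_FLOOR

    def __post_init__(self) -> None:
        if not (0 <= self.preemphasis < 1):
            raise ValueError("preemphasis must be in [0, 1)")
        if self.window_ms > self.fft_ms:
            raise ValueError("window_ms must not exceed fft_ms")
        if self.hop_ms > self.window_ms:
            raise ValueError("hop_ms must not exceed window_ms")

    def window_samples(self, sample_rate: int) -> int:
        return int(round(self.window_ms * sample_rate / 1000.0))

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop_ms * sample_rate / 1000.0))

    def fft_samples(self, sample_rate: int) -> int:
        return int(round(self.fft_ms * sample_rate / 1000.0))

    @property
    def n_features(self) -> int:
        return self.n_mfcc + 1 + self.n_delta


@dataclass(frozen=True)
class FeatureSequence:
    """T x D matrix of per-frame acoustic features with timing metadata."""

    values: np.ndarray
    frame_rate: float
    source_duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        header = " ".join(f"f{i}" for i in range(self.n_features))
        np.savetxt(
            path,
            self.values,
            header=f"frame_rate={self.frame_rate} source_duration={self.source_duration}\n{header}",
        )

    @classmethod
    def load(cls, path) -> "FeatureSequence":
        with open(path) as fh:
            meta = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=") for item in meta)
        values = np.loadtxt(path, ndmin=2)
        return cls(values, float(kv["frame_rate"]), float(kv["source_duration"]))


def preemphasize(signal: AudioSignal, coeff: float | None = None) -> AudioSignal:
    """High-pass pre-emphasis: y[t] = x[t] - coeff * x[t-1], y[0] = x[0]."""
    if coeff is None:
        coeff = FrameSpec().preemphasis
    if not (0 <= coeff < 1):
        raise ValueError("pre-emphasis coefficient must be in [0, 1)")
    x = signal.samples
    if len(x) == 0:
        raise ValueError("cannot pre-emphasize an empty signal")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coeff * x[:-1]
    return AudioSignal(y, signal.sample_rate)


def frame_signal(signal: AudioSignal, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Slice a signal into overlapping frames.

    Returns an (n_frames, window) array with
    n_frames = floor((N - W) / H) + 1.  Frames are *not* windowed or padded
    here; spectral analysis zero-pads to the FFT length.
    """
    x = signal.samples
    w = spec.window_samples(signal.sample_rate)
    h = spec.hop_samples(signal.sample_rate)
    n = len(x)
    if n < w:
        raise ValueError(
            f"signal of {n} samples is shorter than one {w}-sample window"
        )
    n_frames = (n - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    return x[idx]


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: int,
                   f_low: float = 0.0, f_high: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    if f_high is None:
        f_high = sample_rate / 2.0

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        left, centre, right = bins[i], bins[i + 1], bins[i + 2]
        for k in range(left, centre):
            fb[i, k] = (k - left) / max(centre - left, 1)
        for k in range(centre, right):
            fb[i, k] = (right - k) / max(right - centre, 1)
    return fb


def _lifter_weights(n_mfcc: int, lifter: float) -> np.ndarray:
    # sinusoidal cepstral lifter 1 + (L/2) sin(pi n / L), n = 1..n_mfcc
    n = np.arange(1, n_mfcc + 1)
    if lifter <= 0:
        return np.ones(n_mfcc)
    return 1.0 + (lifter / 2.0) * np.sin(np.pi * n / lifter)


def compute_deltas(static: np.ndarray, halfwidth: int = 2) -> np.ndarray:
    """First-order delta (regression) coefficients over frames.

    d[t] = sum_{n=1..N} n * (x[t+n] - x[t-n]) / (2 * sum n^2), with
    replicated-boundary padding.  A single-frame input yields zeros.
    """
    static = np.asarray(static, dtype=np.float64)
    squeeze = static.ndim == 1
    if squeeze:
        static = static[:, None]
    t = static.shape[0]
    if t == 1:
        out = np.zeros_like(static)
        return out[:, 0] if squeeze else out
    padded = np.pad(static, ((halfwidth, halfwidth), (0, 0)), mode="edge")
    denom = 2.0 * sum(n * n for n in range(1, halfwidth + 1))
    delta = np.zeros_like(static)
    for n in range(1, halfwidth + 1):
        delta += n * (padded[halfwidth + n:halfwidth + n + t]
                      - padded[halfwidth - n:halfwidth - n + t])
    delta /= denom
    return delta[:, 0] if squeeze else delta


def extract_features(signal: AudioSignal, spec: FrameSpec = FrameSpec()) -> FeatureSequence:
    """Full front-end: pre-emphasis, framing, MFCC + log-energy + deltas.

    Column layout: [c1..c12 liftered MFCCs | log-energy | 13 deltas].
    Silent frames are floored so log-energy stays finite.
    """
    emphasized = preemphasize(signal, spec.preemphasis)
    frames = frame_signal(emphasized, spec)
    sr = signal.sample_rate
    n_fft = spec.fft_samples(sr)

    # log frame energy on the raw (unwindowed) pre-emphasized frame
    energy = np.sum(frames ** 2, axis=1)
    log_energy = np.log(np.maximum(energy, spec.energy_floor))

    window = np.hamming(frames.shape[1])
    spectrum = scipy.fft.rfft(frames * window, n=n_fft, axis=1)
    power = np.abs(spectrum) ** 2

    fb = mel_filterbank(spec.n_mels, n_fft, sr)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, spec.energy_floor))

    cepstra = scipy.fft.dct(log_mel, type=2, axis=1, norm="ortho")
    mfcc = cepstra[:, 1:spec.n_mfcc + 1] * _lifter_weights(spec.n_mfcc, spec.lifter)

    static = np.column_stack([mfcc, log_energy])
    deltas = compute_deltas(static, spec.delta_halfwidth)[:, :spec.n_delta]
    values = np.column_stack([static, deltas])

    frame_rate = sr / spec.hop_samples(sr)
    return FeatureSequence(values, frame_rate=frame_rate,
                           source_duration=signal.duration)
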