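"""Log-Mel spectrogram front end and sliding analysis windows."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synth import Waveform

__all__ = ["MelConfig", "Spectrogram", "AnalysisWindow", "logmel", "window_stream"]

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class MelConfig:
    """STFT + mel filterbank settings.

    Defaults bracket the whinny band: 25 ms frames / 10 ms hop, 64 mel bands,
    100 Hz – 12 kHz.
    """

    win_s: float = 0.025
    hop_s: float = 0.010
    n_mels: int = 64
    fmin: float = 100.0
    fmax: float = 12000.0

    def __post_init__(self):
        if self.n_mels < 8:
            raise ValueError("n_mels must be >= 8")
        if self.hop_s <= 0 or self.win_s < self.hop_s:
            raise ValueError("require win_s >= hop_s > 0")


@dataclass
class Spectrogram:
    values: np.ndarray  # (frames, n_mels), log scale
    frame_times: np.ndarray  # seconds, strictly increasing
    config: MelConfig

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")


@dataclass
class AnalysisWindow:
    source: str
    start: float
    end: float
    spectrogram: Spectrogram
    padded: bool = False


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_centres_hz(config: MelConfig) -> np.ndarray:
    """Centre frequency (Hz) of each mel band."""
    mel_pts = np.linspace(hz_to_mel(config.fmin), hz_to_mel(config.fmax), config.n_mels + 2)
    return mel_to_hz(mel_pts)[1:-1]


def logmel(w: Waveform, config: MelConfig | None = None) -> Spectrogram:
    """Log-Mel spectrogram with ceil(n_samples / hop_samples) frames.

    The signal is zero-padded at the end so every sample is covered; the log
    is taken after adding a fixed floor so digital silence maps to log(floor).
    """
    if config is None:
        config = MelConfig()
    rate = w.rate
    if config.fmax > rate / 2:
        raise ValueError(f"fmax {config.fmax} Hz exceeds Nyquist {rate / 2} Hz")
    win = int(round(config.win_s * rate))
    hop = int(round(config.hop_s * rate))
    x = np.asarray(w.samples, dtype=np.float64)
    if len(x) < win:
        raise ValueError("waveform shorter than one STFT window")

    n_frames = math.ceil(len(x) / hop)
    need = (n_frames - 1) * hop + win
    if need > len(x):
        x = np.concatenate([x, np.zeros(need - len(x))])
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(win)[None, :]
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, win, rate, config.fmin, config.fmax)
    mel = power @ fb.T
    values = np.log(mel + LOG_FLOOR)
    frame_times = (np.arange(n_frames) * hop + win / 2) / rate
    return Spectrogram(values=values, frame_times=frame_times, config=config)


def window_stream(
    recording: Waveform,
    window: float = 3.0,
    hop: float = 1.5,
    config: MelConfig | None = None,
    source: str = "",
):
    """Slide a ``window``-second analysis window over a recording.

    Yields :class:`AnalysisWindow` covering every sample; for recordings of
    duration >= window the count is ``ceil((duration - window)/hop) + 1``.
    Shorter recordings produce a single zero-padded window flagged ``padded``.
    """
    if hop <= 0 or window < hop:
        raise ValueError("require window >= hop > 0")
    rate = recording.rate
    n = len(recording.samples)
    win_n = int(round(window * rate))
    hop_n = int(round(hop * rate))

    if n < win_n:
        x = np.concatenate([recording.samples, np.zeros(win_n - n)])
        spec = logmel(Waveform(samples=x, rate=rate), config)
        yield AnalysisWindow(source=source, start=0.0, end=window, spectrogram=spec, padded=True)
        return

    count = math.ceil((n - win_n) / hop_n) + 1
    for i in range(count):
        s = i * hop_n
        e = s + win_n
        padded = e > n
        seg = recording.samples[s:e]
        if padded:
            seg = np.concatenate([seg, np.zeros(e - n)])
        spec = logmel(Waveform(samples=seg, rate=rate), config)
        yield AnalysisWindow(
            source=source, start=s / rate, end=e / rate, spectrogram=spec, padded=padded
        )
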