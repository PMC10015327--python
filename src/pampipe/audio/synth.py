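"""Synthetic labelled soundscapes.

Generates whinny-like frequency-modulated calls, rainforest-style background
noise, scheduled multi-hour recordings and labelled clip sets, so the
detection and review stages can be exercised end to end without field audio.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "CallEvent",
    "LabelledClip",
    "synth_whinny",
    "synth_confounder",
    "synth_background",
    "render_recording",
    "make_clipset",
    "band_rms",
    "measure_snr_db",
]

#: band (Hz) used for SNR bookkeeping; brackets the whinny fundamental.
CALL_BAND = (500.0, 4000.0)

#: headroom ceiling: mixes must stay at or below -3 dBFS.
PEAK_CEILING = 10 ** (-3.0 / 20.0)


class ClippingError(ValueError):
    """Raised when a rendered mix would exceed the amplitude headroom."""


class PlacementError(ValueError):
    """Raised when an event does not fall inside any scheduled window."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def write(self, path: str) -> None:
        """Write as 16-bit PCM mono WAV."""
        peak = np.max(np.abs(self.samples)) if len(self.samples) else 0.0
        if peak > 1.0:
            raise ClippingError(f"waveform peaks at {peak:.3f} > 1.0")
        pcm = np.round(self.samples * 32767.0).astype(np.int16)
        wavfile.write(path, int(self.rate), pcm)

    @classmethod
    def read(cls, path: str) -> "Waveform":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if data.dtype == np.int16:
            samples = data.astype(np.float64) / 32767.0
        elif data.dtype == np.int32:
            samples = data.astype(np.float64) / 2147483647.0
        else:
            samples = data.astype(np.float64)
        return cls(samples=samples, rate=int(rate))


@dataclass(frozen=True)
class CallEvent:
    """A single acoustic event on the recording timeline.

    ``onset`` is in seconds from the recording start (day 0, 00:00).
    """

    onset: float
    duration: float
    kind: str  # {"whinny", "confounder"}
    snr_db: float

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.kind == "whinny" and not (0.3 <= self.duration <= 2.0):
            raise ValueError("whinny duration must be in [0.3, 2.0] s")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass
class LabelledClip:
    waveform: Waveform
    label: str  # {"positive", "negative"}
    site_id: str
    provenance: CallEvent | None = None
    clip_id: str = ""


def band_rms(samples: np.ndarray, rate: int, band: tuple[float, float] = CALL_BAND) -> float:
    """RMS of the component of ``samples`` inside ``band`` (FFT brick-wall)."""
    x = np.asarray(samples, dtype=np.float64)
    n = len(x)
    if n == 0:
        return 0.0
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = spec * mask
    y = np.fft.irfft(spec, n=n)
    return float(np.sqrt(np.mean(y**2)))


def measure_snr_db(
    mix: np.ndarray,
    background: np.ndarray,
    rate: int,
    band: tuple[float, float] = CALL_BAND,
) -> float:
    """Post-hoc SNR: band-limited RMS of (mix - background) over background."""
    sig = np.asarray(mix, dtype=np.float64) - np.asarray(background, dtype=np.float64)
    s = band_rms(sig, rate, band)
    b = band_rms(background, rate, band)
    if b == 0:
        return np.inf
    return 20.0 * np.log10(s / b)


def _envelope(n: int, rate: int, attack: float = 0.05, decay: float = 0.05) -> np.ndarray:
    env = np.ones(n)
    na = min(int(attack * rate), n // 2)
    nd = min(int(decay * rate), n // 2)
    if na > 0:
        env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    if nd > 0:
        env[n - nd :] = 0.5 * (1 + np.cos(np.pi * np.arange(nd) / nd))
    return env


def synth_whinny(
    f0_start: float = 700.0,
    f0_end: float = 3500.0,
    duration: float = 0.8,
    n_harmonics: int = 3,
    tremolo_rate: float = 10.0,
    rate: int = 48000,
    seed: int = 0,
) -> Waveform:
    """Render a whinny-like FM harmonic sweep with amplitude tremolo.

    The fundamental sweeps linearly from ``f0_start`` to ``f0_end``;
    ``n_harmonics`` partials with 1/k amplitudes ride on it. Deterministic
    for a fixed seed (the seed drives a small frequency wobble).
    """
    for f in (f0_start, f0_end):
        if not (200.0 <= f <= 8000.0):
            raise ValueError(f"fundamental {f} Hz outside [200, 8000]")
    if not (0.3 <= duration <= 2.0):
        raise ValueError(f"duration {duration} s outside [0.3, 2.0]")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    top = max(f0_start, f0_end) * n_harmonics
    if top >= rate / 2:
        raise ValueError(f"highest harmonic {top} Hz exceeds Nyquist ({rate / 2} Hz)")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f0 = f0_start + (f0_end - f0_start) * t / duration
    # gentle seeded wobble (<1.5% of f0) so calls are not all identical
    wobble = 1.0 + 0.015 * np.sin(2 * np.pi * rng.uniform(2, 5) * t + rng.uniform(0, 2 * np.pi))
    inst_f = f0 * wobble
    phase = 2 * np.pi * np.cumsum(inst_f) / rate

    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        x += np.sin(k * phase) / k
    if tremolo_rate > 0:
        trem = 1.0 + 0.5 * np.sin(2 * np.pi * tremolo_rate * t + rng.uniform(0, 2 * np.pi))
        x *= trem / 1.5
    x *= _envelope(n, rate)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return Waveform(samples=x, rate=rate)


def synth_confounder(
    duration: float = 0.8,
    rate: int = 48000,
    seed: int = 0,
    flavour: str = "reversed",
) -> Waveform:
    """A hard-negative call: FM sweep reversed in direction or shifted in band."""
    nyq = rate / 2.0
    if flavour == "reversed":
        n_harm = max(1, min(3, int((nyq * 0.95) // 3500.0)))
        return synth_whinny(3500.0, 700.0, duration, n_harmonics=n_harm, rate=rate, seed=seed)
    # bird-like: different (higher) band, single partial, faster tremolo
    f_lo = min(4000.0, 0.55 * nyq)
    f_hi = min(6000.0, 0.80 * nyq)
    return synth_whinny(
        f_lo, f_hi, duration, n_harmonics=1, tremolo_rate=20.0, rate=rate, seed=seed
    )


def synth_background(
    duration: float,
    rate: int = 48000,
    components: dict | None = None,
    seed: int = 0,
) -> Waveform:
    """Background bed: pink noise + narrowband insect tones + broadband transients.

    ``components`` keys (all optional):
      pink: {level: float RMS} — 1/f noise bed
      insects: list of {freq: Hz, level: RMS}
      transients: {rate_per_s: float, level: RMS}
    The total RMS matches the summed configured component levels in quadrature
    to within 5% (exact for pink-only).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if components is None:
        components = {"pink": {"level": 0.02}}
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = np.zeros(n)

    pink = components.get("pink")
    if pink:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        scale = np.ones_like(freqs)
        nz = freqs > 0
        scale[nz] = 1.0 / np.sqrt(freqs[nz])
        scale[0] = 0.0
        y = np.fft.irfft(spec * scale, n=n)
        y_rms = np.sqrt(np.mean(y**2))
        if y_rms > 0:
            x += y * (pink["level"] / y_rms)

    for ins in components.get("insects", []) or []:
        t = np.arange(n) / rate
        am = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(3, 8) * t)
        tone = np.sin(2 * np.pi * ins["freq"] * t + rng.uniform(0, 2 * np.pi)) * am / 1.3
        tone_rms = np.sqrt(np.mean(tone**2))
        x += tone * (ins["level"] / tone_rms)

    trans = components.get("transients")
    if trans and trans.get("rate_per_s", 0) > 0:
        n_events = rng.poisson(trans["rate_per_s"] * duration)
        for _ in range(n_events):
            start = rng.integers(0, max(1, n - int(0.05 * rate)))
            m = min(int(0.05 * rate), n - start)
            burst = rng.standard_normal(m) * _envelope(m, rate, 0.005, 0.03)
            b_rms = np.sqrt(np.mean(burst**2))
            if b_rms > 0:
                x[start : start + m] += burst * (trans["level"] / b_rms)

    peak = np.max(np.abs(x)) if n else 0.0
    if peak > PEAK_CEILING:
        raise ClippingError(f"background peaks at {peak:.3f} > {PEAK_CEILING:.3f}")
    return Waveform(samples=x, rate=rate)


def _mix_event(
    bed: np.ndarray, call: Waveform, start_idx: int, snr_db: float, rate: int
) -> None:
    """Mix ``call`` into ``bed`` in place at band-limited SNR ``snr_db``."""
    seg = bed[start_idx : start_idx + len(call.samples)]
    m = len(seg)
    c = call.samples[:m]
    bg_rms = band_rms(seg, rate)
    call_rms = band_rms(c, rate)
    if call_rms == 0:
        return
    if bg_rms == 0:
        bg_rms = 1e-6  # silent bed: anchor SNR to a nominal floor
    gain = (bg_rms * 10 ** (snr_db / 20.0)) / call_rms
    seg += gain * c
    peak = np.max(np.abs(seg))
    if peak > 1.0:
        raise ClippingError(f"mix peaks at {peak:.3f} > 1.0 (reduce SNR or bed level)")


# the published recording schedule: clock-hour windows, last crossing midnight
PAPER_SCHEDULE: tuple[tuple[float, float], ...] = ((5.0, 9.5), (14.0, 18.5), (21.0, 3.0))


def schedule_window_hours(schedule: Sequence[tuple[float, float]]) -> list[float]:
    """Duration in hours of each clock-time window (wrap past midnight)."""
    out = []
    for start, end in schedule:
        d = end - start
        if d <= 0:
            d += 24.0
        out.append(d)
    return out


def render_recording(
    schedule: Sequence[tuple[float, float]] = PAPER_SCHEDULE,
    events: Iterable[CallEvent] = (),
    rate: int = 48000,
    seed: int = 0,
    out_dir: str = ".",
    n_days: int = 1,
    site_id: str = "site0",
    background: dict | None = None,
) -> pd.DataFrame:
    """Render one WAV file per scheduled window per day, mixing in events.

    Events carry onsets in absolute timeline seconds (day 0 at 00:00).
    Returns the manifest (also written to ``out_dir/manifest.csv``) with
    columns file, onset_s (within file), duration_s, kind, snr_db, site_id.
    """
    os.makedirs(out_dir, exist_ok=True)
    events = list(events)
    durations_h = schedule_window_hours(schedule)

    # absolute [start, end) second spans of every (day, window)
    spans = []
    for day in range(n_days):
        for w, ((start_h, _), dur_h) in enumerate(zip(schedule, durations_h)):
            t0 = day * 86400.0 + start_h * 3600.0
            spans.append((day, w, t0, t0 + dur_h * 3600.0))

    placed: dict[int, list[tuple[CallEvent, float]]] = {i: [] for i in range(len(spans))}
    for ev in events:
        hit = None
        for i, (_, _, t0, t1) in enumerate(spans):
            if t0 <= ev.onset and ev.onset + ev.duration <= t1:
                hit = i
                break
        if hit is None:
            raise PlacementError(f"event at t={ev.onset}s does not fit any scheduled window")
        placed[hit].append((ev, ev.onset - spans[hit][2]))

    rows = []
    rng = np.random.default_rng(seed)
    for i, (day, w, t0, t1) in enumerate(spans):
        bed = synth_background(
            t1 - t0, rate=rate, components=background, seed=int(rng.integers(2**31))
        )
        samples = bed.samples.copy()
        fname = f"{site_id}_day{day}_win{w}.wav"
        for ev, offset in placed[i]:
            if ev.kind == "whinny":
                n_harm = max(1, min(3, int((rate / 2 * 0.95) // 3500.0)))
                call = synth_whinny(
                    duration=ev.duration, n_harmonics=n_harm, rate=rate,
                    seed=int(rng.integers(2**31)),
                )
            else:
                call = synth_confounder(duration=ev.duration, rate=rate, seed=int(rng.integers(2**31)))
            _mix_event(samples, call, int(round(offset * rate)), ev.snr_db, rate)
            rows.append(
                {
                    "file": fname,
                    "onset_s": round(offset, 6),
                    "duration_s": ev.duration,
                    "kind": ev.kind,
                    "snr_db": ev.snr_db,
                    "site_id": site_id,
                }
            )
        Waveform(samples=samples, rate=rate).write(os.path.join(out_dir, fname))

    manifest = pd.DataFrame(
        rows, columns=["file", "onset_s", "duration_s", "kind", "snr_db", "site_id"]
    )
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def make_clipset(
    n_pos: int,
    n_neg: int,
    hard_negative_fraction: float = 0.5,
    n_sites: int = 13,
    clip_length: float = 3.0,
    rate: int = 48000,
    snr_range: tuple[float, float] = (5.0, 25.0),
    seed: int = 0,
) -> list[LabelledClip]:
    """Build a labelled clip set with site ids assigned round-robin.

    Positives contain exactly one whinny at an SNR drawn from ``snr_range``
    (spanning faint calls when the range is wide); a ``hard_negative_fraction``
    of the negatives contain a confounder call instead of plain background.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("clip counts must be positive")
    if not (0.0 <= hard_negative_fraction <= 1.0):
        raise ValueError("hard_negative_fraction must be in [0, 1]")
    if clip_length < 2.0:
        raise ValueError("clip_length must be >= the maximum call duration (2.0 s)")

    rng = np.random.default_rng(seed)
    clips: list[LabelledClip] = []
    n_hard = int(round(hard_negative_fraction * n_neg))

    specs = [("positive", i) for i in range(n_pos)] + [("negative", i) for i in range(n_neg)]
    for j, (label, i) in enumerate(specs):
        site = f"site{j % n_sites:02d}"
        bed = synth_background(clip_length, rate=rate, seed=int(rng.integers(2**31)))
        samples = bed.samples.copy()
        prov = None
        if label == "positive":
            dur = float(rng.uniform(0.5, 1.0))
            snr = float(rng.uniform(*snr_range))
            onset = float(rng.uniform(0.1, clip_length - dur - 0.1))
            f0_end = float(rng.uniform(3000, 3800))
            max_harm = max(1, int((rate / 2 * 0.95) // f0_end))
            call = synth_whinny(
                f0_start=float(rng.uniform(600, 800)),
                f0_end=f0_end,
                duration=dur,
                n_harmonics=int(rng.integers(2, 5)) if max_harm >= 4 else min(max_harm, 3),
                tremolo_rate=float(rng.uniform(8, 12)),
                rate=rate,
                seed=int(rng.integers(2**31)),
            )
            _mix_event(samples, call, int(round(onset * rate)), snr, rate)
            prov = CallEvent(onset=onset, duration=dur, kind="whinny", snr_db=snr)
        elif i < n_hard:
            dur = float(rng.uniform(0.5, 1.0))
            snr = float(rng.uniform(*snr_range))
            onset = float(rng.uniform(0.1, clip_length - dur - 0.1))
            conf = synth_confounder(
                duration=dur,
                rate=rate,
                seed=int(rng.integers(2**31)),
                flavour="reversed" if rng.random() < 0.5 else "bird",
            )
            _mix_event(samples, conf, int(round(onset * rate)), snr, rate)
            prov = CallEvent(onset=onset, duration=dur, kind="confounder", snr_db=snr)
        clips.append(
            LabelledClip(
                waveform=Waveform(samples=samples, rate=rate),
                label=label,
                site_id=site,
                provenance=prov,
                clip_id=f"clip{j:05d}",
            )
        )
    return clips


def clipset_manifest(clips: Sequence[LabelledClip]) -> pd.DataFrame:
    rows = []
    for c in clips:
        p = c.provenance
        rows.append(
            {
                "clip_id": c.clip_id,
                "label": c.label,
                "site_id": c.site_id,
                "event_kind": p.kind if p else "",
                "event_onset_s": p.onset if p else np.nan,
                "event_duration_s": p.duration if p else np.nan,
                "event_snr_db": p.snr_db if p else np.nan,
            }
        )
    return pd.DataFrame(rows)
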