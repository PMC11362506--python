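"""Digital audio stimulus synthesis: tones, noise, gaps, AM, WAV export.

Levels are expressed in dB FS (decibels relative to digital full scale) and
are purely relative — nothing here knows about absolute SPL.  For pure tones
0 dB FS means peak amplitude 1.0; for noise the level is RMS-matched to a
full-scale sine (RMS = 10**(dBFS/20) / sqrt(2)), so a tone and a noise at
the same nominal level carry the same power.

The default sample rate is 48 kHz, the rate most playback chains run at;
44.1 kHz (CD standard) works equally.
"""

from __future__ import annotations

import math
import wave as _wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "Waveform",
    "ToneSpec",
    "NoiseSpec",
    "pure_tone",
    "white_noise",
    "apply_ramps",
    "insert_gap",
    "amplitude_modulate",
    "write_wav",
    "read_wav",
]

DEFAULT_SAMPLE_RATE = 48_000


@dataclass(frozen=True)
class Waveform:
    """Sampled mono audio with samples in [-1, 1]."""

    sample_rate: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def _n_samples(duration_ms: float, sample_rate: int) -> int:
    return round(duration_ms * sample_rate / 1000.0)


@dataclass(frozen=True)
class ToneSpec:
    """A pure tone: frequency (Hz), duration (ms), level (dB FS, peak), and
    raised-cosine onset/offset ramp duration (ms)."""

    frequency: float = 1000.0
    duration_ms: float = 250.0
    level_dbfs: float = -20.0
    ramp_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.level_dbfs > 0:
            raise ValueError("level_dbfs must be <= 0 (0 dB FS is full scale)")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be >= 0")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError("onset+offset ramps cannot exceed the duration")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian white noise: duration (ms), level (dB FS, RMS re full-scale
    sine), ramps (ms) and the seed that makes it reproducible."""

    duration_ms: float = 500.0
    level_dbfs: float = -20.0
    ramp_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.level_dbfs > 0:
            raise ValueError("level_dbfs must be <= 0 (0 dB FS is full scale)")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be >= 0")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError("onset+offset ramps cannot exceed the duration")


def pure_tone(spec: ToneSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Synthesize a ramped sine at peak amplitude 10**(level_dbfs/20)."""
    if spec.frequency >= sample_rate / 2:
        raise ValueError(
            f"frequency {spec.frequency} Hz is at or above the Nyquist limit "
            f"({sample_rate / 2} Hz): the tone would alias"
        )
    n = _n_samples(spec.duration_ms, sample_rate)
    t = np.arange(n) / sample_rate
    amp = 10.0 ** (spec.level_dbfs / 20.0)
    wave = Waveform(sample_rate, amp * np.sin(2.0 * math.pi * spec.frequency * t))
    return apply_ramps(wave, spec.ramp_ms)


def white_noise(spec: NoiseSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Seeded Gaussian white noise, RMS-matched to a full-scale sine at the
    given dB FS level and hard-limited to [-1, 1].  Same seed, same samples."""
    n = _n_samples(spec.duration_ms, sample_rate)
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(n)
    target_rms = 10.0 ** (spec.level_dbfs / 20.0) / math.sqrt(2.0)
    x *= target_rms / math.sqrt(np.mean(x**2))
    np.clip(x, -1.0, 1.0, out=x)
    return apply_ramps(Waveform(sample_rate, x), spec.ramp_ms)


def apply_ramps(wave: Waveform, ramp_ms: float) -> Waveform:
    """Gate the waveform on/off with raised-cosine ramps.

    The onset gain is g(t) = 0.5 * (1 - cos(pi * t / T_ramp)) for t in
    [0, T_ramp] — 0 at onset, 0.5 halfway, 1 at the plateau — mirrored at
    offset.  Plateau samples are untouched.
    """
    if ramp_ms < 0:
        raise ValueError("ramp_ms must be >= 0")
    n_ramp = _n_samples(ramp_ms, wave.sample_rate)
    if n_ramp == 0:
        return wave
    if 2 * n_ramp > len(wave):
        raise ValueError(
            f"{ramp_ms}-ms ramps do not fit a {wave.duration_ms:.1f}-ms waveform"
        )
    t = np.arange(n_ramp) / wave.sample_rate
    gain = 0.5 * (1.0 - np.cos(math.pi * t / (ramp_ms / 1000.0)))
    samples = wave.samples.copy()
    samples[:n_ramp] *= gain
    samples[len(samples) - n_ramp :] *= gain[::-1]
    return Waveform(wave.sample_rate, samples)


def insert_gap(wave: Waveform, gap_ms: float, position: str = "center") -> Waveform:
    """Silence a gap_ms-long window of the waveform (abrupt edges).

    The gap is centred at the waveform midpoint by default; output length
    equals input length (the gap replaces samples, it never shortens).
    """
    if gap_ms < 0:
        raise ValueError("gap_ms must be >= 0")
    if gap_ms == 0:
        return wave
    if gap_ms >= wave.duration_ms:
        raise ValueError(
            f"gap of {gap_ms} ms does not fit a {wave.duration_ms:.1f}-ms waveform"
        )
    n_gap = _n_samples(gap_ms, wave.sample_rate)
    if position == "center":
        start = round((len(wave) - n_gap) / 2)
    else:
        raise ValueError(f"unknown gap position {position!r}")
    samples = wave.samples.copy()
    samples[start : start + n_gap] = 0.0
    return Waveform(wave.sample_rate, samples)


def amplitude_modulate(
    wave: Waveform,
    depth_percent: float,
    mod_rate_hz: float = 20.0,
    mod_phase: float = 0.0,
    compensate: bool = True,
) -> Waveform:
    """Sinusoidally amplitude-modulate the waveform.

    y(t) = x(t) * (1 + m * sin(2*pi*f_mod*t + phase)) / (1 + m) with
    m = depth_percent / 100.  The division by (1 + m) keeps the output inside
    [-1, 1] regardless of depth; pass ``compensate=False`` for the raw
    (clipping-prone, level-preserving) modulator.  Depth 0 is an exact
    identity.
    """
    if not 0.0 <= depth_percent <= 100.0:
        raise ValueError(f"depth_percent must be in [0, 100], got {depth_percent}")
    m = depth_percent / 100.0
    if m == 0.0:
        return wave
    t = np.arange(len(wave)) / wave.sample_rate
    envelope = 1.0 + m * np.sin(2.0 * math.pi * mod_rate_hz * t + mod_phase)
    if compensate:
        envelope /= 1.0 + m
    return Waveform(wave.sample_rate, wave.samples * envelope)


def write_wav(wave: Waveform, path: str | Path) -> None:
    """Write 16-bit PCM mono WAV.  Samples outside [-1, 1] are an error, not
    a silent clip; a round-trip read reproduces samples to within 1 LSB."""
    peak = float(np.max(np.abs(wave.samples))) if len(wave) else 0.0
    if peak > 1.0:
        raise ValueError(
            f"samples exceed full scale (peak {peak:.4f}); refusing to clip"
        )
    quantized = np.round(wave.samples * 32767.0).astype("<i2")
    with _wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(wave.sample_rate)
        fh.writeframes(quantized.tobytes())


def read_wav(path: str | Path) -> Waveform:
    """Read a 16-bit PCM mono WAV back into a Waveform."""
    with _wave.open(str(path), "rb") as fh:
        if fh.getnchannels() != 1 or fh.getsampwidth() != 2:
            raise ValueError("only 16-bit PCM mono WAV files are supported")
        rate = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32767.0
    return Waveform(rate, samples)
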