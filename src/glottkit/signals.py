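"""Acoustic, electroglottographic (EGG) and glottal-area signal metrics.

Implements the voice-signal read-outs used to characterise high-pitched
phonation: autocorrelation fundamental-frequency (f_o) estimation in a
100 ms analysis window, the H1-H2 level difference between the first two
harmonics, equal-temperament pitch conversion, and the phase relation
between EGG (vocal fold contact) and the glottal area waveform (GAW).

All levels are relative dB (no sound pressure calibration is attempted).
Harmonic analysis is restricted to below a configurable aliasing guard
(default 4 kHz) because uncontrolled endoscopy-room recordings commonly
alias above that band at 20 kHz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "VoiceSignal",
    "HarmonicMetrics",
    "UnvoicedError",
    "estimate_f0_autocorr",
    "h1_h2",
    "pitch_to_freq",
    "freq_to_pitch",
    "egg_gaw_phase",
]

#: Default harmonic-analysis ceiling [Hz]; harmonics above it are not trusted.
ALIASING_GUARD_HZ = 4000.0


class UnvoicedError(ValueError):
    """Raised when a signal shows no usable periodicity in the search band."""


@dataclass
class VoiceSignal:
    """A sampled 1-D signal with its sampling rate and kind.

    ``kind`` distinguishes audio (microphone), egg (vocal fold contact)
    and gaw (glottal area waveform from imaging); the metrics below treat
    them identically.
    """

    samples: np.ndarray
    fs: float
    kind: Literal["audio", "egg", "gaw"] = "audio"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class HarmonicMetrics:
    """f_o plus first/second harmonic levels of one analysis window."""

    f_o: float
    h1_level: float  # dB, relative
    h2_level: float  # dB, relative
    h1_h2: float  # = h1_level - h2_level [dB]
    window: tuple[float, float]  # (start, length) in seconds


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location/height by parabolic fit through 3 points."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i), float(b)
    delta = 0.5 * (a - c) / denom
    return i + delta, b - 0.25 * (a - c) * delta


def estimate_f0_autocorr(
    sig: VoiceSignal,
    window_center: float | None = None,
    window_len: float = 0.1,
    f_min: float = 800.0,
    f_max: float = 2200.0,
    min_corr: float = 0.3,
) -> float:
    """Estimate f_o by normalized autocorrelation of a single window.

    The window defaults to 100 ms centred at the signal's temporal
    midpoint (midpoint +/- 50 ms).  The normalized autocorrelation is
    evaluated over lags corresponding to [f_min, f_max] and the highest
    peak is refined by parabolic interpolation, giving sub-sample period
    resolution (mandatory at ~13 samples per period for soprano pitches
    sampled at 20 kHz).

    Raises
    ------
    UnvoicedError
        If the best normalized correlation is below ``min_corr``.
    """
    if not f_min < f_max:
        raise ValueError(f"need f_min < f_max, got {f_min} >= {f_max}")
    x = sig.samples
    if window_center is None:
        window_center = sig.duration / 2.0
    n_win = int(round(window_len * sig.fs))
    start = int(round((window_center - window_len / 2.0) * sig.fs))
    start = max(0, min(start, x.size - n_win))
    if n_win > x.size:
        raise ValueError("analysis window longer than signal")
    seg = x[start : start + n_win] - np.mean(x[start : start + n_win])

    lag_min = max(1, int(np.floor(sig.fs / f_max)))
    lag_max = int(np.ceil(sig.fs / f_min))
    if lag_max + 1 >= n_win:
        raise ValueError("window too short for the requested f_min")

    # full autocorrelation via FFT, normalized to r[0]
    n_fft = int(2 ** np.ceil(np.log2(2 * n_win)))
    spec = np.fft.rfft(seg, n_fft)
    r = np.fft.irfft(spec * np.conj(spec))[: lag_max + 2]
    if r[0] <= 0:
        raise UnvoicedError("silent window")
    r = r / r[0]

    band = r[lag_min : lag_max + 1]
    i_best = int(np.argmax(band)) + lag_min
    # keep only genuine local maxima of the correlation function
    lag, peak = _parabolic_refine(r, i_best)
    if peak < min_corr:
        raise UnvoicedError(
            f"no periodicity: best normalized correlation {peak:.3f} < {min_corr}"
        )
    return float(sig.fs / lag)


def h1_h2(
    sig: VoiceSignal,
    f_o: float,
    window_center: float | None = None,
    window_len: float = 0.1,
    search_frac: float = 0.03,
    aliasing_guard: float = ALIASING_GUARD_HZ,
) -> HarmonicMetrics:
    """Level difference between the first and second harmonic, in dB.

    A Hann-windowed magnitude spectrum is computed on the analysis window
    and each harmonic level is the (parabolically refined) peak magnitude
    within +/- ``search_frac`` of k*f_o.  The second harmonic must lie
    below the aliasing guard.

    Raises
    ------
    ValueError
        If the window holds fewer than 20 cycles, if 2*f_o exceeds the
        aliasing guard or Nyquist, or if the harmonic search bands of H1
        and H2 collide (f_o unresolvable at this window length).
    """
    if f_o <= 0:
        raise ValueError("f_o must be positive")
    if 2 * f_o >= min(aliasing_guard, sig.fs / 2.0):
        raise ValueError(
            f"second harmonic {2 * f_o:.0f} Hz above analysis ceiling "
            f"{min(aliasing_guard, sig.fs / 2.0):.0f} Hz"
        )
    x = sig.samples
    if window_center is None:
        window_center = sig.duration / 2.0
    n_win = min(int(round(window_len * sig.fs)), x.size)
    start = int(round((window_center - window_len / 2.0) * sig.fs))
    start = max(0, min(start, x.size - n_win))
    if n_win * f_o / sig.fs < 20:
        raise ValueError("window must cover at least 20 cycles of f_o")
    df = sig.fs / n_win
    if f_o < 3 * df:
        raise ValueError("harmonic bins collide: f_o too low for window length")

    seg = x[start : start + n_win]
    seg = (seg - np.mean(seg)) * np.hanning(n_win)
    mag = np.abs(np.fft.rfft(seg))

    def harmonic_level(k: int) -> float:
        f_k = k * f_o
        i_lo = int(np.floor((1 - search_frac) * f_k / df))
        i_hi = int(np.ceil((1 + search_frac) * f_k / df)) + 1
        i_lo = max(1, i_lo)
        band = mag[i_lo:i_hi]
        i_pk = int(np.argmax(band)) + i_lo
        _, height = _parabolic_refine(mag, i_pk)
        return 20.0 * np.log10(max(height, 1e-300))

    h1 = harmonic_level(1)
    h2 = harmonic_level(2)
    return HarmonicMetrics(
        f_o=f_o,
        h1_level=h1,
        h2_level=h2,
        h1_h2=h1 - h2,
        window=(start / sig.fs, window_len),
    )


_NOTE_SEMITONES = {"C": -9, "D": -7, "E": -5, "F": -4, "G": -2, "A": 0, "B": 2}


def pitch_to_freq(note_name: str, a4: float = 440.0) -> float:
    """Frequency of a scientific-pitch note in 12-tone equal temperament.

    ``f = a4 * 2**(semitones_from_A4 / 12)``; e.g. G6 -> 1567.98 Hz
    (printed as 1568 Hz).
    """
    name = note_name.strip()
    if len(name) < 2:
        raise ValueError(f"malformed note name {note_name!r}")
    letter = name[0].upper()
    if letter not in _NOTE_SEMITONES:
        raise ValueError(f"malformed note name {note_name!r}")
    rest = name[1:]
    accidental = 0
    while rest and rest[0] in "#b♯♭":
        accidental += 1 if rest[0] in "#♯" else -1
        rest = rest[1:]
    try:
        octave = int(rest)
    except ValueError as exc:
        raise ValueError(f"malformed note name {note_name!r}") from exc
    semis = _NOTE_SEMITONES[letter] + accidental + 12 * (octave - 4)
    return a4 * 2.0 ** (semis / 12.0)


def freq_to_pitch(freq: float, a4: float = 440.0) -> tuple[str, float]:
    """Nearest equal-temperament note and the deviation from it in cents."""
    if freq <= 0:
        raise ValueError("frequency must be positive")
    semis = 12.0 * np.log2(freq / a4)
    nearest = int(np.round(semis))
    cents = 100.0 * (semis - nearest)
    # map semitone offset from A4 back to a note name (sharps preferred)
    names = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]
    idx = (nearest + 9) % 12
    octave = 4 + (nearest + 9) // 12
    return f"{names[idx]}{octave}", float(cents)


def egg_gaw_phase(egg: VoiceSignal, gaw: VoiceSignal, f_o: float) -> float:
    """Phase offset of EGG relative to GAW at f_o, in cycles in [-0.5, 0.5).

    Each signal's complex Fourier component at f_o is extracted by direct
    projection onto ``exp(-2j*pi*f_o*t)`` over an integer number of cycles;
    the returned value is the phase difference divided by 2*pi.  An EGG
    contact maximum coinciding with a glottal-area minimum — the hallmark
    of tissue-oscillation (MEAD) voice production — appears as an offset
    near +/-0.5 cycles (antiphase).

    Raises
    ------
    UnvoicedError
        If either signal carries negligible energy at f_o.
    """
    if f_o <= 0:
        raise ValueError("f_o must be positive")

    def component(sig: VoiceSignal) -> complex:
        x = sig.samples - np.mean(sig.samples)
        n_cycles = int(np.floor(x.size * f_o / sig.fs))
        if n_cycles < 1:
            raise UnvoicedError("signal shorter than one cycle of f_o")
        n = int(round(n_cycles * sig.fs / f_o))
        t = np.arange(n) / sig.fs
        c = np.sum(x[:n] * np.exp(-2j * np.pi * f_o * t)) / n
        rms = np.sqrt(np.mean(x[:n] ** 2))
        if rms == 0 or np.abs(c) < 1e-3 * rms:
            raise UnvoicedError("no energy at f_o")
        return c

    dphi = np.angle(component(egg)) - np.angle(component(gaw))
    cycles = dphi / (2 * np.pi)
    # wrap to [-0.5, 0.5)
    cycles = (cycles + 0.5) % 1.0 - 0.5
    return float(cycles)
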