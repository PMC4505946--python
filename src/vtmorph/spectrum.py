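"""Long-term average spectrum analysis and the Hammarberg index.

The LTAS integrates a Welch power-spectral-density estimate into contiguous
frequency bands ``[k*bw, (k+1)*bw)`` (250 Hz wide up to 5.5 kHz by default;
band edges are half-open, so 2000 Hz belongs to the band starting at 2 kHz).
The Hammarberg index (HI) is the level difference between the highest band
level below 2 kHz and the highest between 2 and 5 kHz; a prominent singer's
formant cluster near 3 kHz yields a low or negative HI.  The change between
phonation modes is ``delta_HI = HI_speech_like - HI_singing`` — large
positive values mean the cluster is much more prominent in singing.

The dB reference of absolute levels is arbitrary; only level differences
(HI, delta_HI, compensations) are meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile
from scipy.signal import welch

from .containers import LTASSpectrum

__all__ = [
    "compute_ltas",
    "loudness_compensate",
    "hammarberg_index",
    "HammarbergResult",
    "delta_hi",
    "read_wav",
    "write_wav",
]

#: Split frequency between the HI search ranges; belongs to the upper range.
HI_SPLIT_HZ = 2000.0
#: Upper edge of the HI high-frequency search range.
HI_TOP_HZ = 5000.0

_DB_FLOOR = -200.0


def compute_ltas(audio: np.ndarray, sample_rate: int,
                 band_width: float = 250.0, fmax: float = 5500.0,
                 nperseg: int = 4096, overlap: float = 0.5) -> LTASSpectrum:
    """Long-term average spectrum of a mono waveform.

    Welch-averages the PSD over the full signal (Hann window, configurable
    segment length and overlap) and integrates it into ``band_width``-wide
    bands up to ``fmax``.  Band levels are in dB re full scale; ``leq`` is
    the equivalent level (RMS in dB) of the same signal.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a mono 1D waveform")
    if sample_rate < 2 * fmax:
        raise ValueError(f"sample rate {sample_rate} below 2*fmax={2 * fmax}")
    if len(audio) < 0.5 * sample_rate:
        raise ValueError("audio shorter than 0.5 s")
    if len(audio) < nperseg:
        raise ValueError("audio shorter than one analysis window")
    rms = np.sqrt(np.mean(audio**2))
    if rms == 0:
        raise ValueError("silent signal has no spectrum levels")

    freqs, psd = welch(audio, fs=sample_rate, window="hann", nperseg=nperseg,
                       noverlap=int(nperseg * overlap))
    edges = np.arange(0.0, fmax + band_width / 2, band_width)
    df = freqs[1] - freqs[0]
    power = np.empty(len(edges) - 1)
    for k in range(len(edges) - 1):
        m = (freqs >= edges[k]) & (freqs < edges[k + 1])
        power[k] = psd[m].sum() * df
    levels = 10.0 * np.log10(np.maximum(power, 10.0 ** (_DB_FLOOR / 10.0)))
    leq = 20.0 * np.log10(rms)
    return LTASSpectrum(edges, levels, float(leq))


def loudness_compensate(ltas: LTASSpectrum, delta_leq: float,
                        gain_profile: np.ndarray) -> LTASSpectrum:
    """Compensate band levels for an equivalent-level difference.

    Each band level is shifted by its frequency-dependent gain factor times
    the equivalent-level difference: ``level'_k = level_k + gain_k *
    delta_leq``.  The gain factors quantify how much each band of a voice
    spectrum rises per dB of overall level increase (high bands gain more
    than low ones); they are an empirical, configuration-sensitive input and
    are deliberately not hard-coded.  ``leq`` is updated by the
    power-weighted mean shift so it stays consistent with the new levels.
    """
    gain = np.asarray(gain_profile, dtype=float)
    if gain.shape != ltas.levels.shape:
        raise ValueError(
            f"gain profile covers {gain.shape} bands, spectrum has {ltas.levels.shape}")
    new_levels = ltas.levels + gain * delta_leq
    w = 10.0 ** (ltas.levels / 10.0)
    leq = ltas.leq + float(np.average(gain * delta_leq, weights=w)) if w.sum() > 0 else ltas.leq
    return LTASSpectrum(ltas.band_edges.copy(), new_levels, leq)


def example_gain_profile(band_centers: np.ndarray, knee_hz: float = 1000.0) -> np.ndarray:
    """A documented example compensation profile (not an empirical fit).

    Unity gain below ``knee_hz`` rising linearly to 2.0 at 5.5 kHz —
    qualitatively, higher bands of voice spectra grow faster with vocal
    effort.  Supplied for demonstrations and tests; real analyses should
    pass a profile measured for their recording setup.
    """
    c = np.asarray(band_centers, dtype=float)
    return np.where(c <= knee_hz, 1.0, 1.0 + (c - knee_hz) / (5500.0 - knee_hz))


class HammarbergResult:
    """HI in dB plus the two contributing band peaks (Hz, dB)."""

    def __init__(self, hi: float, peak_low: tuple[float, float],
                 peak_high: tuple[float, float]):
        self.hi = hi
        self.peak_low = peak_low
        self.peak_high = peak_high

    def __repr__(self) -> str:  # pragma: no cover
        return (f"HammarbergResult(hi={self.hi:.2f} dB, "
                f"peak_low={self.peak_low}, peak_high={self.peak_high})")


def hammarberg_index(ltas: LTASSpectrum) -> HammarbergResult:
    """Hammarberg index of an LTAS.

    HI = (highest band level in [0, 2000) Hz) - (highest in [2000, 5000] Hz).
    Band membership follows the half-open band edges, so a band starting at
    2000 Hz counts toward the upper range.  The peak frequencies are
    reported alongside because the upper-range maximum need not be the
    singer's formant cluster.
    """
    lo_edges = ltas.band_edges[:-1]
    low = lo_edges < HI_SPLIT_HZ
    high = (lo_edges >= HI_SPLIT_HZ) & (lo_edges < HI_TOP_HZ)
    if not low.any() or not high.any():
        raise ValueError("LTAS bands must cover 0-5 kHz for the Hammarberg index")
    i_lo = np.flatnonzero(low)[np.argmax(ltas.levels[low])]
    i_hi = np.flatnonzero(high)[np.argmax(ltas.levels[high])]
    peak_low = (float(ltas.band_centers[i_lo]), float(ltas.levels[i_lo]))
    peak_high = (float(ltas.band_centers[i_hi]), float(ltas.levels[i_hi]))
    return HammarbergResult(peak_low[1] - peak_high[1], peak_low, peak_high)


def delta_hi(hi_speech: float, hi_singing: float) -> float:
    """Mode difference of the Hammarberg index, HI_speech-like - HI_singing.

    High values mean a much more prominent singer's formant cluster in
    singing than in the speech-like reference.
    """
    if not (np.isfinite(hi_speech) and np.isfinite(hi_singing)):
        raise ValueError("Hammarberg indices must be finite")
    return float(hi_speech - hi_singing)


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file to a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(rate)


def write_wav(path, audio: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a float waveform as 16-bit PCM WAV."""
    clipped = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (clipped * 32767).astype(np.int16))
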