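"""Resting-state power spectra, ROI averages, alpha peak and band power.

Spectra are segment-averaged periodograms (Welch's method: 4 s cosine-
tapered segments, 50% overlap by default), restricted to the 0.5–30 Hz
analysis range.  Band sums use half-open frequency intervals
``[low, high)`` so that adjacent bands partition the analysis range
exactly and their relative powers sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import Recording

ANALYSIS_BAND = (0.5, 30.0)
ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (15.0, 30.0)


@dataclass
class Spectrum:
    """Power spectral density per channel (or per ROI after averaging)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs) or (n_freqs,) after ROI averaging
    channels: tuple[str, ...] | None
    segment_length_s: float
    method: str
    roi: str | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def channel_power(self, label: str) -> np.ndarray:
        if self.channels is None:
            raise ValueError("spectrum already ROI-averaged")
        return self.power[self.channels.index(label)]


@dataclass
class SpectralPeak:
    """Automatically selected spectral peak within a frequency band."""

    frequency_hz: float
    power: float
    band_hz: tuple[float, float]
    found: bool


def compute_spectrum(
    rec: Recording,
    band: tuple[float, float] = ANALYSIS_BAND,
    segment_length_s: float = 4.0,
    *,
    overlap: float = 0.5,
    window: str = "hann",
) -> Spectrum:
    """Welch periodogram per channel, restricted to ``band``.

    The estimator satisfies Parseval's relation: the integral of the
    full-range density over frequency equals the windowed signal variance.
    """
    nperseg = int(round(segment_length_s * rec.fs))
    if rec.n_samples < 2 * nperseg:
        raise ValueError(
            f"recording ({rec.duration_s:.1f} s) shorter than two "
            f"{segment_length_s} s segments")
    freqs, power = sps.welch(rec.signal, fs=rec.fs, window=window,
                             nperseg=nperseg, noverlap=int(nperseg * overlap),
                             axis=-1)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return Spectrum(freqs[keep], power[:, keep], rec.channels,
                    segment_length_s,
                    f"welch({window},{segment_length_s}s,{overlap:.0%} overlap)")


def roi_average(s: Spectrum, roi: Sequence[str], name: str | None = None) -> Spectrum:
    """Unweighted mean of power across ROI channels, per frequency."""
    if s.channels is None:
        raise ValueError("spectrum already ROI-averaged")
    missing = [c for c in roi if c not in s.channels]
    if missing:
        raise KeyError(f"channels missing from spectrum: {missing}")
    idx = [s.channels.index(c) for c in roi]
    power = s.power[idx].mean(axis=0)
    return replace(s, power=power, channels=None,
                   roi=name or "+".join(roi))


def _as_1d(s: Spectrum) -> np.ndarray:
    if s.power.ndim != 1:
        raise ValueError("ROI-average the spectrum first")
    return s.power


def alpha_peak(s: Spectrum, band: tuple[float, float] = ALPHA_BAND) -> SpectralPeak:
    """Largest interior local maximum of power within the band.

    Monotone spectra (e.g. pure 1/f) have no interior maximum and return
    ``found=False``.
    """
    p = _as_1d(s)
    f = s.freqs
    if band[0] < f[0] or band[1] > f[-1]:
        raise ValueError(f"band {band} outside spectrum range ({f[0]}-{f[-1]} Hz)")
    k = np.arange(1, len(p) - 1)
    interior = k[(p[k] > p[k - 1]) & (p[k] >= p[k + 1])]
    interior = interior[(f[interior] >= band[0]) & (f[interior] <= band[1])]
    if len(interior) == 0:
        return SpectralPeak(np.nan, np.nan, band, False)
    best = interior[np.argmax(p[interior])]
    return SpectralPeak(float(f[best]), float(p[best]), band, True)


def relative_band_power(
    s: Spectrum,
    band: tuple[float, float] = BETA_BAND,
    total: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Fraction of power in ``band`` relative to ``total`` (half-open bins)."""
    if band[0] < total[0] or band[1] > total[1]:
        raise ValueError(f"band {band} not contained in total range {total}")
    p = _as_1d(s)
    f = s.freqs
    in_band = (f >= band[0]) & (f < band[1])
    in_total = (f >= total[0]) & (f < total[1])
    denom = p[in_total].sum()
    if denom <= 0:
        raise ValueError("zero total power in the normalisation range")
    return float(p[in_band].sum() / denom)
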