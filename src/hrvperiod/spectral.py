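"""Power-spectral-density periodicity measures.

A periodic RR-interval series concentrates its spectral power in a narrow
band; an aperiodic one spreads it.  This module quantifies that contrast on
the Lomb-Scargle periodogram of the (unevenly sampled) series restricted to
a periodicity band (default 0.3-2 Hz, excluding very-low-frequency trends):

* ``max_per`` -- the peak of the band-normalized relative power spectrum;
* ``trse``   -- the transformed Relative Shannon Entropy
  ``1 + sum_i P(i) ln P(i) / ln M`` over M equal-width frequency bins,
  1 for a narrowband (periodic) spectrum and 0 for a uniform one.

RR values enter the periodogram at their own beat times, the standard
treatment for beat-indexed series, so no resampling onto a uniform grid is
ever needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle as _scipy_lombscargle

from .dataio import RRSeries, UniformSignal, ValidationError

logger = logging.getLogger("hrvperiod")

__all__ = [
    "Periodogram",
    "RelativePowerSpectrum",
    "BinnedSpectrum",
    "lomb_scargle",
    "default_freq_grid",
    "relative_spectrum",
    "max_per",
    "trse",
    "bin_spectrum",
    "sliding_spectrogram",
    "DegenerateSpectrumError",
]

DEFAULT_BAND = (0.3, 2.0)
DEFAULT_OVERSAMPLE = 4


class DegenerateSpectrumError(ValueError):
    """No in-band power: the spectrum cannot be normalized."""


@dataclass(frozen=True)
class Periodogram:
    """Classical Lomb-Scargle periodogram on a strictly increasing grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)
        if len(f) != len(p):
            raise ValidationError("freqs and power length mismatch")
        if np.any(np.diff(f) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(p < -1e-12):
            raise ValidationError("negative periodogram power")


@dataclass(frozen=True)
class RelativePowerSpectrum:
    """Band-limited periodogram normalized to unit total power.

    With the default in-band normalization the relative powers sum to 1
    exactly; the full-spectrum variant sums to at most 1.
    """

    freqs: np.ndarray
    relpower: np.ndarray
    band: tuple[float, float]
    normalized_in_band: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.relpower, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "relpower", p)
        if self.normalized_in_band and abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("relative power must sum to 1")
        if p.sum() > 1.0 + 1e-9:
            raise ValidationError("relative power cannot exceed 1 in total")
        if np.any(p < 0):
            raise ValidationError("negative relative power")


@dataclass(frozen=True)
class BinnedSpectrum:
    """Relative power aggregated into M equal-width frequency bins P(i)."""

    bin_edges: np.ndarray
    bin_power: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        p = np.asarray(self.bin_power, dtype=float)
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "bin_power", p)
        if len(e) != len(p) + 1 or len(p) < 2:
            raise ValidationError("need M >= 2 bins and M+1 edges")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("binned power must sum to 1")


def lomb_scargle(times: np.ndarray, values: np.ndarray,
                 freq_grid: np.ndarray) -> Periodogram:
    """Classical Lomb-Scargle periodogram of mean-centered ``values``.

    ``times`` must be strictly increasing but need not be uniform.  For
    uniformly sampled input the peak locations agree with an FFT
    periodogram; for gapped input the estimator remains unbiased, which is
    why it is the standard choice for beat-indexed RR series.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if len(times) < 4:
        raise ValidationError("need at least 4 samples for a periodogram")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(freq_grid <= 0):
        raise ValidationError("frequency grid must be strictly positive")
    centered = values - values.mean()
    power = _scipy_lombscargle(times, centered, 2.0 * np.pi * freq_grid)
    return Periodogram(freq_grid, np.maximum(power, 0.0))


def default_freq_grid(duration: float, band: tuple[float, float] = DEFAULT_BAND,
                      oversample: int = DEFAULT_OVERSAMPLE) -> np.ndarray:
    """Inclusive grid over ``band`` with spacing 1/(oversample * duration)."""
    lo, hi = band
    df = 1.0 / (oversample * duration)
    n = int(np.floor((hi - lo) / df)) + 1
    grid = lo + df * np.arange(n)
    if grid[-1] < hi - 1e-12:
        grid = np.append(grid, hi)
    return grid


def relative_spectrum(pg: Periodogram,
                      band: tuple[float, float] = DEFAULT_BAND,
                      normalization: str = "band") -> RelativePowerSpectrum:
    """Drop frequencies outside ``band`` and normalize the rest.

    Very-low-frequency components (below the band) carry slow trends and
    would swamp the periodicity measures, so they are excluded before
    normalization.  With ``normalization="band"`` (the default) the
    in-band powers are divided by their own sum and form a probability
    distribution over the band, which is what the entropy argument behind
    tRSE assumes; ``"full"`` divides by the total power of the whole
    periodogram instead (sensitivity-analysis variant, renormalized
    downstream where a distribution is required).
    """
    lo, hi = band
    mask = (pg.freqs >= lo) & (pg.freqs <= hi)
    if not np.any(mask):
        raise ValidationError("periodogram does not cover the requested band")
    freqs = pg.freqs[mask]
    power = pg.power[mask]
    if normalization == "band":
        total = power.sum()
    elif normalization == "full":
        total = pg.power.sum()
    else:
        raise ValidationError("normalization must be 'band' or 'full'")
    if total <= 0 or power.sum() <= 0:
        raise DegenerateSpectrumError("zero in-band power")
    return RelativePowerSpectrum(freqs, power / total, (lo, hi),
                                 normalized_in_band=(normalization == "band"))


def max_per(rs: RelativePowerSpectrum) -> float:
    """Peak of the relative power spectrum; in (0, 1]."""
    return float(rs.relpower.max())


def bin_spectrum(rs: RelativePowerSpectrum, n_bins: int = 20) -> BinnedSpectrum:
    """Aggregate relative power into ``n_bins`` equal-width frequency bins."""
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    lo, hi = rs.band
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, rs.freqs, side="right") - 1, 0, n_bins - 1)
    power = np.bincount(idx, weights=rs.relpower, minlength=n_bins)
    return BinnedSpectrum(edges, power / power.sum())


def trse(rs: RelativePowerSpectrum, n_bins: int = 20) -> float:
    """Transformed Relative Shannon Entropy of the binned relative spectrum.

    ``tRSE = 1 + sum_i P(i) ln P(i) / ln M`` with ``0 ln 0 := 0``; 1 means
    all power in a single bin (narrowband/periodic), 0 means power uniform
    across bins (broadband/aperiodic).
    """
    bs = bin_spectrum(rs, n_bins)
    p = bs.bin_power
    nz = p[p > 0]
    value = 1.0 + float(np.sum(nz * np.log(nz))) / np.log(len(p))
    # clamp tiny negative round-off; the entropy bound guarantees [0, 1]
    return float(min(max(value, 0.0), 1.0))


def sliding_spectrogram(times: np.ndarray, values: np.ndarray,
                        window_s: float, step_s: float,
                        freq_grid: np.ndarray) -> list[tuple[float, Periodogram]]:
    """Lomb-Scargle periodogram per overlapping window.

    Returns ``(center_time, Periodogram)`` pairs with centers spaced
    ``step_s``; windows holding fewer than 4 samples are skipped with a
    warning.  Useful for time-frequency maps of nonstationary RR series
    (e.g. tracking a varying ventilator frequency).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    duration = times[-1] - times[0]
    if window_s > duration:
        logger.warning("record (%.1f s) shorter than window (%.1f s)", duration, window_s)
        return []
    out: list[tuple[float, Periodogram]] = []
    start = times[0]
    while start + window_s <= times[-1] + 1e-9:
        mask = (times >= start) & (times < start + window_s)
        center = start + window_s / 2.0
        if mask.sum() < 4:
            logger.warning("window at %.1f s has <4 samples; skipped", center)
        else:
            out.append((center, lomb_scargle(times[mask], values[mask], freq_grid)))
        start += step_s
    return out


def rr_periodogram(rr: RRSeries, band: tuple[float, float] = DEFAULT_BAND,
                   oversample: int = DEFAULT_OVERSAMPLE) -> Periodogram:
    """Band-limited periodogram of an RR series at its own beat times."""
    grid = default_freq_grid(rr.duration, band, oversample)
    return lomb_scargle(rr.beat_times, rr.rr, grid)


def signal_periodogram(sig: UniformSignal, band: tuple[float, float] = DEFAULT_BAND,
                       oversample: int = DEFAULT_OVERSAMPLE) -> Periodogram:
    grid = default_freq_grid(sig.duration, band, oversample)
    return lomb_scargle(sig.times, sig.values, grid)
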