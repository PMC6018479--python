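"""Signal-to-scalar wrappers for the five periodicity measures.

Each function maps a raw :class:`~hrvperiod.dataio.UniformSignal` or
:class:`~hrvperiod.dataio.RRSeries` to one number with the package's
default pipeline (0.3-2 Hz band, 20 entropy bins, piecewise-linear
detrending, ACF scoring lags 25-50, FNN/MI-selected embedding with
r = 0.4 SD).  These are the callables fed to the monotonicity benchmark.
"""

from __future__ import annotations

import numpy as np

from .acf import (ACFSeries, autocorrelation, detrend_piecewise, max_acf,
                  mean_acf, se_acf, select_embedding)
from .dataio import RRSeries, RunConfig, UniformSignal
from .spectral import (RelativePowerSpectrum, relative_spectrum,
                       rr_periodogram, signal_periodogram, max_per, trse)

__all__ = [
    "trse_of", "max_per_of", "max_acf_of", "mean_acf_of", "se_acf_of",
    "periodicity_measures",
]

Signal = UniformSignal | RRSeries


def _relspec(sig: Signal, config: RunConfig) -> RelativePowerSpectrum:
    if isinstance(sig, RRSeries):
        pg = rr_periodogram(sig, config.spectral_band)
    else:
        pg = signal_periodogram(sig, config.spectral_band)
    return relative_spectrum(pg, config.spectral_band)


def _acfseries(sig: Signal, config: RunConfig) -> ACFSeries:
    ds = detrend_piecewise(sig)
    return autocorrelation(ds)


def trse_of(sig: Signal, config: RunConfig = RunConfig()) -> float:
    return trse(_relspec(sig, config), config.trse_bins)


def max_per_of(sig: Signal, config: RunConfig = RunConfig()) -> float:
    return max_per(_relspec(sig, config))


def max_acf_of(sig: Signal, config: RunConfig = RunConfig()) -> float:
    return max_acf(_acfseries(sig, config), config.acf_d_range)


def mean_acf_of(sig: Signal, config: RunConfig = RunConfig()) -> float:
    return mean_acf(_acfseries(sig, config), config.acf_d_range)


def se_acf_of(sig: Signal, config: RunConfig = RunConfig()) -> float:
    acf = _acfseries(sig, config)
    choice = select_embedding(acf, tolerance_factor=config.se_acf_tolerance_factor)
    value = se_acf(acf, choice)
    if value is None:
        raise ValueError("SE.ACF undefined: no template matches")
    return value


def periodicity_measures(config: RunConfig = RunConfig()) -> dict:
    """The five periodicity measures as name -> callable(signal)."""
    return {
        "tRSE": lambda s: trse_of(s, config),
        "maxPER": lambda s: max_per_of(s, config),
        "maxACF": lambda s: max_acf_of(s, config),
        "meanACF": lambda s: mean_acf_of(s, config),
        "SE.ACF": lambda s: se_acf_of(s, config),
    }
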