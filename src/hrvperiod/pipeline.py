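"""Per-epoch analysis: run every measure on each epoch of an RR series and
collect the results as IndicesRecord rows ready for tabulation (and for a
downstream repeated-measures comparison, which is out of this package's
hands by design).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from . import acf as _acf
from . import hrv as _hrv
from . import measures as _measures
from .dataio import IndicesRecord, RRSeries, RunConfig
from .ecg import segment_epochs
from .hrv import BandDefinition
from .spectral import rr_periodogram

logger = logging.getLogger("hrvperiod")

__all__ = ["analyze_epoch", "analyze_series"]


def analyze_epoch(rr: RRSeries, epoch_id: int,
                  config: RunConfig = RunConfig()) -> IndicesRecord:
    """All periodicity and conventional HRV indices for one epoch.

    Any measure that cannot be computed on this epoch is flagged missing
    with the failure reason; nothing is silently NaN.
    """
    rec = IndicesRecord(epoch_id=epoch_id, label=rr.label)

    def _try(name: str, fn) -> None:
        try:
            rec.set(name, fn(), reason="undefined")
        except Exception as exc:  # noqa: BLE001 - reason string per contract
            rec.missing[name] = str(exc)
            logger.info("epoch %d: %s missing (%s)", epoch_id, name, exc)

    # periodicity battery
    _try("tRSE", lambda: _measures.trse_of(rr, config))
    _try("maxPER", lambda: _measures.max_per_of(rr, config))
    _try("maxACF", lambda: _measures.max_acf_of(rr, config))
    _try("meanACF", lambda: _measures.mean_acf_of(rr, config))
    _try("SE.ACF", lambda: _measures.se_acf_of(rr, config))

    # conventional battery
    _try("SDNN", lambda: _hrv.sdnn(rr))
    _try("RMSSD", lambda: _hrv.rmssd(rr))
    _try("TriIdx", lambda: _hrv.triangular_index(rr))

    lf = BandDefinition("LF", *config.lf_band)
    hf = BandDefinition("HF", *config.hf_band)
    total = BandDefinition("total", config.lf_band[0], config.hf_band[1])

    def _freq_domain() -> dict[str, float]:
        pg = rr_periodogram(rr, band=(total.low, total.high), oversample=4)
        lf_rel = _hrv.band_relative_power(pg, lf, total)
        hf_rel = _hrv.band_relative_power(pg, hf, total)
        return {"LF": lf_rel, "HF": hf_rel,
                "LHR": lf_rel / hf_rel if hf_rel > 0 else np.nan}

    try:
        for name, v in _freq_domain().items():
            rec.set(name, v, reason="HF power is zero" if name == "LHR" else "")
    except Exception as exc:  # noqa: BLE001
        for name in ("LF", "HF", "LHR"):
            rec.missing[name] = str(exc)

    def _poincare() -> None:
        sd1, sd2, ratio = _hrv.poincare(rr)
        rec.set("SD1", sd1)
        rec.set("SD2", sd2)
        rec.set("SDRatio", ratio, reason="SD2 is zero")

    try:
        _poincare()
    except Exception as exc:  # noqa: BLE001
        for name in ("SD1", "SD2", "SDRatio"):
            rec.missing[name] = str(exc)

    def _dfa() -> None:
        a1, a2 = _hrv.dfa(rr)
        rec.set("alpha1", a1)
        rec.set("alpha2", a2)

    try:
        _dfa()
    except Exception as exc:  # noqa: BLE001
        rec.missing["alpha1"] = rec.missing["alpha2"] = str(exc)

    _try("SampEn", lambda: _hrv.sample_entropy(
        rr.rr, m=config.sampen_m,
        r=config.sampen_r_factor * _hrv.sdnn(rr)))
    return rec


def analyze_series(rr: RRSeries, config: RunConfig = RunConfig(),
                   labels: dict[str, tuple[float, float]] | None = None
                   ) -> list[IndicesRecord]:
    """Epoch an RR series and analyze each epoch."""
    epochs = segment_epochs(rr, config.epoch_length, labels)
    return [analyze_epoch(ep, i, config) for i, ep in enumerate(epochs)]
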