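"""File formats, run configuration, and domain containers.

All analysis modules consume the types defined here.  RR intervals are
stored in milliseconds and beat times in seconds throughout the package;
any unit conversion happens at the file boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hrvperiod")

__all__ = [
    "RRSeries",
    "UniformSignal",
    "RunConfig",
    "IndicesRecord",
    "read_rr_series",
    "write_indices_table",
    "read_indices_table",
    "read_signal",
    "write_signal",
    "load_config",
    "ValidationError",
    "ParseError",
]

#: RR must agree with successive beat-time differences to this tolerance (ms).
RR_CONSISTENCY_TOL_MS = 0.5


class ValidationError(ValueError):
    """Input violates a structural invariant (non-monotone times, RR <= 0, ...)."""


class ParseError(ValueError):
    """A text file could not be parsed; message names the offending line."""


@dataclass(frozen=True)
class RRSeries:
    """Beat-time-stamped RR-interval series.

    Parameters
    ----------
    beat_times : array of float
        Seconds since record start, strictly increasing.
    rr : array of float
        RR intervals in milliseconds, one per beat, all positive.
    label : str
        Free-text period tag (e.g. ``"Bsln"``, ``"V1"``, ``"Rcvry"``).
    """

    beat_times: np.ndarray
    rr: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr", rr)
        if bt.ndim != 1 or rr.ndim != 1 or len(bt) != len(rr):
            raise ValidationError("beat_times and rr must be 1-d and equally long")
        d = np.diff(bt)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0)) + 1
            raise ValidationError(f"beat_times not strictly increasing at index {i}")
        if np.any(rr <= 0):
            i = int(np.argmax(rr <= 0))
            raise ValidationError(f"non-positive RR interval at index {i}")
        # consistency: an interval can never exceed the time elapsed since
        # the previous retained beat.  (It may be *shorter* -- artifact
        # exclusion removes beats and leaves gaps -- so the check is
        # one-sided.)
        if len(rr) > 1:
            excess = rr[1:] - d * 1000.0
            if np.any(excess > RR_CONSISTENCY_TOL_MS):
                i = int(np.argmax(excess > RR_CONSISTENCY_TOL_MS)) + 1
                raise ValidationError(
                    f"rr[{i}] exceeds the beat-time difference by "
                    f"{excess[i - 1]:.3f} ms (> {RR_CONSISTENCY_TOL_MS} ms)"
                )

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def duration(self) -> float:
        """Record span in seconds (first to last beat)."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def with_label(self, label: str) -> "RRSeries":
        return RRSeries(self.beat_times, self.rr, label)


@dataclass(frozen=True)
class UniformSignal:
    """Uniformly sampled real signal (raw ECG, simulated oscillator output)."""

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if v.ndim != 1 or len(v) < 2:
            raise ValidationError("signal needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.sampling_rate


@dataclass
class RunConfig:
    """Analysis constants.

    Defaults follow conventional rodent HRV practice: 2.5-min epochs, the
    0.3-2 Hz periodicity band with 20 spectral-entropy bins, autocorrelation
    lags 25-50 beats, SampEn with m=2 / r=0.2*SDNN, and LF/HF bands of
    0.1-1 / 1-3.5 Hz.
    """

    epoch_length: float = 150.0
    spectral_band: tuple[float, float] = (0.3, 2.0)
    trse_bins: int = 20
    acf_d_range: tuple[int, int] = (25, 50)
    se_acf_tolerance_factor: float = 0.4
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    lf_band: tuple[float, float] = (0.1, 1.0)
    hf_band: tuple[float, float] = (1.0, 3.5)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spectral_band", "lf_band", "hf_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must satisfy low < high")
        lo, hi = self.acf_d_range
        if not (0 < lo < hi):
            raise ValidationError("acf_d_range must satisfy 0 < low < high")
        if self.trse_bins < 2 or self.sampen_m < 1:
            raise ValidationError("counts must be positive (trse_bins >= 2)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: Canonical column order of the per-epoch indices table.
MEASURE_NAMES = (
    "tRSE", "maxPER", "maxACF", "meanACF", "SE.ACF",
    "SDNN", "RMSSD", "TriIdx", "LF", "HF", "LHR",
    "SD1", "SD2", "SDRatio", "alpha1", "alpha2", "SampEn",
)


@dataclass
class IndicesRecord:
    """One per-epoch row of measure results.

    A measure that could not be computed is *flagged* (with a reason) rather
    than silently set to NaN.
    """

    epoch_id: int
    label: str = ""
    values: dict[str, float] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: float | None, reason: str = "") -> None:
        if value is None or not np.isfinite(value):
            self.missing[name] = reason or "not finite"
        else:
            self.values[name] = float(value)

    def get(self, name: str) -> float | None:
        return self.values.get(name)


def _sniff_delimiter(line: str) -> str | None:
    """Pick the delimiter from the first data line: comma, tab or whitespace."""
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # split on any whitespace


def _parse_numeric_rows(path: Path) -> tuple[list[list[float]], str | None]:
    rows: list[list[float]] = []
    delim: str | None = None
    first = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if first:
                delim = _sniff_delimiter(line)
                first = False
            parts = line.split(delim) if delim else line.split()
            try:
                rows.append([float(p) for p in parts if p != ""])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value on line {lineno}: {line!r}") from exc
    return rows, delim


def read_rr_series(path: str | Path, dialect: str = "auto", label: str = "") -> RRSeries:
    """Read an RR-interval series from delimited text.

    Two dialects are supported: ``"two-column"`` files hold beat time in
    seconds and RR in milliseconds; ``"single-column"`` files hold RR in
    milliseconds only, and beat times are reconstructed as the cumulative sum
    of RR/1000 starting at ``rr[0]/1000``.  ``"auto"`` picks by column count.
    """
    path = Path(path)
    rows, _ = _parse_numeric_rows(path)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ParseError(f"{path}: inconsistent column counts")
    if dialect == "auto":
        dialect = "two-column" if ncols >= 2 else "single-column"
    if dialect == "two-column":
        if ncols < 2:
            raise ParseError(f"{path}: two-column dialect requires 2 columns")
        arr = np.asarray(rows, dtype=float)
        return RRSeries(arr[:, 0], arr[:, 1], label)
    rr = np.asarray([r[0] for r in rows], dtype=float)
    if np.any(rr <= 0):
        i = int(np.argmax(rr <= 0))
        raise ValidationError(f"{path}: non-positive RR interval at row {i}")
    beat_times = np.cumsum(rr) / 1000.0
    return RRSeries(beat_times, rr, label)


def write_indices_table(records: Sequence[IndicesRecord], path: str | Path) -> None:
    """Write per-epoch measure rows as a TSV table; missing values become "NA".

    Round-trips through :func:`read_indices_table` unchanged to 12
    significant digits.
    """
    if not records:
        raise ValidationError("cannot write an empty indices table")
    names = [n for n in MEASURE_NAMES
             if any(n in r.values or n in r.missing for r in records)]
    # preserve any non-canonical measure names too, in first-seen order
    for r in records:
        for n in list(r.values) + list(r.missing):
            if n not in names:
                names.append(n)
    with open(path, "w") as fh:
        fh.write("epoch_id\tlabel\t" + "\t".join(names) + "\n")
        for r in records:
            cells = [str(r.epoch_id), r.label]
            for n in names:
                v = r.values.get(n)
                cells.append("NA" if v is None else format(v, ".12g"))
            fh.write("\t".join(cells) + "\n")


def read_indices_table(path: str | Path) -> list[IndicesRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    records = []
    for _, row in df.iterrows():
        rec = IndicesRecord(epoch_id=int(row["epoch_id"]),
                            label="" if pd.isna(row["label"]) else str(row["label"]))
        for name in df.columns:
            if name in ("epoch_id", "label"):
                continue
            v = row[name]
            if pd.isna(v):
                rec.missing[name] = "NA in file"
            else:
                rec.values[name] = float(v)
        records.append(rec)
    return records


def read_signal(path: str | Path, sampling_rate: float) -> UniformSignal:
    """Read a single-column numeric trace sampled at ``sampling_rate`` Hz."""
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    rows, _ = _parse_numeric_rows(Path(path))
    values = np.asarray([r[0] for r in rows], dtype=float)
    if len(values) < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    return UniformSignal(values, sampling_rate)


def write_signal(signal: UniformSignal, path: str | Path) -> None:
    np.savetxt(path, signal.values, fmt="%.10g")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON (field names mirror the dataclass)."""
    with open(path) as fh:
        data = json.load(fh)
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return RunConfig(**kwargs)


def log_run(config: RunConfig, seed: int | None = None, **extra) -> None:
    """Structured log line making a stochastic run replayable."""
    logger.info("run config_hash=%s seed=%s %s", config.config_hash(),
                seed if seed is not None else config.rng_seed,
                " ".join(f"{k}={v}" for k, v in extra.items()))
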