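"""Degree-of-monotonicity benchmark.

A good variability measure should respond monotonically to the control
parameter (the oscillator's noise level C).  For a measure matrix
S[i, k] -- r noise levels by k realizations -- every pair of levels i < j
is compared with a two-sided Wilcoxon rank-sum test at level alpha:

    h(i, j) = +1  if rejected with row j stochastically larger,
              -1  if rejected with row j stochastically smaller,
               0  otherwise,

and the degree of monotonicity is

    M = | 2 / (r (r - 1)) * sum_{i<j} h(i, j) |  in [0, 1],

1 meaning a perfectly monotone response in either direction (the absolute
value makes increasing and decreasing measures score alike) and 0 no
ordering.  Being rank-based, M is invariant under any strictly monotone
transform of the measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dataio import ValidationError
from .synth import SignalEnsemble

logger = logging.getLogger("hrvperiod")

__all__ = [
    "MeasureMatrix",
    "MonotonicityResult",
    "measure_over_ensemble",
    "pairwise_h",
    "degree_of_monotonicity",
    "benchmark_all",
]

DEFAULT_ALPHA = 0.05
#: exact rank-sum null distribution up to this per-group size, normal
#: approximation beyond
EXACT_N_MAX = 25


@dataclass(frozen=True)
class MeasureMatrix:
    """One measure evaluated over a signal ensemble: rows = noise levels."""

    c_values: tuple[float, ...]
    values: np.ndarray  # shape (r, k)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != len(self.c_values):
            raise ValidationError("measure matrix shape mismatch")
        if not np.all(np.isfinite(v)):
            raise ValidationError("measure matrix contains non-finite cells")


@dataclass(frozen=True)
class MonotonicityResult:
    h: np.ndarray  # r x r upper-triangular, entries in {-1, 0, +1}
    m: float
    alpha: float


def measure_over_ensemble(ens: SignalEnsemble,
                          measure: Callable[..., float]) -> MeasureMatrix:
    """Evaluate ``measure(signal)`` over every ensemble cell.

    Individual failures are logged with their (i, k) index; more than 10%
    failures aborts with a summary.  A failed cell is never imputed --
    instead the whole noise level (row i) is excluded from the matrix with
    a logged warning.
    """
    r, k = len(ens.c_values), ens.n_realizations
    values = np.full((r, k), np.nan)
    failures: list[tuple[int, int, str]] = []
    for i in range(r):
        for kk in range(k):
            try:
                values[i, kk] = measure(ens.signals[i][kk])
            except Exception as exc:  # noqa: BLE001 - user-supplied measure
                failures.append((i, kk, str(exc)))
                logger.warning("measure failed at (i=%d, k=%d): %s", i, kk, exc)
    if len(failures) > 0.10 * r * k:
        raise RuntimeError(
            f"measure failed on {len(failures)}/{r * k} cells; first: {failures[0]}")
    if failures:
        bad_rows = sorted({i for i, _, _ in failures})
        logger.warning("excluding incomplete noise levels (rows) %s", bad_rows)
        keep = np.array([i not in bad_rows for i in range(r)])
        return MeasureMatrix(
            tuple(c for i, c in enumerate(ens.c_values) if keep[i]),
            values[keep])
    return MeasureMatrix(ens.c_values, values)


def _ranksum_h(row_i: np.ndarray, row_j: np.ndarray, alpha: float) -> int:
    if np.ptp(row_i) == 0 and np.ptp(row_j) == 0 and row_i[0] == row_j[0]:
        logger.info("identical constant rows: rank-sum test degenerate, h=0")
        return 0
    n1, n2 = len(row_i), len(row_j)
    method = "exact" if max(n1, n2) <= EXACT_N_MAX else "asymptotic"
    try:
        res = stats.mannwhitneyu(row_i, row_j, alternative="two-sided",
                                 method=method)
    except ValueError:
        res = stats.mannwhitneyu(row_i, row_j, alternative="two-sided",
                                 method="asymptotic")
    if res.pvalue >= alpha:
        return 0
    # direction from the rank statistic: U > n1*n2/2 means row_i larger
    return -1 if res.statistic > n1 * n2 / 2.0 else +1


def pairwise_h(s: MeasureMatrix, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Signed rank-sum outcomes h(i, j) for every noise-level pair i < j."""
    if not 0 < alpha < 0.5:
        raise ValidationError("alpha must lie in (0, 0.5)")
    if s.values.shape[1] < 3:
        raise ValidationError("need >= 3 realizations per noise level")
    r = s.values.shape[0]
    h = np.zeros((r, r), dtype=int)
    for i in range(r - 1):
        for j in range(i + 1, r):
            h[i, j] = _ranksum_h(s.values[i], s.values[j], alpha)
    return h


def degree_of_monotonicity(h: np.ndarray, r: int | None = None) -> float:
    """``M = |2 / (r(r-1)) * sum_{i<j} h(i,j)|``, in [0, 1]."""
    if r is None:
        r = h.shape[0]
    if r < 2:
        raise ValidationError("need r >= 2 noise levels")
    iu = np.triu_indices(r, k=1)
    return float(abs(2.0 * h[iu].sum() / (r * (r - 1))))


def monotonicity_of(s: MeasureMatrix, alpha: float = DEFAULT_ALPHA) -> MonotonicityResult:
    h = pairwise_h(s, alpha)
    return MonotonicityResult(h, degree_of_monotonicity(h), alpha)


def benchmark_all(ens: SignalEnsemble,
                  measures: Mapping[str, Callable[..., float]],
                  alpha: float = DEFAULT_ALPHA) -> dict[str, float]:
    """Degree of monotonicity per measure over one ensemble."""
    out: dict[str, float] = {}
    for name, fn in measures.items():
        matrix = measure_over_ensemble(ens, fn)
        out[name] = monotonicity_of(matrix, alpha).m
        logger.info("M(%s) = %.3f", name, out[name])
    return out
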