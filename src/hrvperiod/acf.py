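"""Autocorrelation-based periodicity measures.

The autocorrelation function (ACF) of a periodic series is itself periodic;
that of a broadband series decays quickly and stays flat.  The pipeline is:

1. piecewise-linear detrending via change-point segmentation (slow drifts in
   the RR baseline would otherwise masquerade as long-range correlation);
2. the beat-lag autocorrelation ``R(d) = 1/(N-d) * sum_n xhat_n xhat_{n+d}``
   of the standardized residuals, with lag d counted in heart beats;
3. ``max_acf`` / ``mean_acf``: max and mean of |R(d)| over d = 25..50;
4. ``se_acf``: the sample entropy of the ACF itself, with pattern length m
   chosen by false nearest neighbours, delay tau by the first minimum of
   the mutual information, and tolerance r = 0.4 * SD of the ACF values.
   A regular (periodic) autocorrelogram gives SE.ACF near 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import RRSeries, UniformSignal, ValidationError
from .hrv import sample_entropy

logger = logging.getLogger("hrvperiod")

__all__ = [
    "DetrendedSeries",
    "ACFSeries",
    "EmbeddingChoice",
    "detrend_piecewise",
    "autocorrelation",
    "max_acf",
    "mean_acf",
    "select_embedding",
    "se_acf",
    "DegenerateSeriesError",
]

DEFAULT_D_RANGE = (25, 50)
#: ACF lag ceiling: min(N//2, MAX_LAG).  200 lags comfortably contain the
#: d = 25-50 scoring window plus several oscillation periods at rodent
#: heart rates.
MAX_LAG = 200
DEFAULT_MIN_SEGMENT = 30


class DegenerateSeriesError(ValueError):
    """Constant (zero-variance) series: ACF undefined."""


@dataclass(frozen=True)
class DetrendedSeries:
    """Residuals after piecewise-linear trend removal."""

    values: np.ndarray
    segment_bounds: np.ndarray  # change-point indices incl. 0 and N
    mu: float
    sigma: float


@dataclass(frozen=True)
class ACFSeries:
    """Lag-indexed autocorrelation values R(d), d = 0..D, in beats."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.values):
            raise ValidationError("lags and values length mismatch")
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValidationError("R(0) must equal 1")


@dataclass(frozen=True)
class EmbeddingChoice:
    """Delay-embedding parameters for the ACF sample entropy."""

    m: int
    tau: int
    r: float

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1 or self.r <= 0:
            raise ValidationError("need m >= 1, tau >= 1, r > 0")


# ---------------------------------------------------------------------------
# piecewise-linear detrending

def _line_rss(x: np.ndarray, prefix: dict, lo: int, hi: int) -> float:
    """Residual sum of squares of the OLS line on x[lo:hi] in O(1)."""
    n = hi - lo
    s1 = prefix["t"][hi] - prefix["t"][lo]
    s2 = prefix["t2"][hi] - prefix["t2"][lo]
    sy = prefix["y"][hi] - prefix["y"][lo]
    sy2 = prefix["y2"][hi] - prefix["y2"][lo]
    sty = prefix["ty"][hi] - prefix["ty"][lo]
    det = n * s2 - s1 * s1
    if det <= 0:
        return 0.0
    slope = (n * sty - s1 * sy) / det
    intercept = (sy - slope * s1) / n
    return float(sy2 - 2 * slope * sty - 2 * intercept * sy
                 + slope * slope * s2 + 2 * slope * intercept * s1
                 + n * intercept * intercept)


def _best_split(x: np.ndarray, prefix: dict, lo: int, hi: int,
                min_segment: int) -> tuple[int | None, float]:
    base = _line_rss(x, prefix, lo, hi)
    best_gain, best_k = 0.0, None
    for k in range(lo + min_segment, hi - min_segment + 1):
        gain = base - _line_rss(x, prefix, lo, k) - _line_rss(x, prefix, k, hi)
        if gain > best_gain:
            best_gain, best_k = gain, k
    return best_k, best_gain


def detrend_piecewise(series: RRSeries | UniformSignal | np.ndarray,
                      penalty: float | None = None,
                      min_segment: int = DEFAULT_MIN_SEGMENT) -> DetrendedSeries:
    """Remove a piecewise-linear trend found by binary segmentation.

    Change points are inserted greedily wherever splitting a segment into
    two separately fitted lines reduces the residual sum of squares by more
    than ``penalty``.  The default penalty is BIC-like: ``3 * log(N) *
    sigma2`` per split (three extra parameters: slope, intercept, break
    location), with ``sigma2`` a robust noise estimate from first
    differences, ``var(diff(x))/2``.  Each segment's OLS line is then
    subtracted.
    """
    if isinstance(series, RRSeries):
        x = series.rr.astype(float)
    elif isinstance(series, UniformSignal):
        x = series.values.astype(float)
    else:
        x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2 * min_segment:
        logger.warning("series of %d < 2*min_segment=%d: single-segment detrend",
                       n, 2 * min_segment)
        t = np.arange(n, dtype=float)
        coeffs = np.polyfit(t, x, 1) if n > 1 else (0.0, x[0] if n else 0.0)
        resid = x - np.polyval(coeffs, t)
        return DetrendedSeries(resid, np.array([0, n]), float(resid.mean()),
                               float(resid.std()))

    t = np.arange(n, dtype=float)
    prefix = {
        "t": np.concatenate([[0.0], np.cumsum(t)]),
        "t2": np.concatenate([[0.0], np.cumsum(t * t)]),
        "y": np.concatenate([[0.0], np.cumsum(x)]),
        "y2": np.concatenate([[0.0], np.cumsum(x * x)]),
        "ty": np.concatenate([[0.0], np.cumsum(t * x)]),
    }
    if penalty is None:
        sigma2 = float(np.var(np.diff(x)) / 2.0) if n > 2 else 0.0
        penalty = 3.0 * np.log(n) * max(sigma2, 1e-12)

    bounds = [0, n]
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_segment:
            continue
        k, gain = _best_split(x, prefix, lo, hi, min_segment)
        if k is not None and gain > penalty:
            bounds.append(k)
            stack.extend([(lo, k), (k, hi)])
    bounds = np.array(sorted(bounds))

    resid = np.empty_like(x)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg_t = t[lo:hi]
        coeffs = np.polyfit(seg_t, x[lo:hi], 1)
        resid[lo:hi] = x[lo:hi] - np.polyval(coeffs, seg_t)
    return DetrendedSeries(resid, bounds, float(resid.mean()), float(resid.std()))


# ---------------------------------------------------------------------------
# autocorrelation

def autocorrelation(ds: DetrendedSeries | np.ndarray,
                    max_lag: int | None = None) -> ACFSeries:
    """Beat-lag autocorrelation ``R(d) = 1/(N-d) sum xhat_n xhat_{n+d}``.

    Residuals are standardized with the population (1/N) SD so that
    R(0) = 1 exactly.  The 1/(N-d) normalization can push |R(d)| slightly
    above 1 at large lags; the scoring window d = 25..50 sits well below
    that regime.
    """
    x = ds.values if isinstance(ds, DetrendedSeries) else np.asarray(ds, dtype=float)
    n = len(x)
    sigma = float(np.std(x))  # population SD
    if sigma == 0:
        raise DegenerateSeriesError("constant residuals: ACF undefined")
    if max_lag is None:
        max_lag = min(n // 2, MAX_LAG)
    if max_lag >= n:
        raise ValidationError("max_lag must be < N")
    xhat = (x - x.mean()) / sigma
    full = np.correlate(xhat, xhat, mode="full")[n - 1:]
    lags = np.arange(max_lag + 1)
    values = full[: max_lag + 1] / (n - lags)
    return ACFSeries(lags, values)


def _check_range(acf: ACFSeries, d_range: tuple[int, int]) -> np.ndarray:
    lo, hi = d_range
    if lo < acf.lags[0] or hi > acf.lags[-1]:
        raise ValidationError(f"lag range {d_range} outside computed lags")
    mask = (acf.lags >= lo) & (acf.lags <= hi)
    return np.abs(acf.values[mask])


def max_acf(acf: ACFSeries, d_range: tuple[int, int] = DEFAULT_D_RANGE) -> float:
    """Max of |R(d)| over the scoring window (endpoints inclusive)."""
    return float(_check_range(acf, d_range).max())


def mean_acf(acf: ACFSeries, d_range: tuple[int, int] = DEFAULT_D_RANGE) -> float:
    """Mean of |R(d)| over the scoring window (endpoints inclusive)."""
    return float(_check_range(acf, d_range).mean())


# ---------------------------------------------------------------------------
# embedding selection (MI delay + FNN dimension) and SE.ACF

def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _first_mi_minimum(values: np.ndarray, max_tau: int, bins: int) -> int | None:
    mi = [_mutual_information(values[:-t], values[t:], bins)
          for t in range(1, max_tau + 1)]
    for i in range(1, len(mi) - 1):
        if mi[i] < mi[i - 1] and mi[i] <= mi[i + 1]:
            return i + 1
    return None


def _fnn_fraction(x: np.ndarray, m: int, tau: int, ratio: float) -> float:
    """False-nearest-neighbour fraction for embedding dimension m.

    A nearest neighbour is false if adding the (m+1)-th delay coordinate
    stretches the pair by more than ``ratio`` relative to its m-dim
    distance (distance-ratio criterion).  Pairs at exactly zero m-dim
    distance with diverging continuations are counted false as well.
    """
    n_vec = len(x) - m * tau  # leave room for the (m+1)-th coordinate
    if n_vec < 10:
        return 0.0
    sigma = float(np.std(x))
    emb = np.lib.stride_tricks.sliding_window_view(
        x, (m - 1) * tau + 1)[:n_vec, ::tau]
    d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    dist_m = d[np.arange(n_vec), nn]
    extra = np.abs(x[np.arange(n_vec) + m * tau] - x[nn + m * tau])
    # distances at round-off scale are duplicates, not genuine neighbours;
    # the ratio test on them would amplify floating-point noise
    duplicate = dist_m <= 1e-9 * sigma
    false = np.where(~duplicate, extra > ratio * dist_m,
                     extra > 1e-6 * sigma)
    return float(false.mean())


def select_embedding(acf: ACFSeries, fnn_threshold: float = 0.05,
                     max_m: int = 10, mi_bins: int = 8,
                     fnn_ratio: float = 10.0, min_m: int = 2,
                     tolerance_factor: float = 0.4) -> EmbeddingChoice:
    """Choose (m, tau, r) for the ACF sample entropy.

    tau is the first local minimum of the histogram mutual information
    between R(d) and R(d+tau) over tau = 1..D/4 (fallback 1 if the MI has
    no interior minimum); m is the smallest dimension >= ``min_m`` whose
    false-nearest-neighbour fraction drops below ``fnn_threshold``
    (distance-ratio test, default ratio 10), capped at ``max_m``; r is
    ``tolerance_factor`` times the population SD of the ACF values.

    Two numerical choices matter on short (~200 lag) autocorrelograms: the
    MI histogram is deliberately coarse (8 bins -- finer binning saturates
    the estimate and flattens its minimum), and the FNN scan starts at
    ``min_m`` = 2 because one delay coordinate can never unfold an
    oscillation, yet sampled periodic ACFs contain exact duplicates that
    blind the distance-ratio test in one dimension.
    """
    v = acf.values
    if float(np.std(v)) == 0:
        raise DegenerateSeriesError("constant ACF: embedding undefined")
    max_tau = max(2, len(v) // 4)
    tau = _first_mi_minimum(v, max_tau, mi_bins)
    if tau is None:
        logger.info("no interior MI minimum; falling back to tau=1")
        tau = 1
    m = max_m
    for cand in range(min_m, max_m + 1):
        if len(v) <= (cand + 1) * tau + 10:
            m = max(min_m, cand - 1)
            break
        if _fnn_fraction(v, cand, tau, fnn_ratio) < fnn_threshold:
            m = cand
            break
    r = tolerance_factor * float(np.std(v))
    return EmbeddingChoice(m=m, tau=tau, r=r)


def se_acf(acf: ACFSeries, choice: EmbeddingChoice | None = None) -> float | None:
    """Sample entropy of the autocorrelation function.

    Near 0 for a regular (periodic) autocorrelogram, larger when the cycle
    length varies.  Returns ``None`` when the entropy is undefined (no
    template matches).
    """
    if choice is None:
        choice = select_embedding(acf)
    return sample_entropy(acf.values, m=choice.m, r=choice.r, tau=choice.tau)
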