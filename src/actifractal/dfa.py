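"""Detrended fluctuation analysis with a two-regime scaling-exponent fit.

DFA-1: the signal is centered and integrated into a profile, the profile is
cut into disjoint windows of ``m`` samples, a linear trend is removed in each
window, and ``F(m)`` is the root-mean-square residual pooled over all windowed
points.  A power law ``F(m) ∝ m^α`` indicates fractal scaling; α = 0.5 for
uncorrelated noise, α > 0.5 for persistent correlations, α = 1.5 for Brownian
motion.

For actigraphy of subjects with disrupted fractal regulation the fluctuation
function breaks into two regimes.  Two exponents are therefore fitted on
distinct time ranges — α1 on 3–90 min and α2 on 120–720 min — and their
difference α12 = α1 − α2 (and |α12|) quantifies the break-down of mono-fractal
scaling over the full range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, InsufficientDataError, ParameterError
from .series import ActivityCountSeries

logger = logging.getLogger(__name__)

#: Default fit ranges in minutes (endpoints inclusive).
SHORT_RANGE_MIN = (3.0, 90.0)
LONG_RANGE_MIN = (120.0, 720.0)

#: Default grid: 66 log-spaced window sizes from 3 to 720 minutes.
N_GRID = 66
GRID_MIN_MINUTES = 3.0
GRID_MAX_MINUTES = 720.0

#: A window must hold at least this many samples and at most N/4 of the series.
MIN_WINDOW = 4


@dataclass
class FluctuationFunction:
    """F(m) evaluated on a grid of window sizes.

    ``window_epochs`` are the window sizes in samples of the analyzed series;
    ``window_minutes`` is the same grid on the time axis (``epochs·delta/60``).
    """

    window_epochs: np.ndarray
    window_minutes: np.ndarray
    F: np.ndarray
    delta: int | None = None


@dataclass
class DFAResult:
    """Two-regime scaling exponents and their difference."""

    alpha1: float
    alpha2: float
    alpha12: float
    abs_alpha12: float
    short_range: tuple[float, float] = SHORT_RANGE_MIN
    long_range: tuple[float, float] = LONG_RANGE_MIN
    intercept1: float = float("nan")
    intercept2: float = float("nan")
    resid1: float = float("nan")
    resid2: float = float("nan")


def dfa_fluctuation(x: np.ndarray, window_sizes: np.ndarray) -> np.ndarray:
    """DFA-1 fluctuation function of a plain series, window sizes in samples.

    Windows are taken forward from the start of the profile; the remainder
    beyond ``floor(N/m)·m`` points is discarded.  Residuals from the per-window
    least-squares linear trend are pooled into a single RMS per window size.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("input series must be one-dimensional")
    if x.size < 2 * MIN_WINDOW:
        raise InsufficientDataError("series too short for DFA")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series: F ≡ 0, scaling exponent undefined")
    profile = np.cumsum(x - x.mean())
    n = profile.size
    out = np.empty(len(window_sizes), dtype=float)
    for j, m in enumerate(np.asarray(window_sizes, dtype=int)):
        if m < MIN_WINDOW or m > n // 4:
            raise ParameterError(
                f"window size {m} outside the usable range [{MIN_WINDOW}, {n // 4}]"
            )
        k = n // m
        seg = profile[: k * m].reshape(k, m)
        t = np.arange(m, dtype=float)
        tc = t - t.mean()
        denom = float(tc @ tc)
        slope = (seg @ tc) / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tc
        out[j] = np.sqrt(np.mean(resid * resid))
    return out


def default_window_grid(delta: int) -> np.ndarray:
    """66 log-spaced window sizes from 3 to 720 min, aligned to whole epochs.

    Each nominal size is rounded to an integer number of epochs at resolution
    ``delta``; collisions are pushed up to the next free epoch count so the
    grid stays strictly increasing (all 66 entries survive at every canonical
    ``delta``).  Returned in minutes.
    """
    nominal = np.geomspace(GRID_MIN_MINUTES, GRID_MAX_MINUTES, N_GRID)
    epochs = np.rint(nominal * 60.0 / delta).astype(int)
    epochs = np.maximum(epochs, 1)
    for i in range(1, epochs.size):
        if epochs[i] <= epochs[i - 1]:
            epochs[i] = epochs[i - 1] + 1
    return epochs * delta / 60.0


def fluctuation_function(
    counts: ActivityCountSeries,
    window_sizes_min: np.ndarray | None = None,
) -> FluctuationFunction:
    """Fluctuation function of a count series on a grid given in minutes.

    Window sizes that are not realizable at resolution ``delta`` (fewer than
    4 epochs, or more than a quarter of the series) are dropped with a log
    notice.
    """
    delta = counts.delta
    if window_sizes_min is None:
        window_sizes_min = default_window_grid(delta)
    window_sizes_min = np.asarray(window_sizes_min, dtype=float)
    x = counts.counts.astype(float)
    if x.size == 0:
        raise InsufficientDataError("empty count series")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series: F ≡ 0, scaling exponent undefined")
    epochs = np.unique(np.rint(window_sizes_min * 60.0 / delta).astype(int))
    usable = (epochs >= MIN_WINDOW) & (epochs <= x.size // 4)
    if not np.all(usable):
        dropped = epochs[~usable] * delta / 60.0
        logger.info(
            "dropping %d window size(s) not realizable at delta=%ds: %s min",
            dropped.size, delta, np.round(dropped, 2).tolist(),
        )
    epochs = epochs[usable]
    if epochs.size == 0:
        raise InsufficientDataError(
            f"no usable window sizes; usable epoch range is "
            f"[{MIN_WINDOW}, {x.size // 4}] at delta={delta}s"
        )
    F = dfa_fluctuation(x, epochs)
    return FluctuationFunction(
        window_epochs=epochs,
        window_minutes=epochs * delta / 60.0,
        F=F,
        delta=delta,
    )


def _fit_range(
    fluct: FluctuationFunction, lo: float, hi: float, name: str
) -> tuple[float, float, float]:
    mask = (fluct.window_minutes >= lo) & (fluct.window_minutes <= hi)
    if np.count_nonzero(mask) < 3:
        raise InsufficientDataError(
            f"fewer than 3 grid points inside the {name} range [{lo}, {hi}] min"
        )
    lx = np.log10(fluct.window_minutes[mask])
    ly = np.log10(fluct.F[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def fit_two_regime(
    fluct: FluctuationFunction,
    short_range: tuple[float, float] = SHORT_RANGE_MIN,
    long_range: tuple[float, float] = LONG_RANGE_MIN,
) -> DFAResult:
    """OLS slopes of log10 F vs log10 m on the short and long ranges (inclusive)."""
    a1, c1, r1 = _fit_range(fluct, *short_range, name="short")
    a2, c2, r2 = _fit_range(fluct, *long_range, name="long")
    return DFAResult(
        alpha1=a1,
        alpha2=a2,
        alpha12=a1 - a2,
        abs_alpha12=abs(a1 - a2),
        short_range=tuple(short_range),
        long_range=tuple(long_range),
        intercept1=c1,
        intercept2=c2,
        resid1=r1,
        resid2=r2,
    )


def analyze(counts: ActivityCountSeries, **kwargs) -> tuple[FluctuationFunction, DFAResult]:
    """Convenience wrapper: fluctuation function plus two-regime fit."""
    fluct = fluctuation_function(counts)
    return fluct, fit_two_regime(fluct, **kwargs)
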