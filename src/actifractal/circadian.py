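"""Non-parametric circadian rest–activity metrics (Van Someren family).

All metrics are computed on hourly mean counts, which makes them independent
of the source epoch length:

* IS (inter-daily stability): variance of the average 24 h profile over total
  variance — 1 when every day repeats the same profile, ≈ 1/n_days for noise;
* IV (intra-daily variability): mean squared successive difference over
  variance — ≈ 2 for white noise, small for a smooth rhythm;
* M10 / L5: mean activity of the most active 10 consecutive hours and the
  quietest 5 consecutive hours of the average day (circular windows), with
  their onsets in clock hours;
* RA (relative amplitude): (M10 − L5)/(M10 + L5) ∈ [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateSeriesError, InsufficientDataError, ParameterError
from .series import ActivityCountSeries

HOURS_PER_DAY = 24
M10_HOURS = 10
L5_HOURS = 5


@dataclass
class CircadianMetrics:
    IS: float
    IV: float
    RA: float
    M10: float
    L5: float
    M10_onset: int
    L5_onset: int


def hourly_aggregate(counts: ActivityCountSeries) -> pd.Series:
    """Mean count per clock hour; partial leading/trailing hours are dropped."""
    delta = counts.delta
    if 3600 % delta:
        raise ParameterError(f"epoch length {delta}s does not divide one hour")
    per_hour = 3600 // delta
    start = counts.start_time
    first_full = start.ceil("h")
    lead_seconds = (first_full - start).total_seconds()
    if lead_seconds % delta:
        raise ParameterError("start time is not aligned to the epoch grid")
    offset = int(lead_seconds // delta)
    n_hours = (len(counts) - offset) // per_hour
    if n_hours < 1:
        raise InsufficientDataError("series shorter than one full clock hour")
    block = counts.counts[offset : offset + n_hours * per_hour].astype(float)
    hourly = block.reshape(n_hours, per_hour).mean(axis=1)
    index = first_full + pd.to_timedelta(np.arange(n_hours), unit="h")
    return pd.Series(hourly, index=index, name="hourly_mean")


def _circular_window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Mean of each ``width``-hour window of a 24 h profile, wrapping midnight."""
    tiled = np.concatenate([profile, profile[: width - 1]])
    kernel = np.ones(width) / width
    return np.convolve(tiled, kernel, mode="valid")[:HOURS_PER_DAY]


def circadian_metrics(counts: ActivityCountSeries) -> CircadianMetrics:
    """IS, IV, RA, M10 (and L5 with both onsets) of a count series.

    Requires at least two complete 24 h days after hourly aggregation.
    """
    hourly = hourly_aggregate(counts)
    x = hourly.to_numpy()
    n = x.size
    if n < 2 * HOURS_PER_DAY:
        raise InsufficientDataError(
            f"need ≥ 2 complete days ({2 * HOURS_PER_DAY} hourly values), got {n}"
        )
    total_ss = float(((x - x.mean()) ** 2).sum())
    if total_ss == 0.0:
        raise DegenerateSeriesError("constant hourly series: IS and IV undefined")

    hour_of_day = hourly.index.hour.to_numpy()
    profile = np.array(
        [x[hour_of_day == h].mean() for h in range(HOURS_PER_DAY)]
    )
    is_num = float(((profile - x.mean()) ** 2).sum())
    IS = (n * is_num) / (HOURS_PER_DAY * total_ss)
    IV = (n * float((np.diff(x) ** 2).sum())) / ((n - 1) * total_ss)

    m10_windows = _circular_window_means(profile, M10_HOURS)
    l5_windows = _circular_window_means(profile, L5_HOURS)
    m10_onset = int(np.argmax(m10_windows))
    l5_onset = int(np.argmin(l5_windows))
    M10 = float(m10_windows[m10_onset])
    L5 = float(l5_windows[l5_onset])
    RA = (M10 - L5) / (M10 + L5) if (M10 + L5) > 0 else float("nan")
    return CircadianMetrics(
        IS=float(IS), IV=float(IV), RA=float(RA),
        M10=M10, L5=L5, M10_onset=m10_onset, L5_onset=l5_onset,
    )
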