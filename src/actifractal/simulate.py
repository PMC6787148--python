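"""Synthetic actigraphy with known fractal, circadian and duration structure.

Every downstream stage of the pipeline is testable by parameter recovery on
the output of this module:

* :func:`generate_fractal_noise` — spectral synthesis of Gaussian noise whose
  DFA fluctuation function follows a prescribed scaling exponent, optionally
  with a two-regime crossover (piecewise power-law spectrum
  S(f) ∝ f^(−(2α−1)), crossover frequency 1/crossover_scale);
* :func:`generate_activity_counts` — fractal noise mapped through an
  exponential link to a non-negative intensity, modulated by a 24 h circadian
  envelope and realized as Poisson counts;
* :func:`generate_duration_process` — alternating low/high activity whose low
  durations are drawn i.i.d. from a power-law or lognormal tail, constructed
  so that mean-dichotomization recovers the ground-truth durations exactly;
* :func:`generate_raw_acceleration` — a 30 Hz tri-axial record that
  round-trips bit-exactly through the count preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import GenerationError, ParameterError
from .preprocessing import rebin_counts
from .series import ActivityCountSeries, RawAccelerationSeries, VALID_DELTAS
from .tailfit import DurationSet

#: Log-scale SD of the exponential link in generate_activity_counts.  Chosen
#: for a realistic coefficient of variation (~0.5) of the count intensity.
LOG_INTENSITY_SCALE = 0.5

#: Supra-threshold acceleration excess (in g) used by generate_raw_acceleration.
ACTIVE_EXCESS_G = 0.25


@dataclass
class NoiseSpec:
    """Target for the fractal-noise generator.

    ``alpha_short`` applies below ``crossover_scale`` (in samples),
    ``alpha_long`` above it; equal exponents give mono-fractal noise and the
    crossover is ignored.
    """

    n_samples: int
    alpha_short: float
    alpha_long: float | None = None
    crossover_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_long is None:
            self.alpha_long = self.alpha_short
        if self.n_samples < 2**10:
            raise ParameterError("n_samples must be at least 2^10")
        for a in (self.alpha_short, self.alpha_long):
            if not 0.1 <= a <= 1.9:
                raise ParameterError(
                    f"scaling exponent {a} outside [0.1, 1.9]: spectral exponent undefined"
                )
        if self.alpha_short != self.alpha_long and self.crossover_scale is None:
            raise ParameterError("two-regime noise needs a crossover_scale")

    def check_crossover(self) -> None:
        """Enforce the crossover-scale bound at generation time.

        Deferred from ``__post_init__`` so a spec can serve as a template whose
        ``n_samples`` is overridden (e.g. by :class:`ActivityModelSpec`).
        """
        if self.alpha_short != self.alpha_long:
            if not 4 <= self.crossover_scale <= self.n_samples / 4:
                raise ParameterError(
                    f"crossover_scale must lie in [4, n_samples/4], got {self.crossover_scale}"
                )


@dataclass
class ActivityModelSpec:
    """Multi-day activity-count model: fractal noise × circadian envelope → Poisson."""

    days: int
    delta: int
    noise: NoiseSpec
    circadian_amplitude: float = 0.0
    circadian_period: float = 24.0
    mean_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ParameterError("need at least one day")
        if self.delta not in VALID_DELTAS:
            raise ParameterError(f"delta must be one of {VALID_DELTAS}")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ParameterError("circadian_amplitude must lie in [0, 1]")
        if self.mean_level <= 0:
            raise ParameterError("mean_level must be positive")

    @property
    def n_epochs(self) -> int:
        return self.days * 86400 // self.delta


@dataclass
class DurationModelSpec:
    """Alternating low/high activity with heavy-tailed low-period durations.

    Low durations are i.i.d. power-law (exponent ``beta`` > 1) or lognormal
    (``mu``, ``sigma`` in log-seconds), truncated below at ``d_min`` seconds
    and rounded to whole epochs of length ``delta``.  High periods are
    exponential with mean ``high_duration_mean`` seconds.
    """

    family: str                      # "power_law" | "lognormal"
    n_periods: int
    d_min: float
    delta: int = 60
    beta: float | None = None
    mu: float | None = None
    sigma: float | None = None
    high_duration_mean: float = 600.0
    low_level: int = 2
    high_level: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("power_law", "lognormal"):
            raise ParameterError(f"unknown tail family {self.family!r}")
        if self.delta not in VALID_DELTAS:
            raise ParameterError(f"delta must be one of {VALID_DELTAS}")
        if self.d_min < self.delta:
            raise ParameterError("d_min must be at least one epoch")
        if self.family == "power_law":
            if self.beta is None or self.beta <= 1:
                raise ParameterError("power-law family needs beta > 1")
        else:
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ParameterError("lognormal family needs mu and sigma > 0")
        if not 0 <= self.low_level < self.high_level:
            raise ParameterError("need 0 ≤ low_level < high_level")
        if self.n_periods < 1:
            raise ParameterError("need at least one low period")


# ---------------------------------------------------------------------------

def generate_fractal_noise(spec: NoiseSpec) -> np.ndarray:
    """Zero-mean, unit-variance series with prescribed DFA scaling.

    Spectral synthesis: independent complex Gaussian Fourier coefficients with
    amplitude ∝ f^(−(2α−1)/2), using ``alpha_short`` above the crossover
    frequency 1/crossover_scale and ``alpha_long`` below it, continuous at the
    crossover, then inverse-transformed.  Deterministic given the seed.
    """
    spec.check_crossover()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_samples)
    f = np.fft.rfftfreq(n)
    beta_s = 2.0 * spec.alpha_short - 1.0
    beta_l = 2.0 * spec.alpha_long - 1.0
    amp = np.zeros_like(f)
    nz = f > 0
    if spec.alpha_short == spec.alpha_long:
        amp[nz] = f[nz] ** (-beta_s / 2.0)
    else:
        fx = 1.0 / spec.crossover_scale
        hi = nz & (f >= fx)
        lo = nz & (f < fx)
        amp[hi] = f[hi] ** (-beta_s / 2.0)
        # continuity at fx: C·fx^(−βl/2) = fx^(−βs/2)
        c = fx ** ((beta_l - beta_s) / 2.0)
        amp[lo] = c * f[lo] ** (-beta_l / 2.0)
    coeff = (
        rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    ) * amp / np.sqrt(2.0)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real
    x = np.fft.irfft(coeff, n)
    x -= x.mean()
    x /= x.std()
    return x


def generate_activity_counts(spec: ActivityModelSpec) -> ActivityCountSeries:
    """Non-negative integer counts: exp-link intensity × circadian envelope → Poisson.

    The monotone exponential link preserves rank correlations, so the noise's
    DFA exponents survive approximately (±0.1).  The intensity is normalized
    so the expected count per epoch equals ``mean_level``; the envelope is
    1 + amplitude·cos(2π t / period) with t in hours from the series start.
    """
    n = spec.n_epochs
    noise_spec = replace(spec.noise, n_samples=n)
    z = generate_fractal_noise(noise_spec)
    c = LOG_INTENSITY_SCALE
    intensity = spec.mean_level * np.exp(c * z - 0.5 * c * c)
    t_hours = np.arange(n) * spec.delta / 3600.0
    envelope = 1.0 + spec.circadian_amplitude * np.cos(
        2.0 * np.pi * t_hours / spec.circadian_period
    )
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(intensity * envelope)
    return ActivityCountSeries(counts, spec.delta)


def sample_low_durations(spec: DurationModelSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Ground-truth low-period durations in seconds (whole epochs, ≥ d_min)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_periods
    if spec.family == "power_law":
        u = rng.random(n)
        d = spec.d_min * u ** (-1.0 / (spec.beta - 1.0))
    else:
        d = np.empty(0)
        while d.size < n:
            draw = rng.lognormal(spec.mu, spec.sigma, size=max(n, 2 * (n - d.size)))
            d = np.concatenate([d, draw[draw >= spec.d_min]])
        d = d[:n]
    min_epochs = int(np.ceil(spec.d_min / spec.delta))
    k = np.maximum(min_epochs, np.rint(d / spec.delta).astype(int))
    return k * float(spec.delta)


def generate_duration_process(
    spec: DurationModelSpec,
) -> tuple[ActivityCountSeries, DurationSet]:
    """Alternating low/high count series plus the exact low durations used.

    The series starts and ends with a high period, so every low period is
    interior and mean-dichotomization recovers the ground truth exactly.  Low
    epochs carry ``low_level`` plus small non-negative integer noise capped at
    10% of (mean − low_level) so no low epoch can cross the overall mean.
    """
    rng = np.random.default_rng(spec.seed)
    low_durs = sample_low_durations(spec, rng)
    k_low = np.rint(low_durs / spec.delta).astype(int)
    k_high = np.maximum(
        1, np.rint(rng.exponential(spec.high_duration_mean, spec.n_periods + 1) / spec.delta)
    ).astype(int)

    n_low = int(k_low.sum())
    n_high = int(k_high.sum())
    n_total = n_low + n_high
    base_mean = (spec.low_level * n_low + spec.high_level * n_high) / n_total
    if not spec.low_level < base_mean < spec.high_level:
        raise GenerationError(
            "realized mean not strictly between low and high levels; "
            "regenerate with different levels or durations"
        )
    noise_amp = int(np.floor(0.1 * (base_mean - spec.low_level)))
    segments = []
    for i in range(spec.n_periods):
        segments.append(np.full(k_high[i], spec.high_level, dtype=np.int64))
        low_seg = np.full(k_low[i], spec.low_level, dtype=np.int64)
        if noise_amp >= 1:
            low_seg = low_seg + rng.integers(0, noise_amp + 1, size=k_low[i])
        segments.append(low_seg)
    segments.append(np.full(k_high[-1], spec.high_level, dtype=np.int64))
    counts = np.concatenate(segments)

    mean = counts.mean()
    max_low = spec.low_level + noise_amp
    if not max_low < mean < spec.high_level:
        raise GenerationError(
            "realized overall mean not strictly between the low and high levels"
        )
    series = ActivityCountSeries(counts, spec.delta)
    truth = DurationSet(low_durs, spec.delta, threshold_used=float(mean), state="low")
    return series, truth


def generate_raw_acceleration(
    epoch_counts: ActivityCountSeries, nu: float = 30.0, seed: int = 0
) -> RawAccelerationSeries:
    """30 Hz tri-axial record whose epoch counts round-trip to the input exactly.

    Per epoch of τ = ν·δ samples, exactly ``count`` samples get a
    gravity-corrected magnitude above 0.1 g (device resting along the z axis
    plus a supra-threshold excess); the remaining samples stay at or below the
    threshold.  Active-sample positions are shuffled within each epoch.
    """
    tau = int(round(nu * epoch_counts.delta))
    counts = epoch_counts.counts
    if counts.size and counts.max() > tau:
        raise ParameterError(
            f"count {counts.max()} exceeds τ = ν·δ = {tau} samples per epoch"
        )
    rng = np.random.default_rng(seed)
    mask = np.arange(tau)[None, :] < counts[:, None]
    mask = rng.permuted(mask, axis=1).ravel()
    n = mask.size
    az = np.ones(n)
    # sub-threshold jitter on resting samples, clear excess on active ones
    az += np.where(mask, ACTIVE_EXCESS_G, rng.uniform(0.0, 0.05, size=n))
    samples = np.column_stack([np.zeros(n), np.zeros(n), az])
    return RawAccelerationSeries(
        samples=samples, nu=nu, start_time=epoch_counts.start_time
    )


# ---------------------------------------------------------------------------
# cohort helpers

def generate_multiresolution_counts(
    spec: ActivityModelSpec, deltas: tuple[int, ...] = VALID_DELTAS
) -> dict[str, ActivityCountSeries]:
    """Generate at the finest requested resolution and rebin to the others.

    Mirrors how counts at coarser epochs are exact sums of finer-epoch counts
    when both derive from the same raw record.
    """
    deltas = tuple(sorted(deltas))
    base = generate_activity_counts(replace(spec, delta=deltas[0]))
    out = {base.label: base}
    for d in deltas[1:]:
        s = rebin_counts(base, d)
        out[s.label] = s
    return out


def generate_cohort(
    n_subjects: int, spec: ActivityModelSpec, deltas: tuple[int, ...] = VALID_DELTAS,
    seed: int = 0,
) -> list[dict[str, ActivityCountSeries]]:
    """Independent subjects sharing one model spec, seeds derived from ``seed``."""
    cohort = []
    for i in range(n_subjects):
        s = replace(
            spec,
            seed=int(seed) * 10_000 + i,
            noise=replace(spec.noise, seed=int(seed) * 10_000 + 5_000 + i),
        )
        cohort.append(generate_multiresolution_counts(s, deltas))
    return cohort
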