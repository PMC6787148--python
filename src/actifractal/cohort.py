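"""Per-subject orchestration and cohort-level inference.

For each subject the DFA, duration-tail and circadian analyses are run at
every available resolution (CP5s ... CPM).  Cohort statistics follow:

* BCa (bias-corrected and accelerated) bootstrap 95% confidence intervals for
  sample means and Pearson correlations;
* counts of subjects whose durations are significantly better described by a
  lognormal than a power law (LLR > 0 and Vuong p < 0.1), plus the reverse
  count as an asymmetry check;
* span-of-ranges convergence statistics: the per-subject max − min of a
  quantity across resolutions, summarized over subjects — small spans mean the
  quantity is robust to the acquisition resolution;
* subgroup summaries of the three deviation-from-fractality measures
  (|α12|, LLR, GOF ratio) with their CIs;
* a diagnostic OLS of the fitted power-law exponent γ on its fit nuisances
  (d_min and the maximal duration): a high R² warns that γ reflects the
  fitting procedure rather than genuine scale invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .circadian import CircadianMetrics, circadian_metrics
from .dfa import DFAResult, fit_two_regime, fluctuation_function
from .exceptions import ActifractalError, InsufficientDataError
from .series import ActivityCountSeries, RESOLUTION_LABELS
from .tailfit import FitComparison, compare_fits, dichotomize

logger = logging.getLogger(__name__)

#: Canonical resolution order, coarse to fine.
RESOLUTIONS = ("CPM", "CP30s", "CP15s", "CP10s", "CP5s")

#: Fine resolutions used for convergence (span-of-ranges) assessment.
CONVERGENCE_RESOLUTIONS = ("CP30s", "CP15s", "CP10s", "CP5s")

DEFAULT_N_BOOT = 10_000
DEFAULT_SEED = 0


@dataclass
class ResolutionAnalysis:
    """All per-resolution outputs for one subject (None where a stage failed)."""

    dfa: DFAResult | None = None
    comparison: FitComparison | None = None
    max_low_duration: float | None = None
    failures: dict[str, str] = field(default_factory=dict)


@dataclass
class SubjectResult:
    subject_id: str
    per_resolution: dict[str, ResolutionAnalysis]
    circadian: CircadianMetrics | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    n_boot: int
    method: str = "BCa"
    seed: int = DEFAULT_SEED


# ---------------------------------------------------------------------------
# per-subject pipeline

def analyze_subject(
    counts_by_resolution: dict[str, ActivityCountSeries],
    subject_id: str = "subject",
    metadata: dict | None = None,
) -> SubjectResult:
    """Run DFA, tail comparison and circadian metrics at every resolution.

    Stage failures are recorded as flagged gaps, never silently dropped; the
    subject errors out only if every resolution fails entirely.
    """
    per_res: dict[str, ResolutionAnalysis] = {}
    any_ok = False
    for label, series in counts_by_resolution.items():
        res = ResolutionAnalysis()
        try:
            fluct = fluctuation_function(series)
            res.dfa = fit_two_regime(fluct)
            any_ok = True
        except ActifractalError as exc:
            res.failures["dfa"] = str(exc)
            logger.warning("%s/%s: DFA failed: %s", subject_id, label, exc)
        try:
            low, _high = dichotomize(series)
            res.max_low_duration = float(low.durations.max()) if low.N else None
            res.comparison = compare_fits(low)
            any_ok = True
        except ActifractalError as exc:
            res.failures["tailfit"] = str(exc)
            logger.warning("%s/%s: tail fit failed: %s", subject_id, label, exc)
        per_res[label] = res
    circ = None
    for label in sorted(
        counts_by_resolution, key=lambda k: counts_by_resolution[k].delta
    ):
        try:
            circ = circadian_metrics(counts_by_resolution[label])
            any_ok = True
            break
        except ActifractalError as exc:
            per_res[label].failures["circadian"] = str(exc)
    if not any_ok:
        raise InsufficientDataError(f"{subject_id}: every resolution failed")
    return SubjectResult(
        subject_id=subject_id,
        per_resolution=per_res,
        circadian=circ,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# BCa bootstrap

def _pearson_stat(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    xm = x - np.mean(x, axis=axis, keepdims=True)
    ym = y - np.mean(y, axis=axis, keepdims=True)
    num = np.sum(xm * ym, axis=axis)
    den = np.sqrt(np.sum(xm * xm, axis=axis) * np.sum(ym * ym, axis=axis))
    return num / den


def bca_ci(
    values: np.ndarray,
    statistic: str = "mean",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    y: np.ndarray | None = None,
) -> BootstrapCI:
    """BCa 95% bootstrap CI for a sample mean or a Pearson correlation.

    Bias correction z0 comes from the fraction of the bootstrap distribution
    below the point estimate; the acceleration a from jackknife skewness.
    A zero-variance sample yields the degenerate interval [x, x].
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3 or np.unique(values).size < 2:
        if n == 0:
            raise InsufficientDataError("empty sample")
        est = float(values.mean()) if statistic == "mean" else float("nan")
        if np.ptp(values) == 0 and statistic == "mean":
            logger.warning("zero-variance sample: degenerate CI [x, x]")
            return BootstrapCI(est, est, est, n_boot, seed=seed)
        raise InsufficientDataError("need ≥ 3 distinct values for a BCa interval")
    rng = np.random.default_rng(seed)
    if statistic == "mean":
        data = (values,)
        stat = np.mean
        est = float(values.mean())
        paired = False
    elif statistic == "pearson_r":
        if y is None or np.asarray(y).size != n:
            raise InsufficientDataError("pearson_r needs paired samples of equal length")
        y = np.asarray(y, dtype=float)
        if np.ptp(values) == 0 or np.ptp(y) == 0:
            raise InsufficientDataError("correlation undefined for a constant variable")
        data = (values, y)
        stat = _pearson_stat
        est = float(_pearson_stat(values, y))
        if abs(est) >= 1.0 - 1e-12:
            # perfectly linear pair: every resample reproduces r = ±1
            return BootstrapCI(est, est, est, n_boot, seed=seed)
        paired = True
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    res = stats.bootstrap(
        data,
        stat,
        n_resamples=n_boot,
        paired=paired,
        vectorized=True,
        axis=-1,
        confidence_level=0.95,
        method="BCa",
        rng=rng,
    )
    lo = float(res.confidence_interval.low)
    hi = float(res.confidence_interval.high)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise RuntimeError("bootstrap produced a non-finite confidence interval")
    return BootstrapCI(est, lo, hi, n_boot, seed=seed)


# ---------------------------------------------------------------------------
# quantity extraction

def _get_quantity(res: ResolutionAnalysis, name: str) -> float | None:
    if name in ("alpha1", "alpha2", "alpha12", "abs_alpha12"):
        return None if res.dfa is None else float(getattr(res.dfa, name))
    if res.comparison is None:
        return None
    if name == "llr":
        return float(res.comparison.llr)
    if name == "gof_ratio":
        return float(res.comparison.gof_ratio)
    if name == "gamma":
        g = res.comparison.pl_fit.gamma
        return None if g is None else float(g)
    if name == "d_min_pl":
        return float(res.comparison.pl_fit.d_min)
    raise ValueError(f"unknown quantity {name!r}")


def quantity_values(
    results: list[SubjectResult], name: str, resolution: str
) -> tuple[np.ndarray, list[str]]:
    """Per-subject values of one quantity at one resolution (missing skipped)."""
    vals, ids = [], []
    for r in results:
        res = r.per_resolution.get(resolution)
        if res is None:
            continue
        v = _get_quantity(res, name)
        if v is not None and np.isfinite(v):
            vals.append(v)
            ids.append(r.subject_id)
    return np.asarray(vals), ids


# ---------------------------------------------------------------------------
# cohort summaries

def cohort_summary(
    results: list[SubjectResult],
    resolutions: tuple[str, ...] = RESOLUTIONS,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> dict[str, dict[str, BootstrapCI]]:
    """Per-resolution means with BCa CIs of |α12|, LLR and GOF ratio."""
    out: dict[str, dict[str, BootstrapCI]] = {}
    for res in resolutions:
        row = {}
        for name in ("abs_alpha12", "llr", "gof_ratio"):
            vals, _ = quantity_values(results, name, res)
            if vals.size >= 3:
                row[name] = bca_ci(vals, "mean", n_boot=n_boot, seed=seed)
        if row:
            out[res] = row
    return out


def lognormal_better_counts(
    results: list[SubjectResult], resolution: str
) -> tuple[int, float, int]:
    """(count, fraction, reverse_count) of significant lognormal wins.

    A win requires LLR > 0 with Vuong p < 0.1 at the headline pairing; the
    reverse count tallies significant power-law wins (asymmetry check).
    """
    n_avail = 0
    count = 0
    reverse = 0
    for r in results:
        res = r.per_resolution.get(resolution)
        if res is None or res.comparison is None:
            continue
        n_avail += 1
        flag = res.comparison.better_family_flag
        if flag == "lognormal":
            count += 1
        elif flag == "power_law":
            reverse += 1
    fraction = count / n_avail if n_avail else float("nan")
    return count, fraction, reverse


def span_of_ranges(
    results: list[SubjectResult],
    quantity: str,
    resolutions: tuple[str, ...] = CONVERGENCE_RESOLUTIONS,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-subject max − min of a quantity across resolutions, with a summary.

    The max over subjects is the most conservative convergence measure; the
    summary also reports mean, SD, min and max of the per-subject spans.
    """
    spans: dict[str, float] = {}
    for r in results:
        vals = [
            v
            for res in resolutions
            if (ra := r.per_resolution.get(res)) is not None
            and (v := _get_quantity(ra, quantity)) is not None
            and np.isfinite(v)
        ]
        if len(vals) >= 2:
            spans[r.subject_id] = float(max(vals) - min(vals))
    arr = np.array(list(spans.values()))
    summary = {
        "max": float(arr.max()) if arr.size else float("nan"),
        "mean": float(arr.mean()) if arr.size else float("nan"),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        "min": float(arr.min()) if arr.size else float("nan"),
        "n": int(arr.size),
    }
    return spans, summary


def subgroup_summary(
    results: list[SubjectResult],
    grouping_label: str,
    resolutions: tuple[str, ...] = RESOLUTIONS,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    min_n: int = 3,
) -> dict[str, dict]:
    """Mean |α12|, LLR, GOF ratio with BCa CIs per metadata subgroup."""
    groups: dict[str, list[SubjectResult]] = {}
    for r in results:
        key = r.metadata.get(grouping_label)
        if key is not None:
            groups.setdefault(str(key), []).append(r)
    out = {}
    for key, members in sorted(groups.items()):
        if len(members) < min_n:
            logger.info(
                "subgroup %s=%s has %d < %d subjects; skipped",
                grouping_label, key, len(members), min_n,
            )
            continue
        out[key] = cohort_summary(members, resolutions, n_boot=n_boot, seed=seed)
    return out


# ---------------------------------------------------------------------------
# correlation tables

@dataclass
class CorrelationTable:
    variables: list[str]
    r: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_pairs: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Paper-style layout: r above the diagonal, [lo, hi] strings below."""
        k = len(self.variables)
        out = pd.DataFrame(
            "", index=self.variables, columns=self.variables, dtype=object
        )
        for i, a in enumerate(self.variables):
            out.loc[a, a] = "1"
            for j in range(i + 1, k):
                b = self.variables[j]
                r = self.r.loc[a, b]
                out.loc[a, b] = f"{r:.3f}" if np.isfinite(r) else "n/a"
                lo, hi = self.ci_low.loc[a, b], self.ci_high.loc[a, b]
                out.loc[b, a] = (
                    f"[{lo:.3f}, {hi:.3f}]" if np.isfinite(lo) else "n/a"
                )
        return out


def correlation_table(
    frame: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> CorrelationTable:
    """Pairwise Pearson r with BCa CIs; pairwise deletion for missing values.

    Cells with fewer than 3 complete pairs are marked unavailable (NaN).
    """
    cols = list(frame.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    lo = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    hi = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    np_pairs = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    for i in range(k):
        lo.iloc[i, i] = hi.iloc[i, i] = 1.0
        for j in range(i + 1, k):
            sub = frame[[cols[i], cols[j]]].dropna()
            np_pairs.iloc[i, j] = np_pairs.iloc[j, i] = len(sub)
            if len(sub) < 3:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            x = sub[cols[i]].to_numpy(dtype=float)
            y = sub[cols[j]].to_numpy(dtype=float)
            ci = bca_ci(x, "pearson_r", n_boot=n_boot, seed=seed, y=y)
            r.iloc[i, j] = r.iloc[j, i] = ci.estimate
            lo.iloc[i, j] = lo.iloc[j, i] = ci.lower
            hi.iloc[i, j] = hi.iloc[j, i] = ci.upper
    return CorrelationTable(cols, r, lo, hi, np_pairs)


# ---------------------------------------------------------------------------
# diagnostic regression

@dataclass
class GammaDiagnostic:
    r_squared: float
    coef_pvalues: dict[str, float]
    condition_number: float
    n: int


def gamma_dependence_diagnostic(
    results: list[SubjectResult], resolution: str, min_subjects: int = 10
) -> GammaDiagnostic:
    """OLS of fitted γ on (d_min^PL, maximal low duration) across subjects.

    A high R² means the power-law exponent is driven by fit nuisances rather
    than genuine scale invariance — a validity warning for interpreting γ.
    """
    rows = []
    for r in results:
        res = r.per_resolution.get(resolution)
        if res is None or res.comparison is None:
            continue
        g = res.comparison.pl_fit.gamma
        if g is None or res.max_low_duration is None:
            continue
        rows.append((g, res.comparison.pl_fit.d_min, res.max_low_duration))
    if len(rows) < min_subjects:
        raise InsufficientDataError(
            f"need ≥ {min_subjects} subjects with power-law fits, got {len(rows)}"
        )
    arr = np.asarray(rows, dtype=float)
    y = arr[:, 0]
    if np.ptp(y) == 0:
        return GammaDiagnostic(0.0, {}, float("nan"), len(rows))
    X = sm.add_constant(pd.DataFrame(arr[:, 1:], columns=["d_min", "max_duration"]))
    fit = sm.OLS(y, X).fit()
    return GammaDiagnostic(
        r_squared=float(fit.rsquared),
        coef_pvalues={k: float(v) for k, v in fit.pvalues.items()},
        condition_number=float(fit.condition_number),
        n=len(rows),
    )
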