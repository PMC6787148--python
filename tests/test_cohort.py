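"""BCa bootstrap, correlation tables, spans, subgroup and diagnostic summaries."""

import numpy as np
import pandas as pd
import pytest

from actifractal.cohort import (
    ResolutionAnalysis,
    SubjectResult,
    analyze_subject,
    bca_ci,
    cohort_summary,
    correlation_table,
    gamma_dependence_diagnostic,
    lognormal_better_counts,
    quantity_values,
    span_of_ranges,
    subgroup_summary,
)
from actifractal.dfa import DFAResult
from actifractal.exceptions import InsufficientDataError
from actifractal.tailfit import FitComparison, TailFit


def fake_dfa(a1, a2):
    return DFAResult(a1, a2, a1 - a2, abs(a1 - a2))


def fake_comparison(llr, p, gof=1.5, gamma=1.0, d_min=60.0):
    flag = ("lognormal" if llr > 0 else "power_law") if p < 0.1 else "undecided"
    pl = TailFit("power_law", d_min, 100, -1.0, 0.05, beta=gamma + 1.0)
    return FitComparison(
        llr_at_dmin_pl=llr / 10, vuong_p_pl=0.5,
        llr_at_dmin_ln=llr, vuong_p_ln=p,
        gof_ratio=gof, better_family_flag=flag, pl_fit=pl,
    )


def fake_subject(sid, values_by_res, metadata=None, max_dur=3600.0):
    """values_by_res: {resolution: (a1, a2, llr, p)}"""
    per = {}
    for res, (a1, a2, llr, p) in values_by_res.items():
        per[res] = ResolutionAnalysis(
            dfa=fake_dfa(a1, a2),
            comparison=fake_comparison(llr, p),
            max_low_duration=max_dur,
        )
    return SubjectResult(sid, per, metadata=metadata or {})


class TestBcaCI:
    def test_identical_values_degenerate_interval(self):
        ci = bca_ci(np.full(10, 3.2), "mean", n_boot=100, seed=0)
        assert ci.lower == ci.upper == ci.estimate == 3.2

    def test_gaussian_mean_matches_normal_theory(self):
        x = np.random.default_rng(5).normal(10.0, 2.0, 400)
        ci = bca_ci(x, "mean", n_boot=4000, seed=1)
        se = x.std(ddof=1) / 20.0
        assert ci.lower == pytest.approx(x.mean() - 1.96 * se, abs=0.03)
        assert ci.upper == pytest.approx(x.mean() + 1.96 * se, abs=0.03)

    def test_seed_reproducibility(self):
        x = np.random.default_rng(6).exponential(1.0, 40)
        a = bca_ci(x, "mean", n_boot=500, seed=7)
        b = bca_ci(x, "mean", n_boot=500, seed=7)
        c = bca_ci(x, "mean", n_boot=500, seed=8)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_ci_brackets_estimate(self):
        x = np.random.default_rng(9).lognormal(0, 1, 50)
        ci = bca_ci(x, "mean", n_boot=2000, seed=2)
        assert ci.lower <= ci.estimate <= ci.upper

    def test_pearson_independent_variables_cover_zero(self):
        covered = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            x, y = rng.normal(size=36), rng.normal(size=36)
            ci = bca_ci(x, "pearson_r", n_boot=600, seed=r, y=y)
            covered += ci.lower <= 0.0 <= ci.upper
        assert covered / reps >= 0.85

    def test_perfectly_linear_pair(self):
        x = np.arange(20.0)
        ci = bca_ci(x, "pearson_r", n_boot=200, seed=3, y=2 * x + 1)
        assert ci.estimate == pytest.approx(1.0)
        assert (ci.lower, ci.upper) == (ci.estimate, ci.estimate)


class TestCorrelationTable:
    def test_self_correlation_and_layout(self):
        rng = np.random.default_rng(10)
        frame = pd.DataFrame(
            {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        )
        frame["c"] = frame["a"] * 0.8 + rng.normal(size=30) * 0.3
        table = correlation_table(frame, n_boot=400, seed=0)
        assert np.allclose(np.diag(table.r), 1.0)
        assert table.r.loc["a", "c"] > 0.5
        fmt = table.formatted()
        assert fmt.loc["a", "a"] == "1"
        assert fmt.loc["b", "a"].startswith("[")  # CI below the diagonal
        assert not fmt.loc["a", "b"].startswith("[")  # r above the diagonal

    def test_pairwise_deletion_for_missing(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(
            {"a": rng.normal(size=20), "b": rng.normal(size=20)}
        )
        frame.loc[:4, "b"] = np.nan  # mirrors partially missing MMSE scores
        table = correlation_table(frame, n_boot=300, seed=0)
        assert table.n_pairs.loc["a", "b"] == 15

    def test_too_few_pairs_marked_unavailable(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan, np.nan, 1.0]})
        table = correlation_table(frame, n_boot=100, seed=0)
        assert np.isnan(table.r.loc["a", "b"])
        assert table.formatted().loc["a", "b"] == "n/a"


class TestCohortAggregates:
    def test_span_zero_when_identical_across_resolutions(self):
        subj = fake_subject(
            "s1", {r: (0.9, 0.6, 2.0, 0.05) for r in ("CP30s", "CP15s", "CP10s", "CP5s")}
        )
        spans, summary = span_of_ranges([subj], "abs_alpha12")
        assert spans["s1"] == 0.0
        assert summary["max"] == 0.0

    def test_span_of_two_resolutions_is_difference(self):
        subj = fake_subject(
            "s1", {"CP30s": (0.9, 0.6, 2.0, 0.5), "CP5s": (0.8, 0.6, 5.0, 0.5)}
        )
        spans, _ = span_of_ranges([subj], "alpha1", ("CP30s", "CP5s"))
        assert spans["s1"] == pytest.approx(0.1)
        spans, _ = span_of_ranges([subj], "llr", ("CP30s", "CP5s"))
        assert spans["s1"] == pytest.approx(3.0)

    def test_lognormal_better_counts_and_asymmetry(self):
        subjects = [
            fake_subject("a", {"CPM": (0.9, 0.7, 3.0, 0.01)}),   # significant LN
            fake_subject("b", {"CPM": (0.9, 0.7, 1.0, 0.50)}),   # undecided
            fake_subject("c", {"CPM": (0.9, 0.7, -2.0, 0.05)}),  # significant PL
        ]
        count, fraction, reverse = lognormal_better_counts(subjects, "CPM")
        assert (count, reverse) == (1, 1)
        assert fraction == pytest.approx(1 / 3)

    def test_no_significant_wins_counts_zero(self):
        subjects = [
            fake_subject(str(i), {"CPM": (0.9, 0.7, 1.0, 0.5)}) for i in range(5)
        ]
        count, _, reverse = lognormal_better_counts(subjects, "CPM")
        assert count == 0 and reverse == 0

    def test_subgroup_of_whole_cohort_equals_global_summary(self):
        rng = np.random.default_rng(12)
        subjects = [
            fake_subject(
                f"s{i}",
                {"CPM": (0.9 + 0.05 * rng.normal(), 0.6, rng.normal(2, 1), 0.05)},
                metadata={"site": "all"},
            )
            for i in range(8)
        ]
        whole = cohort_summary(subjects, ("CPM",), n_boot=400, seed=3)
        grouped = subgroup_summary(subjects, "site", ("CPM",), n_boot=400, seed=3)
        got = grouped["all"]["CPM"]["abs_alpha12"]
        want = whole["CPM"]["abs_alpha12"]
        assert (got.estimate, got.lower, got.upper) == (
            want.estimate, want.lower, want.upper,
        )

    def test_small_subgroup_skipped(self):
        subjects = [
            fake_subject(f"s{i}", {"CPM": (0.9, 0.6, 2.0, 0.05)},
                         metadata={"g": "tiny" if i < 2 else "big"})
            for i in range(8)
        ]
        grouped = subgroup_summary(subjects, "g", ("CPM",), n_boot=200, seed=0)
        assert "tiny" not in grouped and "big" in grouped


class TestAnalyzeSubject:
    def test_mono_fractal_subject_small_breakdown_everywhere(self):
        from actifractal.simulate import (
            ActivityModelSpec,
            NoiseSpec,
            generate_multiresolution_counts,
        )

        spec = ActivityModelSpec(
            days=4, delta=15, mean_level=25.0,
            noise=NoiseSpec(2**10, 0.9, seed=31), seed=31,
        )
        multi = generate_multiresolution_counts(spec, deltas=(15, 30, 60))
        result = analyze_subject(multi, "mono")
        vals, _ = quantity_values([result], "abs_alpha12", "CP15s")
        assert vals.size == 1 and vals[0] < 0.15

    def test_failures_are_flagged_not_silent(self, make_counts):
        # only 4 low-activity periods: tail fitting must refuse, DFA and the
        # circadian metrics still run
        values = np.full(6000, 100)
        for start in (500, 1700, 3100, 4600):
            values[start : start + 10] = 0
        series = make_counts(values, delta=60)
        result = analyze_subject({"CPM": series}, "short")
        assert result.per_resolution["CPM"].comparison is None
        assert "tailfit" in result.per_resolution["CPM"].failures
        assert result.circadian is not None

    def test_all_failed_raises(self, make_counts):
        with pytest.raises(InsufficientDataError):
            analyze_subject({"CPM": make_counts([5] * 5000)}, "flat")


class TestGammaDiagnostic:
    @staticmethod
    def _cohort(family, **kw):
        from actifractal.simulate import DurationModelSpec, sample_low_durations
        from actifractal.tailfit import DurationSet, compare_fits

        results = []
        for s in range(14):
            spec = DurationModelSpec(
                family, n_periods=600, d_min=60, delta=5, seed=300 + s, **kw
            )
            d = DurationSet(sample_low_durations(spec), 5)
            ra = ResolutionAnalysis(
                comparison=compare_fits(d),
                max_low_duration=float(d.durations.max()),
            )
            results.append(SubjectResult(f"s{s}", {"CP5s": ra}))
        return results

    def test_misspecified_power_law_gamma_driven_by_fit_nuisances(self):
        r2_pl = gamma_dependence_diagnostic(
            self._cohort("power_law", beta=2.0), "CP5s"
        ).r_squared
        r2_ln = gamma_dependence_diagnostic(
            self._cohort("lognormal", mu=5.0, sigma=0.8), "CP5s"
        ).r_squared
        # for true power-law data γ is (mostly) free of the nuisances; under
        # misspecification they explain most of its variance
        assert r2_ln > r2_pl
        assert r2_ln > 0.5
        assert r2_pl < 0.5

    def test_constant_gamma_gives_zero_r_squared(self):
        subjects = [
            fake_subject(f"s{i}", {"CPM": (0.9, 0.6, 2.0, 0.05)}) for i in range(12)
        ]
        diag = gamma_dependence_diagnostic(subjects, "CPM")
        assert diag.r_squared == 0.0
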