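# actifractal

Fractal and circadian analysis of wrist-actigraphy count series.

Locomotor activity of healthy adults shows *fractal* temporal structure:
activity fluctuations follow a power law across time scales from minutes to
hours, with a detrended-fluctuation-analysis (DFA) scaling exponent α close
to 1.  In neurodegenerative disease this mono-fractal scaling breaks down —
the fluctuation function splits into two regimes with distinct exponents,
and the distribution of low-activity period durations departs from the power
law expected under scale invariance.  `actifractal` implements the full
analysis pipeline needed to quantify these deviations from actigraphy, plus
a synthetic-data generator with known ground truth so that every stage can
be validated by parameter recovery.

## What it computes

**Preprocessing.**  Raw tri-axial acceleration sampled at ν = 30 Hz is
converted to epoch activity counts: per sample the acceleration magnitude is
gravity-corrected (scalar subtraction of 1 g), binarized at > 0.1 g, and
summed over non-overlapping epochs of δ ∈ {5, 10, 15, 30, 60} s (named CP5s
… CPM, with τ = νδ samples per epoch).

**DFA (two regimes).**  The count series is centered, integrated and cut
into disjoint windows of length *m*; F(*m*) is the pooled RMS residual
around per-window linear trends (DFA-1), evaluated on 66 log-spaced window
sizes from 3 to 720 min.  Scaling exponents are fitted by OLS on log–log
axes in two ranges:

- α₁ over 3–90 min (below 1.5 h),
- α₂ over 120–720 min (beyond 2 h),

with α₁₂ = α₁ − α₂ and |α₁₂| quantifying the break-down of single-power-law
scaling.  Reference points: α = 0.5 for uncorrelated noise, α = 1.5 for
Brownian motion.

**Duration distributions (CDDs).**  The series is dichotomized at its
overall mean; sorted low-activity durations d₁ < … < d_n define the
empirical complementary cumulative distribution P(X ≥ d).  Two tail models
are fitted by maximum likelihood above a lower bound d_min (selected by a
Kolmogorov–Smirnov scan over the observed support):

- power law   p(x) = (β−1) d_min^(β−1) x^(−β),  CCDF exponent γ = β − 1;
- lognormal   truncated at d_min, parameters (μ, σ).

The models are compared by the log-likelihood ratio (LLR > 0 ⇒ lognormal
better) with a Vuong normal-approximation p-value (winner declared only at
p < 0.1), and by the ratio of KS distances of the two best fits (GOF ratio
> 1 ⇒ lognormal better).  Because the two models generally select different
lower bounds, the LLR is computed pairwise at both d_min^PL and d_min^LN.

**Circadian metrics.**  Nonparametric rest–activity measures on hourly
aggregates: interdaily stability (IS), intradaily variability (IV), the most
active 10 h / quietest 5 h window means (M10, L5) and the relative amplitude
RA = (M10 − L5)/(M10 + L5).

**Cohort inference.**  Per-subject orchestration across all five
resolutions; BCa (bias-corrected and accelerated) bootstrap 95% CIs for
means and Pearson correlations; counts of subjects significantly better
described by a lognormal; span-of-ranges convergence statistics across
resolutions; subgroup summaries; and a diagnostic OLS of γ on its fit
nuisances (d_min, maximal duration) that warns when the power-law exponent
merely reflects the fitting procedure.

## Worked example

```python
from actifractal.simulate import NoiseSpec, ActivityModelSpec, DurationModelSpec, \
    generate_activity_counts, generate_duration_process
from actifractal.dfa import fluctuation_function, fit_two_regime
from actifractal.tailfit import compare_fits, dichotomize

# four days of 30 s counts with a genuine scaling crossover at ~105 min
spec = ActivityModelSpec(
    days=4, delta=30, mean_level=50.0, circadian_amplitude=0.0,
    noise=NoiseSpec(2**10, alpha_short=0.9, alpha_long=0.5,
                    crossover_scale=210, seed=1),
    seed=1,
)
series = generate_activity_counts(spec)
result = fit_two_regime(fluctuation_function(series))
print(f"alpha1 = {result.alpha1:.3f}   alpha2 = {result.alpha2:.3f}   "
      f"|alpha12| = {result.abs_alpha12:.3f}")

# low-activity durations drawn from a lognormal: the comparison detects it
dur_spec = DurationModelSpec("lognormal", n_periods=500, d_min=60, delta=30,
                             mu=5.0, sigma=0.8, seed=1)
dur_series, truth = generate_duration_process(dur_spec)
low, _ = dichotomize(dur_series)
comp = compare_fits(low)
print(f"LLR = {comp.llr:.1f}   Vuong p = {comp.vuong_p:.2g}   "
      f"GOF ratio = {comp.gof_ratio:.2f}   winner: {comp.better_family_flag}")
```

Output:

```
alpha1 = 0.809   alpha2 = 0.500   |alpha12| = 0.309
LLR = 83.4   Vuong p = 7.9e-13   GOF ratio = 1.26   winner: lognormal
```

The fitted α₁ ≈ 0.81 and α₂ ≈ 0.50 recover the generator's two scaling
regimes (0.9 at short scales, 0.5 beyond the crossover; the short-scale
estimate sits slightly low because the Poisson count layer adds white
noise), and |α₁₂| ≈ 0.31 flags the break-down of mono-fractal scaling.  For
the duration process, the positive LLR with p ≪ 0.1 and a GOF ratio above 1
correctly identify the lognormal tail.

A command-line interface mirrors the library:
`actifractal simulate|preprocess|dfa|tailfit|circadian|cohort --help`.

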