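# Methods

This note documents the statistical models implemented in `actifractal`, the
choices made where the methods literature leaves the design open, and what
the synthetic-data validation does and does not demonstrate.

## Signals and preprocessing

The pipeline's central object is the epoch activity-count series: the number
of 30 Hz acceleration samples per epoch of δ seconds whose gravity-corrected
magnitude exceeds 0.1 g.  Gravity correction is a *scalar* subtraction of
1 g from the Euclidean magnitude, not a vector high-pass filter; the
threshold comparison is strict, so a sample exactly at the threshold counts
as rest.  Epochs are aligned to the first sample and a trailing partial
epoch is discarded, keeping counts integer in [0, τ = νδ] and comparable
across records.  Counts at a coarser resolution are exact block sums of the
finest resolution, so `rebin_counts` reproduces what re-running the
threshold pipeline at a larger δ would give.

## DFA

`dfa` implements DFA-1: profile (centered cumulative sum), disjoint windows
taken forward from the series start with the remainder discarded, linear
least-squares detrending per window, and F(m) as the RMS residual pooled
over all windowed points.  Choices the method description leaves open:

- **Detrending order**: first order (DFA-1), the default of the standard
  tools in the actigraphy-DFA literature.
- **Window grid**: 66 log-spaced sizes over 3–720 min, each rounded to a
  whole number of epochs; collisions are pushed up one epoch so the grid
  stays strictly increasing.  Windows shorter than 4 epochs or longer than
  N/4 are dropped with a log notice (at CPM the 3 min point is therefore
  unavailable; the short-range fit then starts at 4 min).
- **Two-regime fit**: unweighted OLS of log10 F vs log10 m with endpoints
  inclusive, α₁ on [3, 90] min and α₂ on [120, 720] min; "below 1.5 h" and
  "beyond 2 h" are mapped to these closed numeric ranges.
- **Missing data** are not imputed; series are assumed gap-free (continuous
  wear).

F(m) is invariant to adding a constant to the input (centering) and scales
linearly with the input amplitude, so the exponents are scale-free.  For
n ≤ 200 the vectorized implementation agrees with a naive loop/normal-
equations oracle to 1e-10 relative; on 2^16-sample simulations it recovers
0.5 for iid noise, 1.5 for random walks, and mono-fractal targets across
0.5–1.5 within ±0.05 (20-seed means).

## Duration distributions and tail-model comparison

`tailfit` dichotomizes a count series at its overall arithmetic mean.
Epochs strictly below the mean are "low"; ties go "high" (with integer
counts and a fractional mean, exact ties are rare at fine resolutions).
Boundary periods truncated by the recording edges are included by default —
they censor long durations slightly, but excluding them is an equally
arbitrary choice; `drop_boundary=True` (CLI `--drop-boundary`) toggles this.

The power-law tail is fitted by the continuous maximum-likelihood estimator
β̂ = 1 + n/Σ ln(dᵢ/d_min); the lognormal truncated at d_min is fitted
numerically (L-BFGS-B with analytic gradients, moment initialization from
the log-durations, σ bounded below at 1e-6).  The lower bound d_min is
selected by scanning every observed unique duration (with at least 10
durations and, for the lognormal, 3 distinct values left in the tail) and
minimizing the KS distance between the fitted and empirical tail CDFs;
consecutive candidates warm-start the lognormal optimizer.

**Continuous MLE on discrete durations.**  Durations are integer multiples
of δ, while the fitted densities are continuous.  The discretization mostly
affects the d_min scan near the smallest durations: on power-law samples
rounded to epochs the selected d_min is biased upward (by roughly a factor
2–3 relative to the continuous-data case), whereas β̂ remains unbiased.
This is a known caveat of continuous-likelihood tail fitting on binned data
and is shared by the standard tools.

**Model comparison.**  Both models are fitted with their own KS-optimal
lower bound; since these generally differ, the log-likelihood ratio
Σ [ln p_LN(dᵢ) − ln p_PL(dᵢ)] is computed pairwise at both d_min^PL (with
the lognormal refitted there) and d_min^LN (with the power law refitted
there), each with a two-sided Vuong p-value based on the normalized
statistic LLR/(s·√n), where s is the SD of the pointwise log-likelihood
differences.  The GOF ratio divides the best power-law KS distance by the
best lognormal one.  A winner is declared only when p < 0.1.

**Which pairing is the headline?**  A design point the method description
leaves open.  Calibration on synthetic data settles it: with genuinely
lognormal durations (n = 1000), the d_min^PL pairing detects the lognormal
in only ~15% of replicates — the power-law KS scan climbs deep into the
tail, where any lognormal is locally indistinguishable from a power law —
while the d_min^LN pairing detects it in ~95% and stays calibrated on true
power-law data (~4% false lognormal wins at β = 2).  The headline
per-subject LLR, Vuong p and winner flag therefore come from the d_min^LN
pairing; both pairings are always reported.  When the lognormal wins, the
power-law exponent γ = β̂ − 1 is still emitted but carries
`gamma_valid=False`: under misspecification γ is a function of d_min and
the maximal observed duration rather than of any underlying scale-free
mechanism, which is exactly what `gamma_dependence_diagnostic` measures
(OLS of γ on those two nuisances; R² ≈ 0.9 on lognormal cohorts vs ≈ 0.2 on
true power-law cohorts in the shipped tests).

## Circadian metrics

Computed on hourly means regardless of the source δ (which makes them
resolution-independent): IS = (n Σ_h (x̄_h − x̄)²)/(24 Σ_i (xᵢ − x̄)²),
IV = (n Σ (xᵢ − xᵢ₋₁)²)/((n−1) Σ (xᵢ − x̄)²), and M10/L5 as the extreme
means over 10 h/5 h windows sliding in 1 h steps over the *average* 24 h
profile, wrapping midnight; RA = (M10 − L5)/(M10 + L5).  At least two
complete days are required.  Limiting values used as checks: IS = 1 for a
day-repeating profile, IV ≈ 2 for hourly white noise, RA = 1 for a
10 h-on/14 h-off profile.  IS and IV are invariant to affine transforms of
the signal; RA is invariant to positive scaling but not to shifts.

## Bootstrap and cohort statistics

Means and Pearson correlations carry BCa 95% CIs (bias correction from the
bootstrap distribution, acceleration from jackknife skewness), computed via
`scipy.stats.bootstrap` with a seeded generator; the default replicate count
is 10,000.  Zero-variance samples short-circuit to the degenerate interval
[x, x], and a perfectly linear pair returns [r, r] since every resample
reproduces r = ±1.  Missing metadata (e.g. cognitive scores available for
only part of a cohort) is handled by pairwise deletion in correlation
tables; cells with fewer than 3 complete pairs are marked unavailable.

A known property surfaced by the shipped coverage test: for strongly skewed
data at small n (mean of Exp(1), n = 30), BCa's realized coverage is ≈ 92–93%
rather than the nominal 95%.  This is a finite-sample property of the BCa
method itself, not of this implementation — the same routine matches the
mean ± 1.96·SE interval on large Gaussian samples to three decimals.

Span-of-ranges statistics (per-subject max − min of a quantity across the
CP30s…CP5s resolutions, summarized over subjects) quantify robustness to
the acquisition resolution.  On synthetic crossover cohorts the DFA
measures converge across resolutions (max |α₁₂| span ≈ 0.01) while the
duration-based LLR fluctuates by more than its own typical magnitude — the
central methodological contrast the cohort module is designed to expose.

## Synthetic data: what it emulates, and what it does not

`generate_fractal_noise` uses spectral synthesis: independent complex
Gaussian Fourier coefficients with amplitude ∝ f^(−(2α−1)/2), piecewise in
frequency for two-regime targets (crossover frequency 1/crossover_scale,
amplitude-continuous at the break), inverse-transformed and standardized.
The spectral break is placed exactly at 1/crossover_scale; 50-seed slope
fits confirm the DFA-visible crossover lands at the intended scale without
further calibration.  Spectral synthesis was preferred over circulant-
embedding generators because it encodes the two-regime spectrum directly.

`generate_activity_counts` maps the noise through an exponential link
(log-scale SD 0.5, giving a realistic intensity CV of ≈ 0.5), multiplies by
the circadian envelope 1 + A·cos(2πt/24 h) and draws Poisson counts.  The
monotone link preserves rank correlations, so DFA exponents survive within
about ±0.1; the Poisson layer adds a white floor that biases short-scale
slopes slightly toward 0.5 at low mean counts.  Cohort-level recovery tests
use 4-day records at δ = 5 s with a mean of 8.25 counts/5 s (≈ 99 counts
per minute, a realistic geriatric inpatient level) and circadian amplitude
0, isolating the fractal component: a 24 h envelope adds an oscillatory,
non-stationary contribution at the long-range scales that is a genuine
confound of α₂ in real data but would make exponent-recovery tests measure
the envelope, not the estimator.

`generate_duration_process` draws low-period durations i.i.d. from the
requested tail family truncated at d_min and rounded to whole epochs, joins
them with exponential high periods (mean 600 s by default), and emits a
two-level series whose low epochs carry integer noise capped at 10% of the
gap between the low level and the overall mean — so dichotomization at the
mean provably returns the ground-truth durations exactly (the series starts
and ends with a high period, keeping every low period interior).
Calibration cohorts use lognormal (μ = 5.0, σ = 0.8 log-seconds; median
≈ 2.5 min) and power-law (β = 2.0) durations above d_min = 60 s at δ = 5 s,
with 1000 periods per subject — duration counts and magnitudes typical of
multi-week actigraphy.

What passing these tests shows: the estimators recover known generative
structure of the right kind and magnitude.  What it does not show: the
generator produces stationary (apart from the optional circadian envelope),
gap-free, Gaussian-driven signals; real actigraphy adds non-wear gaps,
day-to-day non-stationarity, device calibration drift, bouts with intensity
profiles no Poisson layer reproduces, and duration distributions that need
not belong to either fitted family.  Conclusions about real cohorts rest on
the robustness analyses (resolution spans, the γ diagnostic), not on the
recovery results alone.

## Numerical details

- Truncated-lognormal likelihood and CDF are evaluated through the normal
  log-survival function, stable even when a scan candidate pushes the
  truncation point many σ beyond μ; optimizer non-convergence raises with
  the last iterate and gradient norm.
- If the pointwise log-likelihood differences have zero variance (identical
  densities on the tail), the LLR (exactly 0) is still returned, with a NaN
  Vuong p and an explicit warning rather than an exception.
- Degenerate inputs raise typed errors: constant series (no dichotomy, no
  DFA slope, undefined IS/IV), tails below 10 durations, fewer than 3 grid
  points in a fit range, fewer than 2 days for circadian metrics.
- All generators and bootstraps are deterministic given their seeds.

## Problem sizes used in the shipped validation

Simulation sizes were chosen as the smallest that leave Monte-Carlo error
well below the asserted tolerances: 20 seeds × 2^16 samples for the DFA
reference exponents and mono-fractal recovery; a 20-subject, 4-day cohort
at five resolutions for crossover recovery and resolution-robustness; 100
replicates × 1000 durations for tail-selection calibration; 500 replicates
× 2000 resamples for bootstrap coverage.  The full suite runs in a few
minutes on one CPU.
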