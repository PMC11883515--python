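# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Respirometry model and estimators

An intermittent-flow trial alternates sealed *measure* phases and *flush*
phases on a fixed cycle (default 10 min: 6 min measure, 4 min flush — the
measure length matches the 6-min post-exercise monitoring convention).
Within a measure phase the oxygen decline is fitted by ordinary least
squares; the mass-specific uptake is

    MO2 = (−slope) · (V_chamber − m/1000) · 60 / (m/1000)  [mg O2 kg⁻¹ h⁻¹]

with the fish displacing its own volume of water at density 1 g mL⁻¹.
Phase labels are authoritative when present (so variable-length measure
phases, e.g. early flushes triggered at 80% saturation, are first-class);
a fixed schedule is used only for unlabeled traces. Windows with fewer
than 2 samples are dropped with a warning; windows with slope r² < 0.9 or
positive slope are flagged, never silently removed.

**MMR** is the MO2 of the first measurement cycle after the exhaustive
chase — deliberately *not* the maximum over cycles, which is available
behind `use_max_cycle=True` but off by default. Rolling-window maximum
slopes are out of scope.

**SMR** is the 0.20 quantile (linear interpolation between order
statistics) of MO2 over cycles starting at or after the 5-h exclusion
boundary (half-open: a cycle starting exactly at 300 min is included).
The alternative reading of "lowest 20th percentile" — the mean of the
lowest 20% of values — is implemented (`method="mean_lowest"`) but not the
default: the quantile is the estimator recommended in the respirometry
methods literature and is the stabler of the two. At least 10 cycles must
remain after exclusion.

Note that an interpolated quantile is not monotone under insertion of a
value just above it (the interpolation weight can shift onto the inserted
order statistic); the safe monotone properties — monotone in q, and in
values added at or above the maximum — are what the property tests assert.

**Background correction.** Empty-chamber slopes measured before and after
the trial are converted to mass-specific equivalents using the *full*
chamber volume (no fish present) and subtracted: pre-trial from MMR,
post-trial from SMR. The synthetic generator drifts the background
linearly from its pre- to its post-trial level, which is why the
asymmetric correction reduces bias. AS = MMR_c − SMR_c holds exactly for
every record; negative corrected values and MMR < SMR are flagged.

## Synthetic generator

The generator emulates every raw input with explicit ground truth:

* **Trait curves.** SMR(T) = a·e^{bT} with defaults a = 28 mg O2 kg⁻¹ h⁻¹,
  b = 0.063 °C⁻¹ (a Q10 of ~1.9, in the middle of the range such fishes
  exhibit); AS(T) Gaussian with amplitude 420 mg O2 kg⁻¹ h⁻¹, optimum
  29.2 °C and breadth 11.8 °C (the scale of published aerobic-scope fits
  for small reef fishes); MMR = SMR + AS, so MMR > SMR by construction.
* **Allometry.** Per-fish truths scale as (m/m_ref)^b with b = 0.8
  (typical metabolic mass exponent); masses are lognormal (median 1.4 g,
  log-sd 0.5, a small cryptobenthic fish); multiplicative lognormal
  individual variation with CV 10% by default — no between-individual
  variance model is available to copy, so this is a stated default.
* **Traces.** 18 h overnight trials sampled every 10 s at a saturation
  baseline of 6.8 mg L⁻¹ (typical warm seawater; the pipeline works in
  concentration units throughout). Post-exercise uptake decays toward SMR
  as a single exponential with time constant `epoc_tau` = 60 min, which
  makes the 5-h exclusion window meaningful (residual elevation
  e^{−5h/1h} < 1%). `epoc_tau = 0` is the idealised limit: the first cycle
  runs at exactly MMR, later cycles at exactly SMR, giving exact
  zero-noise recovery. Sensor noise is Gaussian (sd 0.005 mg L⁻¹);
  background slopes default to −2·10⁻⁴ (pre) and −4·10⁻⁴ (post)
  mg L⁻¹ min⁻¹ (microbial load grows over a trial).
* **CT trials.** Water ramps at 0.1 °C min⁻¹; internal temperature follows
  the first-order lag (below); loss of equilibrium fires when internal
  temperature crosses the individual's limit (default CTmax 39.5 °C,
  CTmin 8.7 °C, individual sd 0.3 °C).
* **SST.** Daily series = annual sinusoid + Gaussian noise (sd 0.3 °C),
  minimum in mid-February. Presets: a strongly seasonal sea (mean
  27.25 °C, amplitude 9.25 °C → annual range 18.5 °C, extremes
  36.5/18.0 °C) and a moderate one (mean 27.0, amplitude 5.5 → range
  11 °C).

What the generator does **not** emulate: chamber mixing hydrodynamics,
handling stress beyond the EPOC term, sensor drift/calibration error,
tides or weather in the SST (a pure sinusoid plus white noise), or
satellite-retrieval artefacts. Passing recovery tests therefore shows the
estimators are correct *given* this data model, not that real traces are
this clean; on real data the flags (low r², positive slopes, negative
corrected traits) matter.

All generators are deterministic given (config, seed); child seeds derive
from `numpy.random.SeedSequence`.

## Allometric correction

Log10–log10 regression space is the default (standard for metabolic
scaling; a linear-space option exists for sensitivity). Regions and
acclimation temperatures are pooled within species × trait, and the pivot
mass is the arithmetic mean over all fish entering that regression — the
separation is by species and trait only. Non-positive trait values are
excluded (with a warning) before the log transform. Because the pooled
regression shares one intercept across temperatures, its slope equals the
generative exponent exactly only when a single temperature is pooled (or
masses are balanced); the recovery tests are built accordingly.

## Thermal performance curves and Q10

The exponential fit is nonlinear least squares on the original scale,
initialised from the log-linear OLS solution; the quadratic is the exact
closed form; the Gaussian is bounded (breadth ∈ (0, 50] °C, optimum within
the sampled span ± 10 °C), initialised from temperature-binned means
(optimum at the largest binned mean, breadth at half the span), with 5
jittered restarts before a fit is declared unconverged. r² is
1 − SS_res/SS_tot on the original scale and may be negative; fits on flat
data end at the breadth bound and are flagged, and 3-temperature Gaussian
fits are exact-by-construction and flagged as such. Fits are performed on
individual fish values by default (group-mean fitting is a caller choice —
pass binned means).

Q10 over the commonly shared 22.0–31.5 °C span is computed from group-mean
trait values at those two acclimation temperatures, not from fitted
curves (fitted-curve Q10 is available via `TPCFit.predict`).

## Critical limits, environmental extremes, safety margins

Body temperature lags a linear ramp as dT_b/dt = k(T_w − T_b) with
k = k₀·m^(−γ); the closed form T_b = T_w ∓ (r/k)(1 − e^{−kt}) is applied
at the observed endpoint, with t the elapsed ramp time. The lag
coefficients are not identifiable from a CT endpoint alone, so they are
required configuration with documented defaults (k₀ = 1.2 min⁻¹ at 1 g,
γ = 0.33 — order-of-magnitude values for small fish); every corrected
table records the coefficients used, and k → ∞ recovers the raw
water-temperature limits for sensitivity analysis.

Environmental extremes are means across calendar years of the daily SST
maximum (and minimum). A partially covered year contributes its maximum
only if the configured summer months (default Jul–Sep, ≥ 20 days each)
are covered, and its minimum only if the winter months (Jan–Mar) are:
a truncated year otherwise biases the extreme toward the season it
happens to include. Annual medians/ranges drop years with < 300 days.

TSMs are per-individual: summer margin = CT_internal − mean annual
maximum; winter margin = mean annual minimum − CT_internal. Negative
margins are kept and flagged. Seasonal membership is by acclimation
temperature matching the regional seasonal map (strongly seasonal region:
35.5 °C summer / 18.0 °C winter; moderate region: 31.5 / 22.0). Cross-
species summaries are **unweighted** means of per-species means — the
regional gap is the mean of per-species (GO − AG) differences and the
seasonal grand mean is the mean of per-species means, so unequal sample
sizes do not tilt the comparison.

## Statistics

Temperature is categorical (discrete acclimation groups). The factorial
model is `response ~ C(temp) * C(region)` with Type-II sums of squares by
default (Type I available; they coincide on balanced designs, which the
tests verify); body mass enters as a covariate for CT models. An empty
temperature × region cell makes the interaction inestimable, so it is
dropped with a warning rather than silently NaN-ed.

The model-selection policy is explicit and logged: linear model →
Shapiro–Wilk on residuals (pass = p > 0.05) → on failure, Tukey ladder
transform of the response and refit → on failure again, PERMANOVA on the
untransformed response. The ladder scans
λ ∈ {−2, −1, −0.5, 0, 0.5, 1, 2} (0 = log, negative rungs negated to
preserve order, a shift of 1 − min(y) for non-positive samples) and keeps
the λ with the largest Shapiro–Wilk W — with one deliberate twist: λ = 1
is kept unless another rung improves W by more than 0.01. On
already-normal data the W of neighbouring rungs differs only by sampling
noise, and under a strict argmax the identity would be selected only about
a quarter of the time; the margin makes "no transformation needed" the
answer whenever it is defensible.

The PERMANOVA is implemented from scratch as the trace partition of the
Gower-centred matrix under nested hat matrices (sequential SS; main
effects in order, then the two-factor interaction), with unrestricted
permutation of raw observations and p = (1 + #{F* ≥ F}) / (1 + n_perm).
For Euclidean distances and a univariate response the pseudo-F is
numerically identical to the classical ANOVA F, which is the main
correctness oracle; a full-enumeration mode exists for small two-group
designs. Pairwise contrasts run either as cell-mean t contrasts with the
pooled residual variance or as two-group permutation tests, both followed
by the package's own Benjamini–Hochberg step-up (monotonicity enforced,
stable order restored). Two-sample tests default to pooled-variance
Student's t (Welch behind a flag) and an exact Mann–Whitney U when the
smaller group has ≤ 8 observations. All permutation procedures are
reproducible from (data, seed, n_perm).

## Problem sizes and numerical tolerances

The test suite and acceptance script choose sizes that make the Monte
Carlo assertions sharp while staying lightweight: zero-noise recovery
uses one single-temperature cohort (12 fish) and one five-temperature
equal-mass cohort (40 fish), asserted at 1e-6 relative; noisy recovery
uses replicate cohorts of 5 temperatures × 8 fish at ~12% individual CV
(200 replicates in the tests, 100 in the acceptance script); permutation
null calibration uses n = 20 with 199 permutations per test (2000
simulations in the tests, 1000 in the script). Closed-form/ODE agreement
for the lag model is asserted at 1e-6 °C over r ∈ {0.05, 0.1, 0.2},
k ∈ [0.01, 10] and ramps up to 300 min, with the ODE integrated at
rtol 1e-10. Nonlinear fits run with xtol = ftol = gtol = 1e-14 so that
noiseless recovery is limited by the optimiser, not the tolerance.

## Known limitations

* The lag coefficients (k₀, γ) are assumptions, not estimates; conclusions
  about internal limits inherit them. The no-lag limit bounds their effect.
* The pooled mass-scaling slope conflates temperature structure with
  allometry when masses are unbalanced across temperatures.
* Cross-species summary means of printed per-species values can differ in
  the second decimal from summaries computed over raw individuals (the
  winter-season grand mean is an example); this package defines the
  summary as the unweighted mean of per-species means and applies it
  consistently.
* The MANOVA is Euclidean-distance only, fixed effects only, with
  unrestricted raw permutation; restricted (within-block) permutation
  schemes are not implemented.
* The SST generator's sinusoid has no trend; long-term warming must be in
  the supplied data, not the preset.
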