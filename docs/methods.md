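# Methods

## Scope and model structure

`picost` is a per-case cost–consequence model, not a cost-effectiveness
analysis: it converts a short-term within-subject healing signal into
modeled healing-time and monetary consequences under explicit assumptions,
and quantifies how those consequences move when the assumptions do.  The
chain has five stages — effect estimation, baseline imputation, translation,
valuation, uncertainty — each implemented in its own module
(`effects`, `healing`, `costs`, `bootstrap`, `scenarios`) with the
`CostConsequenceModel` estimator composing them.

## Effect estimation

The unit of inference is the within-subject difference in daily wound-area
reduction, Δ, over 14-day periods.  The paired *t* interval uses the Student
quantile with *n* − 1 degrees of freedom (scipy); the Wilcoxon signed-rank
check drops zero differences and uses the exact null when there are no ties
(scipy's convention).  When every within-subject difference is identical the
*t* machinery degenerates (p set to 1 for a zero effect, 0 otherwise; CI
collapses) and the Wilcoxon p is flagged undefined.

Crossover diagnostics are the classical Grizzle-style contrasts: treatment
and period effects from between-sequence comparisons of within-patient
period differences, the carryover (sequence) diagnostic from within-patient
sums, all with equal-variance two-sample *t* tests — a deliberately simple
framework given 12 patients.  A first-period-only contrast is also
reported.  These are transparency checks, not confirmatory inference; at
*n* = 6 + 6 their power is low.

The acceleration ratio r = mean(ES)/mean(placebo) is carried only as a
translation parameter.  Its mean-based value on a calibrated cohort is
0.179/0.051 ≈ 3.51; the base case uses the constant 3.52 (the value implied
by unrounded patient-level means), configurable via
`TranslationSpec.r`/`CostConsequenceModel(base_case_r=...)`.  The
"median-based" ratio is ambiguous without patient-level data; the package's
default is the ratio of period medians, with the median of per-patient
ratios available as an option (`median_ratio_method="per_patient"`), since
per-patient ratios explode when a patient's placebo reduction is near
zero — the opposite of the robustness the summary is meant to provide.
Neither variant is asserted to reproduce any particular published value.

## Baseline imputation and translation

Baseline time to heal is a lookup in a depth × DESIGN-R-category table of
published median healing days (superficial 15/33/140, deep 26/63/259 for
≤9 / 10–18 / ≥19 points).  Category boundaries are inclusive integers;
DESIGN-R totals are integers so no boundary ambiguity exists.  The table
validates that medians are positive and non-decreasing in severity within
each depth.

Constant-ratio translation divides the baseline by r.  The
diminishing-acceleration rule addresses the strong assumption that a 14-day
acceleration persists over months of healing: progress accrues at rate r
per day during the `accel_window_days` treatment window (default 14, the
trial's period length) and at 1 + κ(r − 1) afterwards.  Closed form:

    T_ES = T_placebo / r                        if T_placebo ≤ r·w
    T_ES = w + (T_placebo − r·w) / (1 + κ(r−1)) otherwise

κ = 1 recovers the constant rule, κ = 0 removes all post-window benefit;
the default κ = 0.5 is the midpoint of that range.  This two-phase form was
chosen as the simplest rule that nests both extremes; no functional form
for attenuation is established empirically.  The closed form is verified
against a day-stepping simulator in the test suite (agreement < 0.01 days).

Whether the ratio is applied to per-patient baselines and then averaged, or
to the mean baseline, is irrelevant under the constant rule (both give the
same mean) but not under the diminishing rule; the bootstrap applies the
translation to the resample's mean baseline, and `project_case` to whatever
baseline it is given.

## Valuation and costs

All money is nominal JPY, provider perspective.  The per-day value proxy
(JPY 4000/day) is the sum of procedures 1000, labor 1500 (30 min/day ×
JPY 50/min), support surfaces 500 (15,000/month), nutrition 1000 (2 ×
JPY 500 servings); it is a budget-impact proxy, not an accounting cost, and
is therefore swept over 3000–10,000 in sensitivity analysis.  The fixed
implementation cost is round(77,000/12) + 3,600 = JPY 10,017 per case — the
device allocation is rounded to whole JPY *before* summing, reproducing the
published arithmetic chain.  ES labor (JPY 750/day) accrues over every day
of T_ES, per the per-day construction of the average implementation cost
C_impl/day = fixed/T_ES + 750.  Negative days saved (r < 1) propagate to
negative offsets rather than being floored, so downside scenarios are
visible.  Internally everything is full precision; the reporting layer
rounds days to one decimal and money to whole JPY (half away from zero).

Break-even: the maximum average per-day implementation cost with
non-negative net impact is v·(T_placebo − T_ES)/T_ES, which equals
v·(r − 1) under constant-ratio translation.  Net impact > 0 exactly when
the realized average implementation cost is below this threshold; the test
suite asserts the equivalence of both published net-impact formulations on
randomized inputs.

## Synthetic cohort generator

The trial's patient-level records are not public, so the generator emulates
the study conditions: 12 deep-PI patients (5 at DESIGN-R 10–18, 7 at ≥19),
14-day periods, alternating then seed-shuffled sequence assignment, and
period means of daily reduction equal to 0.179 (ES) and 0.051 (placebo)
cm²/day.  Per-patient (ES, placebo) reductions are drawn from a bivariate
normal and affinely recentred so the cohort means hit the targets exactly;
Δ = 0.128 cm²/day is therefore reproduced on every seed by construction.

Defaults for what the study does not report:

- dispersion sd_es = sd_pl = 0.138 cm²/day, correlation 0.5 — obtained by
  inverting the reported Δ confidence interval (half-width 0.0875 at
  *n* = 12 implies sd(diff) ≈ 0.138; with equal sds and ρ = 0.5,
  sd(diff) = sd);
- start areas lognormal with median 8 cm², log-sd 0.5 — strictly positive
  and right-skewed at a typical deep-PI scale;
- placebo reductions may be negative (wound growth), deliberately: ratio
  denominators straddling zero are the documented source of bootstrap
  instability.

Areas are chained within a patient (period 2 starts where period 1 ended).
When a drawn start area cannot accommodate the drawn reductions, the start
area is raised so the wound closes exactly at the period end; the event
count is exposed as `Cohort.n_floor_adjusted`.  Raising the start (rather
than truncating the end) keeps the realized area-derived reductions equal
to the drawn ones, preserving exact mean calibration alongside
non-negativity.

What the generator does **not** emulate: measurement error in wound
tracing, temporal within-period dynamics (only endpoints exist), carryover,
dropouts, and any real joint distribution of severity and healing rate.
Tests passing on generated cohorts therefore validate the *model
machinery* — calibration, invariances, interval mechanics — not clinical
generalizability.

## Bootstrap

Patient-level nonparametric bootstrap, default 10,000 iterations,
`numpy.random.default_rng(seed)` for determinism.  Each resample (patients
with replacement) recomputes r (mean method), the mean baseline from the
resample's stratum mix (so cohort-composition uncertainty propagates into
the baseline), and every downstream output including per-iteration
re-amortization of fixed costs.  Intervals are 2.5th/97.5th percentiles
with linear interpolation between order statistics (numpy default),
documented so results are reproducible across implementations.

Resamples whose period means are not both positive leave r (hence T_ES)
undefined.  They are excluded from the percentile computation, counted in
`n_degenerate`, and a warning fires when they exceed 1% of iterations.
Under the default calibrated cohort this warning is expected: a placebo
mean of 0.051 with sd 0.138 straddles zero, which is also why the r draws
are strongly right-skewed (mean > median) — the same instability the
trimmed-ratio summary (mean of draws strictly inside the central 95% band)
is designed to damp.  Stratum-level bootstraps resample within stratum with
T_placebo fixed to the stratum median.

Known limitation, measured by the acceptance suite: at *n* = 12 the
percentile interval for r covers a known simulated population ratio in
about 91% of replications rather than 95%, with symmetric misses — the
familiar small-sample narrowing of percentile intervals (≈√((n−1)/n))
compounded by the skew of a ratio statistic.  The enumeration oracle on
3-patient cohorts confirms the percentile engine itself is exact, so this
is a property of the method at this sample size, not of the
implementation.  BCa or studentized intervals would mitigate it but are
deliberately out of scope.

## Scenario grid

Scenarios are declarative records (name, per-day value, ratio source and
multiplier, baseline multiplier, translation mode, optional alternative
table) executed by a pure function — no state between runs.  The bundled
preset covers the prespecified analyses: value grid 3000–10,000, r ± 20%,
median-based and trimmed ratios, diminishing acceleration, baseline
× 0.7/0.8/1.2/1.3, and a depth-unstratified variant.  For the latter no
pooled medians are published; the shipped substitute applies the deep-wound
medians to both depth classes (every trial wound was deep) and is labelled
illustrative — an explicit `alternative_table` is required rather than
silently defaulting, because inventing pooled medians would fabricate
data.

## Numerical and design choices

- Scenario-size choices in the test and acceptance suites (e.g. 1,000
  coverage replications with 10,000-iteration bootstraps, 100,000-draw
  enumeration comparisons, 500-seed parameter-recovery runs) balance
  Monte-Carlo error against runtime; all are seeded and deterministic.
- Equality tolerances: exact-by-construction identities are asserted at
  ~1e-12 relative; published rounded values at their printed precision.
- Degenerate inputs fail loudly and specifically: zero placebo mean →
  undefined-ratio error; negative denominator → polarity warning with the
  value returned; empty sequence group → diagnostics error; t_es ≤ 0 →
  amortization error.
- The base-case device-sharing assumption (12 cases/device) is
  conservative; higher throughput lowers the fixed per-case cost linearly
  via `cases_per_device`.
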