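# Methods

This note documents the models, conventions and design choices behind
`mppycost`: what each stage assumes, which knobs matter, and what the
synthetic data do and do not establish about real cohorts.

## Person-time and the MPPY estimator

Each patient contributes two observation windows around their enrolment
(baseline) date.  The pre window is the full year `[baseline − 365 d,
baseline)` — the design enrols only patients with a complete prior year of
care, so pre-baseline exposure is never censored.  The post window is
`[baseline, min(baseline + 365 d, death, loss to follow-up))`.  All
intervals are half-open: an event dated on the censoring day is not
counted, and person-days are exact integer differences of dates.  The year
is fixed at 365 days; leap days are deliberately ignored so that rates,
person-years and the ×365 scaling are mutually consistent.

MPPY is the pooled ratio — total events over total person-days, times
365 — not the mean of per-patient rates.  The two disagree whenever
person-time varies between patients; the pooled form weights each patient
by exposure and is the quantity whose numerator is a sum of Poisson
counts.  Patients contributing zero person-time to a period (e.g. death
recorded on the baseline date) are excluded from that period's denominator
with a logged warning, never silently zero-filled; a death date before
baseline is a validation error because such a patient cannot exist in this
design.

The confidence interval is the exact Garwood construction from gamma
quantiles: with k events in T person-years,
`lower = Q_gamma(α/2; k)/T` (0 when k = 0) and
`upper = Q_gamma(1 − α/2; k + 1)/T`.  Endpoints satisfy the Poisson tail
equations `P(X ≥ k | λ = lower·T) = α/2` and `P(X ≤ k | λ = upper·T) =
α/2`, so the interval is conservative: true coverage is at least the
nominal level for every rate.  Person-time is treated as fixed, which
matches the design (follow-up is administratively censored at one year and
censoring events are rare).  The equivalent chi-square form would agree to
floating-point precision.  The default level is 0.95 and is configurable
in (0, 1).

## Microcosting

Unit costs are top-down expenditure-based.  A department's direct annual
cost is the sum of its SCOPE categories (staff, consumables, procedures,
equipment — equipment entering as an annual figure supplied by the user,
since no annuitization schedule is modelled); overheads are a single
multiplicative percentage apportioned by the hospital finance office, as a
required configuration value rather than a hard-coded default.  Unit cost
= direct total × (1 + overhead) / workload.  Pooling across departments
that produce interchangeable units (the combined-laboratory and radiology
cases) sums loaded costs and workloads, which makes the pooled unit cost
the workload-weighted average of departmental unit costs and bounds it by
their minimum and maximum.

The reference schedule used throughout (EUR, 2017 prices) is €96 per
outpatient visit, €3 per combined laboratory test, €18 per radiological
investigation, €1,001 non-ARV pharmacy per patient-year and €9,976 ARV
per patient-year.  The clinic's headline annual pharmacy services figure
(€1,135) differs from the €1,001 per-patient-year component that the
published totals require; both are stored on the schedule
(`pharmacy_annual_billed` vs `pharmacy_annual_pppy`) and the latter is
what enters aggregation.

## Cost aggregation and comparison

ACPPY = MPPY × unit cost, with the Poisson CI scaled by the same
constant: unit costs are treated as known constants, so all sampling
uncertainty in a cost component comes from the count process.  Money is
`decimal.Decimal` end to end; subtotals and totals are exact sums of their
parts, and half-up rounding to whole euros (and whole percent) happens
only when a report is rendered.

The reference ("fixture") reproduction path feeds the *printed* component
costs into the aggregation rather than recomputing rate × unit cost,
because the published subtotals are sums of independently rounded
components (3.1 × 96 = 297.6 prints as €301 upstream of rounding).  The
product path is validated separately at €1 tolerance (2.0 × 96 = 192
against the printed €193); the totals path is exact.

ICER = (Cost A − Cost B)/(Outcome A − Outcome B).  The minimal clinically
important difference (mcid, per outcome measure, default 0) gates the
ratio: an outcome difference within mcid means equivalence, an undefined
ICER, and a cost-minimization classification — the evaluated pathway's
own situation, where outcomes were stable and the comparison reduces to
the €109 annual saving per patient-year.  In the patient-level pipeline
the fixture's null outcome difference is replaced by observed month-0 to
month-12 median changes per measure, so with the default mcid of 0 any
nonzero sample change yields a defined ICER; setting a per-measure mcid is
how a user encodes "did not change substantially".

## Outcome processing

Viral loads are log10-transformed; values below the assay detection limit
(default 50 copies/mL) are floored at the limit and flagged rather than
imputed.  Summaries are median and quartiles under the linear-interpolation
quantile convention (the numpy default, fixed here so results are
reproducible across tools), plus mean and an explicit missing count.
Trajectories over the two-year window are condensed by a trapezoidal
time-weighted mean — area under the piecewise-linear value–time curve over
the span — which returns the plain value with a warning for degenerate
single-timepoint series.  Mixed-effects modelling of within-patient
covariance is intentionally out of scope: the package's comparison surface
is descriptive (medians, IQRs, time-weighted means, before/after deltas).

## The synthetic cohort generator

The generator emulates the study conditions, and its defaults *are* those
conditions: 586 patients enrolled over a two-year window; homogeneous
Poisson service use at 3.1/2.0 (visits), 246.9/253.1 (laboratory tests)
and 2.8/1.7 (radiology) events per patient-year pre/post; rare censoring
(annual death probability 0.005, loss to follow-up 0.01 — the study
reports censoring only as rare, so these are chosen to give a handful of
events in 586 patients); CD4 log-normal calibrated to median 723 and IQR
506–944 cells/mm³; viral load log-normal with median 36 and IQR 26–65
copies/mL against a 50 copies/mL limit; PAM-13 normal clamped to [0, 100]
with median 70.2 and IQR 60.6–77.7.  PROQOL-HIV has no published summary
row here; its defaults (median 65, IQR 52–78 on a 0–100 scale) are
synthetic calibration targets only and are excluded from any acceptance
check.

Modelling choices where the design was open: event counts are Poisson
with mean rate × exposed-days/365 and event dates uniform within the
exposed interval (the maximum-entropy placement consistent with a
homogeneous Poisson process — only annual rates are specified); censoring
dates are uniform within the post year; log-normal shapes are set by the
quartile ratio `σ = ln(q75/q25)/(2 z₀.₇₅)` with the median pinned exactly,
which reproduces the median and quartile *ratio* but not both printed
quartiles when the target IQR is more skewed than a log-normal; CD4 has a
patient-level set point plus small within-patient visit noise (σ = 0.05 on
the log scale), so cross-sectional spread is between-patient while
longitudinal deltas are nearly null — exactly the stable-cohort null the
analysis should recover.

Reproducibility: one master seed; each patient draws from a private
substream keyed by (seed, stable hash of patient id, stream), with
separate streams for event/censoring draws and outcome draws.
Consequences: identical parameters give byte-identical CSVs, enlarging
the cohort leaves existing patients untouched, and regenerating outcomes
never perturbs event dates.

What passing tests on this generator establish: that the estimation and
costing pipeline recovers known rates under the study's own censoring and
sample-size conditions, and that the exact intervals hold their coverage.
What they do not establish: behaviour under within-patient rate
heterogeneity (no negative-binomial overdispersion), visit-interval
structure, behavioural responses to the pathway, ART regimen changes, or
informative censoring — none of which the generator models.

## Problem sizes in the checked suites

Calibration of empirical rates against configured rates uses a single
5,000-patient cohort at 2% relative tolerance.  Parameter recovery runs
200 replicate cohorts of 100 patients and requires each service type's
configured rates inside the exact 95% CI in at least 93% of checks
(pre and post periods both counted; Poisson-exact coverage is independent
of cohort size, so replicate size trades only Monte-Carlo time).  Interval
coverage is measured on 2,000 simulated totals at 586 patient-years and
rate 3.1.  The Monte-Carlo check of the generator against the closed-form
Poisson oracle uses 100 seeds and a three-standard-error band around the
oracle probability of landing in the published interval.

## Known limitations

* Overhead apportionment is a single percentage; no step-down allocation
  across hospital sites is modelled, matching the expenditure data
  actually available to such costings.
* Currency handling is a single ISO code with no conversion or inflation
  indexing.
* The ICER surface is deterministic: no probabilistic sensitivity
  analysis, discounting, or QALY weighting.
* Outcome comparisons are descriptive; no within-patient correlation
  model, and missingness is counted, never imputed.
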