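# mppycost

Before/after economic evaluation of outpatient care pathways: censored
person-time service-use rates with exact Poisson confidence intervals,
departmental microcosting, annual cost aggregation per patient-year, and
cost-minimization / ICER comparison — with a synthetic patient-level
cohort generator so the whole pipeline is testable end to end.

## The problem

mHealth care pathways let medically stable patients — here, people living
with HIV attending a large Lisbon outpatient clinic — replace some
face-to-face visits with app-mediated review of results and messaging.
Does that save money without harming outcomes?  The evaluation design is a
pre-post comparison: each of n = 586 participants contributes one year of
service use before their enrolment (baseline) date and up to one year
after it, right-censored at death or loss to follow-up.

## The statistics

**Service use.**  The mean number of services used per patient-year
(MPPY) is a pooled person-time ratio, not a mean of per-patient rates:

```
M = ( Σᵢ Σⱼ Sᵢⱼ ) / ( Σᵢ Σⱼ (tᵢⱼ − tᵢ(ⱼ₋₁)) ) × 365
```

where `Sᵢⱼ` is patient *i*'s use of the service on day *j* and the
denominator is total censored follow-up in days.  Windows are half-open
`[start, end)`; the pre window is always `[baseline − 365 d, baseline)`,
the post window ends at the earliest of `baseline + 365 d`, death, or loss
to follow-up.  Uncertainty is an exact (Garwood) Poisson interval from
gamma quantiles, treating person-time as fixed; exact intervals are
conservative (coverage ≥ nominal).

**Costs.**  Departmental unit costs come from SCOPE microcosting (Staff,
Consumables, Overheads, Procedures, Equipment): annual expenditure with an
apportioned overhead percentage, divided by annual workload; departments
producing interchangeable units (e.g. several laboratories) pool
workload-weighted.  ACPPY (average annual cost per patient-year) is
MPPY × unit cost, with the CI scaled by the same constant.  Per period:
components → subtotal → + pharmacy annual → outpatient-services total →
+ ARV annual → grand total, all in exact decimal euros.

**Comparison.**  ICER = (Cost A − Cost B)/(Outcome A − Outcome B).  When
the outcome difference is within the minimal clinically important
difference, the ratio is undefined and the comparison collapses to a
cost-minimization; a cheaper, at-least-as-effective alternative is
cost-saving dominant.

## Worked example

Reproduce the published comparison table from the printed rates and unit
costs (no simulation involved — once rates and unit costs are fixed, the
cost pipeline is closed arithmetic):

```sh
mppycost run-all --fixture --outdir results/fixture
```

`results/fixture/report.md` then contains:

```
| Services | Before | 95% CI | After | 95% CI | Change |
|---|---|---|---|---|---|
| Mean outpatient visits (MPPY) | 3.1 | 3.0–3.3 | 2.0 | 1.9–2.1 | 35% decrease |
| Average costs, outpatient visits | €301 | €288–€316 | €193 | €182–€204 | 36% decrease |
| Mean laboratory tests (MPPY) | 246.9 | 244.9–247.5 | 253.1 | 251.9–254.5 | 3% increase |
| Average costs, laboratory tests | €741 | €735–€743 | €759 | €756–€764 | 2% increase |
| Mean radiology investigations (MPPY) | 2.8 | 2.6–2.9 | 1.7 | 1.6–1.8 | 39% decrease |
| Average costs, radiology investigations | €50 | €47–€52 | €31 | €29–€32 | 38% decrease |
| Subtotal average costs | €1,092 |  | €983 |  | 10% decrease |
| Annual pharmacy costs excluding ARVs | €1,001 |  | €1,001 |  | 0% |
| Average annual outpatient services costs | €2,093 |  | €1,984 |  | 5% decrease |
| Annual ARV costs | €9,976 |  | €9,976 |  | 0% |
| Total annual costs | €12,069 |  | €11,960 |  | 1% decrease |
```

Reading: outpatient visits fell 35% (3.1 → 2.0 per patient-year) and
their annual cost per patient-year fell €301 → €193; the
outpatient-services total fell 5% (€2,093 → €1,984); with antiretroviral
drugs included the grand total fell 1% (€12,069 → €11,960), ARVs being
83% of the total.  Outcomes (CD4, viral load, PAM-13, PROQOL-HIV) did not
change substantially, so `comparison.json` classifies the result as a
cost-minimization with an annual saving of €109 per patient-year.

The same pipeline runs on patient-level data — synthetic or real:

```sh
mppycost run-all --seed 1 --outdir results/synthetic        # simulate n=586
mppycost run-all --input mydata/ --outdir results/mydata    # your CSVs
```

with `patients.csv` (patient_id, baseline_date, death_date, ltfu_date),
`events.csv` (patient_id, service_type, event_date) and `outcomes.csv`
(patient_id, timepoint_months, measure, value); dates ISO-8601.

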