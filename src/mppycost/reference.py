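"""Published point estimates for the Lisbon mHealth-pathway evaluation.

These are the printed results of the 586-patient before/after evaluation
at a Lisbon HIV outpatient clinic (2017 financial year, EUR): Poisson
service-use rates with exact 95% CIs, the microcosted unit costs, the
annual cost build-up per period, and the PAM-13 summaries.  They let the
economic comparison be reproduced exactly at desk scale — once rates and
unit costs are fixed, the cost pipeline is closed arithmetic — without
access to the patient-level records, and they double as calibration
targets for the synthetic cohort generator.

The printed annual-cost components are sums of rounded figures (e.g. the
visit cost €301 comes from an unrounded rate near 3.1 multiplied by €96),
so the fixture carries the printed component values verbatim rather than
recomputing rate × unit cost; totals then match the published table to the
euro.
"""

from __future__ import annotations

from decimal import Decimal

from .costing import CostSchedule, UnitCost, build_cost_schedule
from .economics import (
    ACPPYComponent,
    AnnualCostSummary,
    PeriodComparison,
    compare_periods,
)
from .mppy import MPPYEstimate
from .outcomes import OutcomeSummary

__all__ = [
    "reference_cost_schedule",
    "reference_mppy_estimates",
    "reference_acppy_components",
    "reference_summaries",
    "reference_comparison",
    "reference_pam13_summaries",
]

# Published MPPY (rate, ci_low, ci_high) per (service type, period).
_MPPY = {
    ("outpatient_visit", "pre"): (3.1, 3.0, 3.3),
    ("outpatient_visit", "post"): (2.0, 1.9, 2.1),
    ("lab_test", "pre"): (246.9, 244.9, 247.5),
    ("lab_test", "post"): (253.1, 251.9, 254.5),
    ("radiology", "pre"): (2.8, 2.6, 2.9),
    ("radiology", "post"): (1.7, 1.6, 1.8),
}

# Published ACPPY euro components (value, ci_low, ci_high).
_ACPPY = {
    ("outpatient_visit", "pre"): (301, 288, 316),
    ("outpatient_visit", "post"): (193, 182, 204),
    ("lab_test", "pre"): (741, 735, 743),
    ("lab_test", "post"): (759, 756, 764),
    ("radiology", "pre"): (50, 47, 52),
    ("radiology", "post"): (31, 29, 32),
}

_PHARMACY_PPPY = 1001  # per-patient-year component entering the totals
_PHARMACY_BILLED = 1135  # headline annual non-ARV pharmacy services figure
_ARV_PPPY = 9976


def reference_cost_schedule() -> CostSchedule:
    """Microcosted unit costs: €96/visit, €3/test, €18/investigation."""
    return build_cost_schedule(
        [
            UnitCost("outpatient_visit", 96.0, "per_visit"),
            UnitCost("lab_test", 3.0, "per_test"),
            UnitCost("radiology", 18.0, "per_investigation"),
        ],
        pharmacy_annual=_PHARMACY_PPPY,
        arv_annual=_ARV_PPPY,
        currency="EUR",
        price_year=2017,
        pharmacy_annual_billed=_PHARMACY_BILLED,
    )


def reference_mppy_estimates() -> dict[str, dict[str, MPPYEstimate]]:
    """Published rates keyed as [period][service_type] (no raw counts)."""
    out: dict[str, dict[str, MPPYEstimate]] = {"pre": {}, "post": {}}
    for (stype, period), (rate, lo, hi) in _MPPY.items():
        out[period][stype] = MPPYEstimate(
            service_type=stype, period=period, mppy=rate, ci_low=lo,
            ci_high=hi, level=0.95,
        )
    return out


def reference_acppy_components() -> dict[str, list[ACPPYComponent]]:
    """Published euro components keyed by period."""
    out: dict[str, list[ACPPYComponent]] = {"pre": [], "post": []}
    for (stype, period), (value, lo, hi) in _ACPPY.items():
        out[period].append(
            ACPPYComponent(
                service_type=stype, period=period, acppy=Decimal(value),
                ci_low=Decimal(lo), ci_high=Decimal(hi),
            )
        )
    return out


def reference_summaries() -> tuple[AnnualCostSummary, AnnualCostSummary]:
    """Annual cost build-ups whose totals match the published table exactly."""
    components = reference_acppy_components()
    summaries = []
    for period in ("pre", "post"):
        comps = tuple(components[period])
        subtotal = sum((c.acppy for c in comps), Decimal(0))
        outpatient = subtotal + Decimal(_PHARMACY_PPPY)
        summaries.append(
            AnnualCostSummary(
                period=period,
                components=comps,
                subtotal=subtotal,
                pharmacy_annual=Decimal(_PHARMACY_PPPY),
                outpatient_services_total=outpatient,
                arv_annual=Decimal(_ARV_PPPY),
                grand_total=outpatient + Decimal(_ARV_PPPY),
                currency="EUR",
            )
        )
    return summaries[0], summaries[1]


def reference_comparison() -> PeriodComparison:
    """The full published before/after comparison table."""
    pre, post = reference_summaries()
    est = reference_mppy_estimates()
    return compare_periods(pre, post, mppy_pre=est["pre"], mppy_post=est["post"])


def reference_pam13_summaries() -> tuple[OutcomeSummary, OutcomeSummary]:
    """PAM-13 medians/IQRs at month 0 and month 12 (n not published per row)."""
    month0 = OutcomeSummary(measure="pam13", timepoint=0, n=586, median=70.2,
                            iqr_low=60.6, iqr_high=77.7, mean=float("nan"))
    month12 = OutcomeSummary(measure="pam13", timepoint=12, n=586, median=67.8,
                             iqr_low=58.1, iqr_high=75.0, mean=float("nan"))
    return month0, month12
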