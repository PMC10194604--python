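"""Annual costs per patient-year, period comparison, and ICER.

Costs build up as ACPPY (average annual cost per patient-year): a service's
MPPY multiplied by its unit cost, with the Poisson confidence interval
scaled by the same constant (unit costs are treated as fixed, without
sampling uncertainty).  Per period, components sum to a subtotal, plus the
fixed non-ARV pharmacy annual cost gives the outpatient-services total,
plus the annual ARV cost gives the grand total.

Money is exact `decimal.Decimal` arithmetic throughout — totals equal the
sum of their parts with no float drift — and is rounded half-up to whole
euros (and whole percent) only when rendered.

The incremental cost-effectiveness ratio ICER = ΔCost/ΔOutcome between two
alternatives A and B degrades gracefully: when the outcome difference is
within the minimal clinically important difference (mcid), outcomes are
equivalent and the comparison collapses to cost minimization; when B costs
less and does at least as well, B is cost-saving dominant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .costing import CostSchedule, UnitCost
from .errors import UndefinedChangeError, ValidationError
from .mppy import MPPYEstimate

__all__ = [
    "ACPPYComponent",
    "AnnualCostSummary",
    "ICERResult",
    "ComparisonRow",
    "PeriodComparison",
    "acppy",
    "annual_cost_summary",
    "percent_change",
    "format_percent_change",
    "icer",
    "compare_periods",
    "round_euro",
]


def _D(x) -> Decimal:
    """Exact decimal from a number, via its shortest string form."""
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


def round_euro(x) -> int:
    """Half-up rounding to whole euros, applied only at report time."""
    return int(_D(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ACPPYComponent:
    """One service's annual cost per patient-year with scaled CI."""

    service_type: str
    period: str
    acppy: Decimal
    ci_low: Decimal
    ci_high: Decimal

    def __post_init__(self) -> None:
        if not self.ci_low <= self.acppy <= self.ci_high:
            raise ValidationError(
                f"ACPPY CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"{self.acppy}"
            )


@dataclass(frozen=True)
class AnnualCostSummary:
    """Per-period cost build-up: components → subtotal → totals."""

    period: str
    components: tuple[ACPPYComponent, ...]
    subtotal: Decimal
    pharmacy_annual: Decimal
    outpatient_services_total: Decimal
    arv_annual: Decimal
    grand_total: Decimal
    currency: str = "EUR"

    def __post_init__(self) -> None:
        if sum(c.acppy for c in self.components) != self.subtotal:
            raise ValidationError("subtotal != sum of component ACPPYs")
        if self.subtotal + self.pharmacy_annual != self.outpatient_services_total:
            raise ValidationError(
                "outpatient_services_total != subtotal + pharmacy_annual"
            )
        if self.outpatient_services_total + self.arv_annual != self.grand_total:
            raise ValidationError(
                "grand_total != outpatient_services_total + arv_annual"
            )


def acppy(est: MPPYEstimate, uc: UnitCost) -> ACPPYComponent:
    """Scale an MPPY estimate and its CI by a per-event unit cost."""
    if uc.basis == "per_patient_year":
        raise ValidationError(
            f"{uc.service_type}: ACPPY needs a per-event unit cost, got "
            "basis 'per_patient_year' (annual costs enter totals directly)"
        )
    if est.service_type != uc.service_type:
        raise ValidationError(
            f"service type mismatch: estimate {est.service_type!r} vs unit "
            f"cost {uc.service_type!r}"
        )
    amount = _D(uc.amount)
    return ACPPYComponent(
        service_type=est.service_type,
        period=est.period,
        acppy=_D(est.mppy) * amount,
        ci_low=_D(est.ci_low) * amount,
        ci_high=_D(est.ci_high) * amount,
    )


def annual_cost_summary(
    components: Iterable[ACPPYComponent],
    schedule: CostSchedule,
    period: str,
) -> AnnualCostSummary:
    """Aggregate one period's components into the annual cost build-up."""
    components = tuple(components)
    seen: set[str] = set()
    for c in components:
        if c.period != period:
            raise ValidationError(
                f"component {c.service_type!r} has period {c.period!r}, "
                f"expected {period!r}"
            )
        if c.service_type in seen:
            raise ValidationError(
                f"duplicate component for service type {c.service_type!r}"
            )
        seen.add(c.service_type)
    expected = set(schedule.unit_costs)
    if expected and seen != expected:
        raise ValidationError(
            f"components {sorted(seen)} do not cover the schedule's service "
            f"types {sorted(expected)}"
        )
    subtotal = sum((c.acppy for c in components), Decimal(0))
    pharmacy = _D(schedule.pharmacy_annual_pppy)
    arv = _D(schedule.arv_annual_pppy)
    outpatient = subtotal + pharmacy
    return AnnualCostSummary(
        period=period,
        components=components,
        subtotal=subtotal,
        pharmacy_annual=pharmacy,
        outpatient_services_total=outpatient,
        arv_annual=arv,
        grand_total=outpatient + arv,
        currency=schedule.currency,
    )


def percent_change(before, after) -> float:
    """(after − before) / before × 100; undefined for a zero baseline."""
    before_d, after_d = _D(before), _D(after)
    if before_d == 0:
        raise UndefinedChangeError("percent change from a zero baseline is undefined")
    return float((after_d - before_d) / before_d * 100)


def format_percent_change(pct: float) -> str:
    """Render a signed percent change the way reports print it.

    Half-up integer rounding on the magnitude: -35.48 → "35% decrease".
    """
    magnitude = int(_D(abs(pct)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if magnitude == 0:
        return "0%"
    direction = "decrease" if pct < 0 else "increase"
    return f"{magnitude}% {direction}"


@dataclass(frozen=True)
class ICERResult:
    cost_a: Decimal
    cost_b: Decimal
    outcome_a: float
    outcome_b: float
    mcid: float
    icer: float | None
    classification: str  # icer | cost_saving_dominant | cost_minimization

    @property
    def cost_difference(self) -> Decimal:
        """Cost of B minus cost of A (negative when B is cheaper)."""
        return self.cost_b - self.cost_a


def icer(cost_a, cost_b, outcome_a: float, outcome_b: float,
         mcid: float = 0.0) -> ICERResult:
    """Incremental cost-effectiveness ratio, or the degenerate cases.

    ICER = (cost_a − cost_b) / (outcome_a − outcome_b).  If the outcome
    difference is within ``mcid`` the outcomes are equivalent, the ratio is
    undefined, and the comparison is a cost-minimization; if B is cheaper
    and at least as effective (beyond mcid), B dominates.
    """
    if mcid < 0:
        raise ValidationError(f"mcid must be >= 0, got {mcid}")
    cost_a_d, cost_b_d = _D(cost_a), _D(cost_b)
    d_outcome = outcome_a - outcome_b
    if abs(d_outcome) <= mcid:
        classification = "cost_minimization"
        value = None
    else:
        value = float((cost_a_d - cost_b_d) / _D(d_outcome))
        if cost_b_d < cost_a_d and outcome_b >= outcome_a:
            classification = "cost_saving_dominant"
        else:
            classification = "icer"
    return ICERResult(
        cost_a=cost_a_d, cost_b=cost_b_d, outcome_a=outcome_a,
        outcome_b=outcome_b, mcid=mcid, icer=value,
        classification=classification,
    )


@dataclass(frozen=True)
class ComparisonRow:
    """One before/after line: a usage rate or a money amount."""

    label: str
    kind: str  # "usage" or "cost"
    before: float | Decimal
    after: float | Decimal
    before_ci: tuple[float, float] | None = None
    after_ci: tuple[float, float] | None = None

    @property
    def abs_change(self):
        return self.after - self.before

    @property
    def pct_change(self) -> float | None:
        try:
            return percent_change(self.before, self.after)
        except UndefinedChangeError:
            return None


@dataclass(frozen=True)
class PeriodComparison:
    """Before/after comparison across the full cost build-up."""

    rows: tuple[ComparisonRow, ...]
    pre: AnnualCostSummary
    post: AnnualCostSummary
    currency: str = "EUR"

    @property
    def arv_share_before(self) -> float:
        if self.pre.grand_total == 0:
            return 0.0
        return float(self.pre.arv_annual / self.pre.grand_total * 100)

    @property
    def arv_share_after(self) -> float:
        if self.post.grand_total == 0:
            return 0.0
        return float(self.post.arv_annual / self.post.grand_total * 100)

    def to_dict(self) -> dict:
        def money(x) -> float:
            return float(x)

        return {
            "currency": self.currency,
            "rows": [
                {
                    "label": r.label,
                    "kind": r.kind,
                    "before": money(r.before),
                    "after": money(r.after),
                    "before_ci": list(map(float, r.before_ci)) if r.before_ci else None,
                    "after_ci": list(map(float, r.after_ci)) if r.after_ci else None,
                    "abs_change": money(r.abs_change),
                    "pct_change": r.pct_change,
                }
                for r in self.rows
            ],
            "subtotal": {"before": money(self.pre.subtotal),
                         "after": money(self.post.subtotal)},
            "outpatient_services_total": {
                "before": money(self.pre.outpatient_services_total),
                "after": money(self.post.outpatient_services_total),
            },
            "grand_total": {"before": money(self.pre.grand_total),
                            "after": money(self.post.grand_total)},
            "arv_share_pct": {"before": self.arv_share_before,
                              "after": self.arv_share_after},
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "kind": r.kind,
                    "before": float(r.before),
                    "after": float(r.after),
                    "abs_change": float(r.abs_change),
                    "pct_change": r.pct_change,
                }
                for r in self.rows
            ]
        )


_SERVICE_LABELS = {
    "outpatient_visit": "outpatient visits",
    "lab_test": "laboratory tests",
    "radiology": "radiology investigations",
}


def compare_periods(
    pre: AnnualCostSummary,
    post: AnnualCostSummary,
    mppy_pre: Mapping[str, MPPYEstimate] | None = None,
    mppy_post: Mapping[str, MPPYEstimate] | None = None,
) -> PeriodComparison:
    """Tabulate before/after usage and cost rows with changes.

    When MPPY estimates are supplied (keyed by service type), each service
    gets a usage row above its cost row, mirroring the standard annual-cost
    table layout.
    """
    if pre.currency != post.currency:
        raise ValidationError(
            f"currency mismatch: {pre.currency!r} vs {post.currency!r}"
        )
    pre_by_type = {c.service_type: c for c in pre.components}
    post_by_type = {c.service_type: c for c in post.components}
    if set(pre_by_type) != set(post_by_type):
        raise ValidationError(
            "pre and post summaries cover different service types"
        )
    rows: list[ComparisonRow] = []
    for stype in pre_by_type:
        label = _SERVICE_LABELS.get(stype, stype)
        if mppy_pre is not None and mppy_post is not None:
            a, b = mppy_pre[stype], mppy_post[stype]
            rows.append(
                ComparisonRow(
                    label=f"Mean {label} (MPPY)", kind="usage",
                    before=a.mppy, after=b.mppy,
                    before_ci=(a.ci_low, a.ci_high),
                    after_ci=(b.ci_low, b.ci_high),
                )
            )
        ca, cb = pre_by_type[stype], post_by_type[stype]
        rows.append(
            ComparisonRow(
                label=f"Average costs, {label}", kind="cost",
                before=ca.acppy, after=cb.acppy,
                before_ci=(float(ca.ci_low), float(ca.ci_high)),
                after_ci=(float(cb.ci_low), float(cb.ci_high)),
            )
        )
    rows += [
        ComparisonRow("Subtotal average costs", "cost",
                      pre.subtotal, post.subtotal),
        ComparisonRow("Annual pharmacy costs excluding ARVs", "cost",
                      pre.pharmacy_annual, post.pharmacy_annual),
        ComparisonRow("Average annual outpatient services costs", "cost",
                      pre.outpatient_services_total,
                      post.outpatient_services_total),
        ComparisonRow("Annual ARV costs", "cost",
                      pre.arv_annual, post.arv_annual),
        ComparisonRow("Total annual costs", "cost",
                      pre.grand_total, post.grand_total),
    ]
    return PeriodComparison(rows=tuple(rows), pre=pre, post=post,
                            currency=pre.currency)
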