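"""Departmental microcosting: SCOPE expenditure to unit costs.

A department's annual expenditure is broken into Staff, Consumables,
Overheads, Procedures and Equipment (SCOPE).  The unit cost of its output
is top-down expenditure-based: direct annual cost, plus a finance-office
overhead percentage apportioned on top, divided by the annual workload
(number of visits, tests or investigations produced).  Heterogeneous
departments that produce interchangeable units — e.g. haematology,
biochemistry and immunology laboratories all producing "a test" — are
pooled by summing costs and workloads, i.e. workload-weighted, never the
mean of per-department unit costs.

Money is plain decimal EUR; rounding to whole euros happens only at report
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ValidationError

__all__ = [
    "BASES",
    "DEFAULT_BASIS",
    "ScopeCosts",
    "UnitCost",
    "CostSchedule",
    "department_unit_cost",
    "pooled_unit_cost",
    "build_cost_schedule",
    "read_scope_costs",
    "write_schedule",
    "read_schedule",
]

BASES: tuple[str, ...] = (
    "per_visit", "per_test", "per_investigation", "per_patient_year",
)

#: Natural costing basis for each service type.
DEFAULT_BASIS: Mapping[str, str] = {
    "outpatient_visit": "per_visit",
    "lab_test": "per_test",
    "radiology": "per_investigation",
}


@dataclass(frozen=True)
class ScopeCosts:
    """One department's annual SCOPE expenditure and workload."""

    department: str
    staff: float
    consumables: float
    procedures: float
    equipment: float
    overhead_pct: float = 0.0
    workload: float = 0.0
    service_type: str | None = None

    def __post_init__(self) -> None:
        for name in ("staff", "consumables", "procedures", "equipment"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(
                    f"{self.department}: {name} must be >= 0, got {v}"
                )
        if not 0.0 <= self.overhead_pct <= 1.0:
            raise ValidationError(
                f"{self.department}: overhead_pct must be in [0, 1], got "
                f"{self.overhead_pct}"
            )

    @property
    def direct_total(self) -> float:
        return self.staff + self.consumables + self.procedures + self.equipment

    @property
    def total_with_overhead(self) -> float:
        return self.direct_total * (1.0 + self.overhead_pct)


@dataclass(frozen=True)
class UnitCost:
    service_type: str
    amount: float
    basis: str

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValidationError(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.amount < 0:
            raise ValidationError(f"unit cost must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class CostSchedule:
    """Per-event unit costs plus fixed per-patient-year annual costs.

    ``pharmacy_annual_pppy`` is the non-ARV pharmacy cost per patient-year
    used in aggregation; ``pharmacy_annual_billed``, when present, records
    the department's headline annual pharmacy services figure, which can
    differ from the per-patient-year component actually entering totals.
    """

    unit_costs: Mapping[str, UnitCost] = field(default_factory=dict)
    pharmacy_annual_pppy: float = 0.0
    arv_annual_pppy: float = 0.0
    pharmacy_annual_billed: float | None = None
    currency: str = "EUR"
    price_year: int = 2017

    def __post_init__(self) -> None:
        for stype, uc in self.unit_costs.items():
            if uc.service_type != stype:
                raise ValidationError(
                    f"unit_costs key {stype!r} does not match "
                    f"UnitCost.service_type {uc.service_type!r}"
                )
        for name in ("pharmacy_annual_pppy", "arv_annual_pppy"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def department_unit_cost(sc: ScopeCosts, *, basis: str | None = None) -> UnitCost:
    """Unit cost of one department's output.

    amount = (staff + consumables + procedures + equipment)
             × (1 + overhead_pct) / workload
    """
    if sc.workload <= 0:
        raise ValidationError(
            f"department {sc.department!r}: workload must be > 0 to derive a "
            "unit cost"
        )
    stype = sc.service_type or "outpatient_visit"
    basis = basis or DEFAULT_BASIS.get(stype, "per_visit")
    return UnitCost(stype, sc.total_with_overhead / sc.workload, basis)


def pooled_unit_cost(departments: Sequence[ScopeCosts], *,
                     basis: str | None = None) -> UnitCost:
    """Single aggregate unit cost across departments producing the same unit.

    Workload-weighted: total costs (with overhead) over total workload.
    """
    if not departments:
        raise ValidationError("pooled_unit_cost requires at least one department")
    stypes = {d.service_type for d in departments if d.service_type is not None}
    if len(stypes) > 1:
        raise ValidationError(
            f"cannot pool departments with mixed service types: {sorted(stypes)}"
        )
    for d in departments:
        if d.workload <= 0:
            raise ValidationError(
                f"department {d.department!r}: workload must be > 0 for pooling"
            )
    total = sum(d.total_with_overhead for d in departments)
    workload = sum(d.workload for d in departments)
    stype = next(iter(stypes)) if stypes else "outpatient_visit"
    basis = basis or DEFAULT_BASIS.get(stype, "per_visit")
    return UnitCost(stype, total / workload, basis)


def build_cost_schedule(
    unit_costs: Iterable[UnitCost],
    pharmacy_annual: float,
    arv_annual: float,
    currency: str = "EUR",
    price_year: int = 2017,
    pharmacy_annual_billed: float | None = None,
) -> CostSchedule:
    """Assemble and validate a cost schedule from per-service unit costs."""
    mapping: dict[str, UnitCost] = {}
    for uc in unit_costs:
        if uc.service_type in mapping:
            raise ValidationError(
                f"duplicate unit cost for service type {uc.service_type!r}"
            )
        mapping[uc.service_type] = uc
    return CostSchedule(
        unit_costs=mapping,
        pharmacy_annual_pppy=pharmacy_annual,
        arv_annual_pppy=arv_annual,
        pharmacy_annual_billed=pharmacy_annual_billed,
        currency=currency,
        price_year=price_year,
    )


# ---------------------------------------------------------------------------
# I/O: costs.csv (departmental SCOPE lines) and schedule.yaml.

def read_scope_costs(path: str | Path) -> list[ScopeCosts]:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"department", "staff", "consumables", "procedures",
                "equipment", "overhead_pct", "workload"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        out.append(
            ScopeCosts(
                department=str(row["department"]),
                staff=float(row["staff"]),
                consumables=float(row["consumables"]),
                procedures=float(row["procedures"]),
                equipment=float(row["equipment"]),
                overhead_pct=float(row["overhead_pct"]),
                workload=float(row["workload"]),
                service_type=(str(row["service_type"])
                              if "service_type" in row and pd.notna(row["service_type"])
                              else None),
            )
        )
    return out


def write_schedule(schedule: CostSchedule, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "currency": schedule.currency,
        "price_year": schedule.price_year,
        "unit_costs": {
            stype: {"amount": uc.amount, "basis": uc.basis}
            for stype, uc in sorted(schedule.unit_costs.items())
        },
        "pharmacy_annual_pppy": schedule.pharmacy_annual_pppy,
        "arv_annual_pppy": schedule.arv_annual_pppy,
    }
    if schedule.pharmacy_annual_billed is not None:
        doc["pharmacy_annual_billed"] = schedule.pharmacy_annual_billed
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def read_schedule(path: str | Path) -> CostSchedule:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: schedule YAML must be a mapping")
    unit_costs = [
        UnitCost(stype, float(entry["amount"]), str(entry["basis"]))
        for stype, entry in (doc.get("unit_costs") or {}).items()
    ]
    billed = doc.get("pharmacy_annual_billed")
    return build_cost_schedule(
        unit_costs,
        pharmacy_annual=float(doc.get("pharmacy_annual_pppy", 0.0)),
        arv_annual=float(doc.get("arv_annual_pppy", 0.0)),
        currency=str(doc.get("currency", "EUR")),
        price_year=int(doc.get("price_year", 2017)),
        pharmacy_annual_billed=None if billed is None else float(billed),
    )
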