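"""Synthetic patient-level cohorts for before/after service-use analysis.

This module generates cohorts with the statistical structure the downstream
pipeline assumes: each patient has one year of observation before a baseline
(enrolment) date and up to one year after it, service use is a homogeneous
Poisson process with period-specific annual rates, and post-baseline
follow-up may be right-censored by death or loss to follow-up.  Clinical
outcomes (CD4 count, viral load, PAM-13 patient-activation score, PROQOL-HIV
quality of life) are drawn without any systematic pre/post shift — the
stable-cohort null that an mHealth pathway for medically stable HIV patients
is expected to preserve.

Default parameters describe the study conditions of a 586-patient Lisbon HIV
outpatient cohort: ~3.1 visits, ~246.9 laboratory tests and ~2.8 radiology
investigations per patient-year before the pathway (2.0 / 253.1 / 1.7
after), a median CD4 count of 723 cells/mm³ (IQR 506–944) and a suppressed
viral load with median 36 copies/mL (IQR 26–65) against a 50 copies/mL
detection limit.

Reproducibility: one master seed; every patient draws from a private
substream keyed by a stable hash of the patient id, so enlarging the cohort
never perturbs existing patients and identical parameters give bit-identical
CSV output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "SERVICE_TYPES",
    "OUTCOME_MEASURES",
    "OUTCOME_TIMEPOINTS",
    "YEAR_DAYS",
    "CohortParams",
    "PatientRecord",
    "ServiceEvent",
    "OutcomeMeasurement",
    "generate_cohort",
    "generate_outcomes",
    "write_cohort",
    "read_cohort",
]

#: The three service categories tracked by the costing exercise.
SERVICE_TYPES: tuple[str, ...] = ("outpatient_visit", "lab_test", "radiology")

OUTCOME_MEASURES: tuple[str, ...] = ("cd4", "viral_load", "pam13", "proqol")

#: Months relative to baseline at which outcomes are measured.
OUTCOME_TIMEPOINTS: tuple[int, ...] = (-12, 0, 12)

#: Person-time arithmetic uses a fixed 365-day year; leap days are ignored.
YEAR_DAYS: int = 365

# Substream keys: event/censoring draws and outcome draws are independent
# streams per patient, so generating outcomes never perturbs event dates.
_EVENTS_KEY = 0
_OUTCOMES_KEY = 1

_Z75 = 0.6744897501960817  # standard normal upper quartile


@dataclass(frozen=True)
class ServiceEvent:
    """One dated use of a service by one patient."""

    patient_id: str
    service_type: str
    event_date: date

    def __post_init__(self) -> None:
        if self.service_type not in SERVICE_TYPES:
            raise ValidationError(
                f"service_type must be one of {SERVICE_TYPES}, got "
                f"{self.service_type!r}"
            )


@dataclass(frozen=True)
class OutcomeMeasurement:
    """One outcome value at a visit timepoint (months relative to baseline)."""

    patient_id: str
    timepoint_months: int
    measure: str
    value: float

    def __post_init__(self) -> None:
        if self.measure not in OUTCOME_MEASURES:
            raise ValidationError(
                f"measure must be one of {OUTCOME_MEASURES}, got {self.measure!r}"
            )
        if self.measure in ("cd4", "viral_load") and self.value < 0:
            raise ValidationError(f"{self.measure} must be >= 0, got {self.value}")
        if self.measure in ("pam13", "proqol") and not 0.0 <= self.value <= 100.0:
            raise ValidationError(
                f"{self.measure} score must be within [0, 100], got {self.value}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One participant: baseline date, censoring events, events, outcomes."""

    patient_id: str
    baseline_date: date
    death_date: date | None = None
    ltfu_date: date | None = None
    events: tuple[ServiceEvent, ...] = ()
    outcomes: tuple[OutcomeMeasurement, ...] = ()

    def __post_init__(self) -> None:
        for name in ("death_date", "ltfu_date"):
            d = getattr(self, name)
            if d is None:
                continue
            lo = self.baseline_date - timedelta(days=YEAR_DAYS)
            hi = self.baseline_date + timedelta(days=YEAR_DAYS)
            if not lo < d <= hi:
                raise ValidationError(
                    f"{name} {d} outside (baseline-365d, baseline+365d] for "
                    f"patient {self.patient_id}"
                )


def _check_iqr(name: str, median: float, iqr: tuple[float, float]) -> None:
    lo, hi = iqr
    if not lo <= median <= hi:
        raise ValidationError(
            f"{name}: IQR bounds must satisfy low <= median <= high, "
            f"got median={median}, iqr=({lo}, {hi})"
        )
    if lo <= 0:
        raise ValidationError(f"{name}: IQR lower bound must be > 0, got {lo}")


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; defaults are the reference study conditions.

    Rates are expected events per uncensored patient-year, per service type
    and period.  ``p_death`` and ``p_ltfu`` are annual probabilities of the
    two censoring events in the post-baseline year (pre-baseline observation
    is complete by design: only patients with a full prior year of care are
    enrolled).  Outcome parameters are cohort medians and interquartile
    ranges used to calibrate the sampling distributions.
    """

    n_patients: int = 586
    enrolment_start: date = date(2016, 11, 1)
    enrolment_end: date = date(2018, 10, 30)
    rate_pre: Mapping[str, float] = field(
        default_factory=lambda: {
            "outpatient_visit": 3.1,
            "lab_test": 246.9,
            "radiology": 2.8,
        }
    )
    rate_post: Mapping[str, float] = field(
        default_factory=lambda: {
            "outpatient_visit": 2.0,
            "lab_test": 253.1,
            "radiology": 1.7,
        }
    )
    p_death: float = 0.005
    p_ltfu: float = 0.01
    cd4_median: float = 723.0
    cd4_iqr: tuple[float, float] = (506.0, 944.0)
    vl_median: float = 36.0
    vl_iqr: tuple[float, float] = (26.0, 65.0)
    detection_limit: float = 50.0
    pam13_median: float = 70.2
    pam13_iqr: tuple[float, float] = (60.6, 77.7)
    proqol_median: float = 65.0
    proqol_iqr: tuple[float, float] = (52.0, 78.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.enrolment_end < self.enrolment_start:
            raise ValidationError(
                "enrolment_window: enrolment_end before enrolment_start"
            )
        for name, rates in (("rate_pre", self.rate_pre), ("rate_post", self.rate_post)):
            for stype, r in rates.items():
                if stype not in SERVICE_TYPES:
                    raise ValidationError(
                        f"{name}: unknown service type {stype!r}"
                    )
                if r < 0:
                    raise ValidationError(f"{name}[{stype}] must be >= 0, got {r}")
        for name in ("p_death", "p_ltfu"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.p_death + self.p_ltfu > 1.0:
            raise ValidationError(
                f"p_death + p_ltfu must be <= 1, got {self.p_death + self.p_ltfu}"
            )
        _check_iqr("cd4", self.cd4_median, self.cd4_iqr)
        _check_iqr("viral_load", self.vl_median, self.vl_iqr)
        _check_iqr("pam13", self.pam13_median, self.pam13_iqr)
        _check_iqr("proqol", self.proqol_median, self.proqol_iqr)
        if self.detection_limit <= 0:
            raise ValidationError(
                f"detection_limit must be > 0, got {self.detection_limit}"
            )


def _patient_rng(seed: int, patient_id: str, key: int) -> np.random.Generator:
    # Stable hash (not Python's salted hash) so substreams survive restarts.
    digest = hashlib.blake2b(patient_id.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big"), key])
    )


def _lognormal_sigma(iqr: tuple[float, float]) -> float:
    """Log-normal shape whose quartile ratio matches the target IQR."""
    return float(np.log(iqr[1] / iqr[0]) / (2.0 * _Z75))


def _normal_sd(iqr: tuple[float, float]) -> float:
    return float((iqr[1] - iqr[0]) / (2.0 * _Z75))


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Generate a cohort of patients with dated service events.

    For each patient and service type, the event count in each period is a
    Poisson draw with mean ``rate × exposed_days / 365`` where the exposed
    interval is the full pre-baseline year and the (possibly censored)
    post-baseline window; event dates are uniform within the exposed
    interval, the maximum-entropy placement consistent with a homogeneous
    Poisson process.  No event is ever placed on or after the censoring
    date, so death/LTFU consistency holds by construction.
    """
    span = (params.enrolment_end - params.enrolment_start).days
    patients: list[PatientRecord] = []
    for i in range(params.n_patients):
        pid = f"P{i:04d}"
        rng = _patient_rng(params.seed, pid, _EVENTS_KEY)
        baseline = params.enrolment_start + timedelta(days=int(rng.integers(0, span + 1)))
        death: date | None = None
        ltfu: date | None = None
        u = rng.random()
        # Censoring dates are strictly inside the post year (offsets 1..364).
        if u < params.p_death:
            death = baseline + timedelta(days=int(rng.integers(1, YEAR_DAYS)))
        elif u < params.p_death + params.p_ltfu:
            ltfu = baseline + timedelta(days=int(rng.integers(1, YEAR_DAYS)))

        censor = baseline + timedelta(days=YEAR_DAYS)
        if death is not None:
            censor = min(censor, death)
        if ltfu is not None:
            censor = min(censor, ltfu)

        events: list[ServiceEvent] = []
        windows = (
            (params.rate_pre, baseline - timedelta(days=YEAR_DAYS), YEAR_DAYS),
            (params.rate_post, baseline, (censor - baseline).days),
        )
        for rates, start, ndays in windows:
            start_ord = start.toordinal()
            for stype in SERVICE_TYPES:
                rate = rates.get(stype, 0.0)
                mean = rate * ndays / YEAR_DAYS
                k = int(rng.poisson(mean)) if mean > 0 else 0
                if k == 0:
                    continue
                offsets = np.sort(rng.integers(0, ndays, size=k))
                events.extend(
                    ServiceEvent(pid, stype, date.fromordinal(start_ord + int(o)))
                    for o in offsets
                )
        patients.append(
            PatientRecord(pid, baseline, death_date=death, ltfu_date=ltfu,
                          events=tuple(events))
        )
    return patients


def generate_outcomes(
    params: CohortParams, patients: Sequence[PatientRecord]
) -> list[PatientRecord]:
    """Attach outcome series at months -12, 0 and +12 to each patient.

    CD4 counts are log-normal, calibrated so the cohort median and quartile
    ratio match the configured targets, with a patient-level set point plus
    small within-patient visit noise.  Viral loads are log-normal around the
    (suppressed) configured median; true values below the detection limit
    are stored as generated — flooring at the limit is the analysis module's
    concern.  PAM-13 and PROQOL-HIV scores are normal, clamped to [0, 100].
    No distribution shifts between periods: stability is the null.
    """
    cd4_sigma = _lognormal_sigma(params.cd4_iqr)
    vl_sigma = _lognormal_sigma(params.vl_iqr)
    pam_sd = _normal_sd(params.pam13_iqr)
    proqol_sd = _normal_sd(params.proqol_iqr)
    out: list[PatientRecord] = []
    for patient in patients:
        rng = _patient_rng(params.seed, patient.patient_id, _OUTCOMES_KEY)
        cd4_setpoint = np.log(params.cd4_median) + cd4_sigma * rng.standard_normal()
        measurements: list[OutcomeMeasurement] = []
        for tp in OUTCOME_TIMEPOINTS:
            cd4 = float(np.exp(cd4_setpoint + 0.05 * rng.standard_normal()))
            vl = float(
                np.exp(np.log(params.vl_median) + vl_sigma * rng.standard_normal())
            )
            pam = float(
                np.clip(params.pam13_median + pam_sd * rng.standard_normal(), 0.0, 100.0)
            )
            proqol = float(
                np.clip(params.proqol_median + proqol_sd * rng.standard_normal(),
                        0.0, 100.0)
            )
            measurements += [
                OutcomeMeasurement(patient.patient_id, tp, "cd4", cd4),
                OutcomeMeasurement(patient.patient_id, tp, "viral_load", vl),
                OutcomeMeasurement(patient.patient_id, tp, "pam13", pam),
                OutcomeMeasurement(patient.patient_id, tp, "proqol", proqol),
            ]
        out.append(replace(patient, outcomes=tuple(measurements)))
    return out


# ---------------------------------------------------------------------------
# CSV round trip.  Dialect: UTF-8, comma-separated, ISO-8601 dates, '\n'
# line endings; empty cell = missing date.

_PATIENT_COLS = ["patient_id", "baseline_date", "death_date", "ltfu_date"]
_EVENT_COLS = ["patient_id", "service_type", "event_date"]
_OUTCOME_COLS = ["patient_id", "timepoint_months", "measure", "value"]


def write_cohort(patients: Iterable[PatientRecord], directory: str | Path) -> dict[str, Path]:
    """Write patients/events/outcomes CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patients = list(patients)

    pat = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "baseline_date": p.baseline_date.isoformat(),
                "death_date": p.death_date.isoformat() if p.death_date else "",
                "ltfu_date": p.ltfu_date.isoformat() if p.ltfu_date else "",
            }
            for p in patients
        ],
        columns=_PATIENT_COLS,
    )
    ev = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "service_type": e.service_type,
                "event_date": e.event_date.isoformat(),
            }
            for p in patients
            for e in p.events
        ],
        columns=_EVENT_COLS,
    )
    oc = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "timepoint_months": m.timepoint_months,
                "measure": m.measure,
                "value": float(m.value),
            }
            for p in patients
            for m in p.outcomes
        ],
        columns=_OUTCOME_COLS,
    )
    paths = {
        "patients": directory / "patients.csv",
        "events": directory / "events.csv",
        "outcomes": directory / "outcomes.csv",
    }
    pat.to_csv(paths["patients"], index=False, lineterminator="\n")
    ev.to_csv(paths["events"], index=False, lineterminator="\n")
    oc.to_csv(paths["outcomes"], index=False, lineterminator="\n")
    return paths


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError("file not found", file=str(path))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}", file=str(path),
            column=missing[0],
        )
    return df


def _parse_date(raw: str, *, path: Path, row: int, column: str,
                required: bool) -> date | None:
    if raw == "":
        if required:
            raise SchemaError("date is required", file=str(path), row=row,
                              column=column)
        return None
    try:
        return date.fromisoformat(raw)
    except ValueError as exc:
        raise SchemaError(f"invalid ISO date {raw!r}", file=str(path), row=row,
                          column=column) from exc


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    directory = Path(directory)
    pat_path = directory / "patients.csv"
    ev_path = directory / "events.csv"
    oc_path = directory / "outcomes.csv"
    pat = _read_csv(pat_path, _PATIENT_COLS)
    ev = _read_csv(ev_path, _EVENT_COLS)
    oc = _read_csv(oc_path, _OUTCOME_COLS)

    events: dict[str, list[ServiceEvent]] = {}
    for i, row in enumerate(ev.itertuples(index=False), start=1):
        if row.service_type not in SERVICE_TYPES:
            raise SchemaError(
                f"unknown service_type {row.service_type!r}", file=str(ev_path),
                row=i, column="service_type",
            )
        d = _parse_date(row.event_date, path=ev_path, row=i,
                        column="event_date", required=True)
        events.setdefault(row.patient_id, []).append(
            ServiceEvent(row.patient_id, row.service_type, d)
        )

    outcomes: dict[str, list[OutcomeMeasurement]] = {}
    for i, row in enumerate(oc.itertuples(index=False), start=1):
        if row.measure not in OUTCOME_MEASURES:
            raise SchemaError(
                f"unknown measure {row.measure!r}", file=str(oc_path), row=i,
                column="measure",
            )
        try:
            tp = int(row.timepoint_months)
            value = float(row.value)
        except ValueError as exc:
            raise SchemaError(
                "timepoint_months/value must be numeric", file=str(oc_path),
                row=i, column="timepoint_months",
            ) from exc
        outcomes.setdefault(row.patient_id, []).append(
            OutcomeMeasurement(row.patient_id, tp, row.measure, value)
        )

    patients: list[PatientRecord] = []
    for i, row in enumerate(pat.itertuples(index=False), start=1):
        baseline = _parse_date(row.baseline_date, path=pat_path, row=i,
                               column="baseline_date", required=True)
        death = _parse_date(row.death_date, path=pat_path, row=i,
                            column="death_date", required=False)
        ltfu = _parse_date(row.ltfu_date, path=pat_path, row=i,
                           column="ltfu_date", required=False)
        patients.append(
            PatientRecord(
                row.patient_id, baseline, death_date=death, ltfu_date=ltfu,
                events=tuple(events.get(row.patient_id, ())),
                outcomes=tuple(outcomes.get(row.patient_id, ())),
            )
        )
    return patients
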