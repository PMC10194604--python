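"""Censored person-time accounting and per-patient-year service-use rates.

The central statistic is the mean number of services used per patient-year
(MPPY), a pooled ratio estimator::

    M = (Σ_i Σ_j S_ij) / (Σ_i Σ_j (t_ij − t_i(j−1))) × 365

i.e. total events divided by total censored follow-up days, scaled to a
365-day year.  It is *not* the mean of per-patient rates: patients weight
the estimate by the person-time they contribute.

Follow-up windows use half-open interval convention [start, end): an event
on the censoring date itself is excluded.  The pre-baseline window is
always the full year [baseline−365d, baseline); the post-baseline window
runs from baseline to the earliest of baseline+365d, death, or loss to
follow-up.

Confidence intervals are exact (Garwood) Poisson intervals obtained from
gamma quantiles, treating person-time as fixed; they are conservative
(coverage ≥ nominal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .cohort import SERVICE_TYPES, YEAR_DAYS, PatientRecord, ServiceEvent
from .errors import ValidationError, ZeroFollowUpError, ZeroPersonTimeError

__all__ = [
    "PERIODS",
    "FollowUpInterval",
    "MPPYEstimate",
    "derive_followup_interval",
    "count_events",
    "compute_mppy",
    "exact_poisson_ci",
    "cohort_estimates",
    "estimates_frame",
    "write_estimates",
]

PERIODS: tuple[str, ...] = ("pre", "post")


@dataclass(frozen=True)
class FollowUpInterval:
    """A censored [start, end) window of person-time for one patient."""

    patient_id: str
    period: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(f"period must be one of {PERIODS}, got {self.period!r}")
        if not self.start_date < self.end_date:
            raise ValidationError(
                f"empty follow-up interval [{self.start_date}, {self.end_date}) "
                f"for patient {self.patient_id}"
            )
        if self.person_days > YEAR_DAYS:
            raise ValidationError(
                f"person_days {self.person_days} exceeds {YEAR_DAYS} for "
                f"patient {self.patient_id}"
            )

    @property
    def person_days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass(frozen=True)
class MPPYEstimate:
    """An MPPY rate with its exact Poisson confidence interval.

    ``total_events`` and ``total_person_days`` are the pooled numerator and
    denominator; they are ``None`` for literature-supplied point estimates
    where only the published rate and interval are known.
    """

    service_type: str
    period: str
    mppy: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    total_events: int | None = None
    total_person_days: int | None = None
    n_patients: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must be in (0, 1), got {self.level}")
        if not self.ci_low <= self.mppy <= self.ci_high:
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket rate {self.mppy}"
            )
        if self.total_events is not None and self.total_person_days is not None:
            expected = self.total_events * YEAR_DAYS / self.total_person_days
            if not math.isclose(self.mppy, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise ValidationError(
                    f"mppy {self.mppy} inconsistent with "
                    f"{self.total_events} events / {self.total_person_days} days"
                )
            if (self.ci_low == 0.0) != (self.total_events == 0):
                raise ValidationError("ci_low must be 0 exactly when total_events is 0")


def derive_followup_interval(patient: PatientRecord, period: str) -> FollowUpInterval:
    """Censored follow-up window for one patient in one period.

    pre  → [baseline − 365d, baseline)
    post → [baseline, min(baseline + 365d, death_date, ltfu_date))

    Raises
    ------
    ZeroFollowUpError
        If the post-period censoring date falls on or before baseline, so
        the patient contributes no person-time (callers exclude the patient
        from the denominator, with a logged warning).
    """
    if period not in PERIODS:
        raise ValidationError(f"period must be one of {PERIODS}, got {period!r}")
    b = patient.baseline_date
    if patient.death_date is not None and patient.death_date < b:
        raise ValidationError(
            f"death_date {patient.death_date} precedes baseline {b} for "
            f"patient {patient.patient_id}"
        )
    if period == "pre":
        return FollowUpInterval(patient.patient_id, "pre",
                                b - timedelta(days=YEAR_DAYS), b)
    end = b + timedelta(days=YEAR_DAYS)
    for censor in (patient.death_date, patient.ltfu_date):
        if censor is not None and censor < end:
            end = censor
    if end <= b:
        raise ZeroFollowUpError(
            f"patient {patient.patient_id} contributes no post-baseline "
            f"person-time (censored at {end})"
        )
    return FollowUpInterval(patient.patient_id, "post", b, end)


def count_events(events: Iterable[ServiceEvent], interval: FollowUpInterval,
                 service_type: str) -> int:
    """Count events of one type inside the half-open follow-up window."""
    if service_type not in SERVICE_TYPES:
        raise ValidationError(
            f"service_type must be one of {SERVICE_TYPES}, got {service_type!r}"
        )
    return sum(
        1
        for e in events
        if e.service_type == service_type
        and interval.start_date <= e.event_date < interval.end_date
    )


def exact_poisson_ci(total_events: int, person_years: float,
                     level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson rate.

    lower = Q_gamma((1−level)/2; shape=k) / T          (0 when k = 0)
    upper = Q_gamma((1+level)/2; shape=k+1) / T

    where k is the event count and T the person-time in years.  Endpoints
    satisfy the defining tail equations P(X ≥ k | λ=lower·T) = α/2 and
    P(X ≤ k | λ=upper·T) = α/2, which makes the interval conservative.
    """
    if total_events < 0 or total_events != int(total_events):
        raise ValidationError(f"total_events must be a non-negative integer, got {total_events}")
    if not person_years > 0:
        raise ValidationError(f"person_years must be > 0, got {person_years}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    k = int(total_events)
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.gamma.ppf(alpha / 2.0, k)) / person_years
    high = float(stats.gamma.ppf(1.0 - alpha / 2.0, k + 1)) / person_years
    return low, high


def compute_mppy(
    counts: Sequence[int],
    person_days: Sequence[int],
    *,
    service_type: str = "outpatient_visit",
    period: str = "pre",
    level: float = 0.95,
) -> MPPYEstimate:
    """Pooled MPPY over per-patient counts and person-days.

    ``counts[i]`` and ``person_days[i]`` belong to the same patient.  Every
    patient must contribute positive person-time — zero-exposure patients
    are excluded upstream, never silently zeroed here.
    """
    if len(counts) != len(person_days):
        raise ValidationError(
            f"counts ({len(counts)}) and person_days ({len(person_days)}) "
            "must have equal length"
        )
    if any(c < 0 for c in counts):
        raise ValidationError("event counts must be non-negative")
    if any(d <= 0 for d in person_days):
        raise ValidationError(
            "all person_days must be > 0; exclude zero-exposure patients first"
        )
    total_days = int(sum(person_days))
    if total_days == 0:
        raise ZeroPersonTimeError("total person-time is zero; rate undefined")
    total_events = int(sum(counts))
    person_years = total_days / YEAR_DAYS
    mppy = total_events * YEAR_DAYS / total_days
    low, high = exact_poisson_ci(total_events, person_years, level)
    return MPPYEstimate(
        service_type=service_type,
        period=period,
        mppy=mppy,
        ci_low=low,
        ci_high=high,
        level=level,
        total_events=total_events,
        total_person_days=total_days,
        n_patients=len(counts),
    )


def cohort_estimates(
    patients: Sequence[PatientRecord],
    level: float = 0.95,
    on_zero_followup=None,
) -> list[MPPYEstimate]:
    """All six (service type × period) MPPY estimates for a cohort.

    Patients contributing zero person-time to a period are excluded from
    that period's denominator; ``on_zero_followup(patient_id, period)`` is
    invoked for each exclusion (e.g. to log a warning).
    """
    estimates: list[MPPYEstimate] = []
    for period in PERIODS:
        per_patient: list[tuple[dict[str, int], int]] = []
        for p in patients:
            try:
                interval = derive_followup_interval(p, period)
            except ZeroFollowUpError:
                if on_zero_followup is not None:
                    on_zero_followup(p.patient_id, period)
                continue
            tallies = dict.fromkeys(SERVICE_TYPES, 0)
            for e in p.events:
                if interval.start_date <= e.event_date < interval.end_date:
                    tallies[e.service_type] += 1
            per_patient.append((tallies, interval.person_days))
        for stype in SERVICE_TYPES:
            estimates.append(
                compute_mppy(
                    [t[stype] for t, _ in per_patient],
                    [d for _, d in per_patient],
                    service_type=stype,
                    period=period,
                    level=level,
                )
            )
    return estimates


def estimates_frame(estimates: Iterable[MPPYEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "service_type": e.service_type,
                "period": e.period,
                "total_events": e.total_events,
                "person_days": e.total_person_days,
                "mppy": e.mppy,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "level": e.level,
            }
            for e in estimates
        ],
        columns=["service_type", "period", "total_events", "person_days",
                 "mppy", "ci_low", "ci_high", "level"],
    )


def write_estimates(estimates: Iterable[MPPYEstimate], path: str | Path) -> Path:
    path = Path(path)
    estimates_frame(estimates).to_csv(path, index=False, lineterminator="\n")
    return path
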