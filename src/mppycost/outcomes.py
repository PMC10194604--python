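"""Descriptive processing of clinical and patient-reported outcomes.

Viral loads are log10-transformed to stabilise variance, with values below
the assay detection limit floored at the limit (and flagged).  Summaries
are medians with interquartile ranges — quartiles by the linear
interpolation convention — plus means and missing counts.  Trajectories
over the two-year window are condensed by a trapezoidal time-weighted mean.
Before/after deltas of the summaries are the scalars handed to the
cost-effectiveness comparison as its outcome arguments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .errors import ValidationError

__all__ = [
    "DegenerateSeriesWarning",
    "LogViralLoad",
    "OutcomeSummary",
    "OutcomeDelta",
    "log_viral_load",
    "summarize_outcome",
    "time_weighted_mean",
    "outcome_delta",
    "summarize_cohort_outcomes",
    "write_outcome_summaries",
]


class DegenerateSeriesWarning(UserWarning):
    """A time series had a single distinct timepoint; no weighting possible."""


class LogViralLoad(NamedTuple):
    value: float  # log10 copies/mL
    floored: bool  # True when the raw value was below the detection limit


def log_viral_load(value: float, detection_limit: float = 50.0) -> LogViralLoad:
    """log10 viral load with flooring at the detection limit.

    Returns log10(max(value, detection_limit)); ``floored`` marks
    undetectable values reported below the limit.
    """
    if detection_limit <= 0:
        raise ValidationError(f"detection_limit must be > 0, got {detection_limit}")
    if value < 0:
        raise ValidationError(f"viral load must be >= 0, got {value}")
    floored = value < detection_limit
    return LogViralLoad(math.log10(max(value, detection_limit)), floored)


@dataclass(frozen=True)
class OutcomeSummary:
    """Median/IQR/mean summary of one measure at one timepoint or period."""

    measure: str
    timepoint: int | str
    n: int
    median: float
    iqr_low: float
    iqr_high: float
    mean: float
    missing: int = 0

    def __post_init__(self) -> None:
        if not self.iqr_low <= self.median <= self.iqr_high:
            raise ValidationError(
                f"{self.measure}@{self.timepoint}: quartiles out of order "
                f"({self.iqr_low}, {self.median}, {self.iqr_high})"
            )


def summarize_outcome(
    values: Sequence[float],
    *,
    measure: str = "outcome",
    timepoint: int | str = 0,
    cohort_size: int | None = None,
) -> OutcomeSummary:
    """Median, quartiles (linear interpolation), mean and missing count.

    NaNs count as missing, as do patients absent from ``values`` when
    ``cohort_size`` is given; missing values are never imputed.
    """
    arr = np.asarray(values, dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise ValidationError(
            f"{measure}@{timepoint}: no non-missing values to summarise"
        )
    missing = int(arr.size - observed.size)
    if cohort_size is not None:
        if cohort_size < arr.size:
            raise ValidationError(
                f"cohort_size {cohort_size} smaller than {arr.size} values"
            )
        missing += cohort_size - arr.size
    q25, q50, q75 = np.percentile(observed, [25, 50, 75])  # linear interpolation
    return OutcomeSummary(
        measure=measure,
        timepoint=timepoint,
        n=int(observed.size),
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
        mean=float(observed.mean()),
        missing=missing,
    )


def time_weighted_mean(series: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal time-weighted mean of a (months, value) series.

    Area under the piecewise-linear value–time curve divided by the time
    span.  A series with a single distinct timepoint returns its value and
    emits :class:`DegenerateSeriesWarning`.
    """
    if not series:
        raise ValidationError("time_weighted_mean requires a non-empty series")
    pts = sorted((float(t), float(v)) for t, v in series)
    times = np.array([t for t, _ in pts])
    values = np.array([v for _, v in pts])
    span = times[-1] - times[0]
    if span == 0:
        warnings.warn(
            "series has a single distinct timepoint; returning its value",
            DegenerateSeriesWarning,
            stacklevel=2,
        )
        return float(values.mean())
    return float(np.trapezoid(values, times) / span)


class OutcomeDelta(NamedTuple):
    median_change: float  # post median − pre median
    mean_change: float


def outcome_delta(pre: OutcomeSummary, post: OutcomeSummary) -> OutcomeDelta:
    """Post-minus-pre change in the summary location (median and mean)."""
    if pre.measure != post.measure:
        raise ValidationError(
            f"measure mismatch: {pre.measure!r} vs {post.measure!r}"
        )
    return OutcomeDelta(post.median - pre.median, post.mean - pre.mean)


def summarize_cohort_outcomes(
    patients: Iterable[PatientRecord],
    detection_limit: float = 50.0,
) -> list[OutcomeSummary]:
    """Per-(measure, timepoint) summaries over a cohort.

    Viral load is summarised both on the raw copies/mL scale and, as
    ``viral_load_log10``, on the log10 scale after flooring at the
    detection limit.
    """
    by_key: dict[tuple[str, int], list[float]] = {}
    n_patients = 0
    for p in patients:
        n_patients += 1
        for m in p.outcomes:
            by_key.setdefault((m.measure, m.timepoint_months), []).append(m.value)
    summaries: list[OutcomeSummary] = []
    for (measure, tp), values in sorted(by_key.items()):
        summaries.append(
            summarize_outcome(values, measure=measure, timepoint=tp,
                              cohort_size=n_patients)
        )
        if measure == "viral_load":
            logs = [log_viral_load(v, detection_limit).value for v in values]
            summaries.append(
                summarize_outcome(logs, measure="viral_load_log10",
                                  timepoint=tp, cohort_size=n_patients)
            )
    return summaries


def write_outcome_summaries(summaries: Iterable[OutcomeSummary],
                            path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "measure": s.measure,
                "timepoint": s.timepoint,
                "n": s.n,
                "median": s.median,
                "iqr_low": s.iqr_low,
                "iqr_high": s.iqr_high,
                "mean": s.mean,
                "missing": s.missing,
            }
            for s in summaries
        ],
        columns=["measure", "timepoint", "n", "median", "iqr_low", "iqr_high",
                 "mean", "missing"],
    ).to_csv(path, index=False, lineterminator="\n")
    return path
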