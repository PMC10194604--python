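"""Person-time derivation, pooled MPPY estimator, exact Poisson CI."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mppycost import (
    FollowUpInterval,
    MPPYEstimate,
    PatientRecord,
    ServiceEvent,
    ValidationError,
    ZeroFollowUpError,
    compute_mppy,
    count_events,
    derive_followup_interval,
    exact_poisson_ci,
)

BASELINE = date(2018, 3, 1)


def _patient(**kwargs):
    return PatientRecord("P0001", BASELINE, **kwargs)


class TestFollowUpIntervals:
    def test_uncensored_post_year_is_365_days(self):
        iv = derive_followup_interval(_patient(), "post")
        assert iv.person_days == 365
        assert iv.start_date == BASELINE

    def test_earliest_censoring_event_wins(self):
        p = _patient(death_date=BASELINE + timedelta(days=100),
                     ltfu_date=BASELINE + timedelta(days=200))
        assert derive_followup_interval(p, "post").person_days == 100

    def test_pre_period_unaffected_by_post_censoring(self):
        p = _patient(death_date=BASELINE + timedelta(days=50))
        iv = derive_followup_interval(p, "pre")
        assert iv.person_days == 365
        assert iv.end_date == BASELINE

    def test_death_on_baseline_gives_zero_followup_error(self):
        p = PatientRecord("P0002", BASELINE, death_date=BASELINE)
        with pytest.raises(ZeroFollowUpError, match="P0002"):
            derive_followup_interval(p, "post")

    def test_death_before_baseline_rejected(self):
        p = PatientRecord("P0003", BASELINE,
                          death_date=BASELINE - timedelta(days=10))
        with pytest.raises(ValidationError, match="precedes baseline"):
            derive_followup_interval(p, "post")


class TestCountEvents:
    @pytest.fixture()
    def interval(self):
        return FollowUpInterval("P0001", "post", BASELINE,
                                BASELINE + timedelta(days=365))

    def _ev(self, offset):
        return ServiceEvent("P0001", "outpatient_visit",
                            BASELINE + timedelta(days=offset))

    def test_half_open_convention(self, interval):
        on_start, on_end = self._ev(0), self._ev(365)
        assert count_events([on_start], interval, "outpatient_visit") == 1
        assert count_events([on_end], interval, "outpatient_visit") == 0

    def test_counts_only_requested_service_type(self, interval):
        events = [self._ev(10), self._ev(50), self._ev(300),
                  ServiceEvent("P0001", "lab_test", BASELINE)]
        assert count_events(events, interval, "outpatient_visit") == 3
        assert count_events([], interval, "lab_test") == 0


class TestComputeMppy:
    def test_single_patient_full_year(self):
        est = compute_mppy([3], [365])
        assert est.mppy == 3.0

    def test_pooled_ratio_not_mean_of_rates(self):
        # (2 events, 365 d) + (1 event, 182 d): 3/547 x 365, by hand
        est = compute_mppy([2, 1], [365, 182])
        assert est.mppy == pytest.approx(3 / 547 * 365, rel=1e-12)
        assert est.mppy == pytest.approx(2.0018281535648994, rel=1e-12)

    def test_rejects_zero_person_time_patients(self):
        with pytest.raises(ValidationError, match="person_days"):
            compute_mppy([1, 0], [365, 0])

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValidationError, match="equal length"):
            compute_mppy([1, 2], [365])

    def test_estimate_invariants_enforced(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            MPPYEstimate("outpatient_visit", "pre", mppy=1.0, ci_low=0.5,
                         ci_high=1.5, total_events=3, total_person_days=365)

    @given(
        counts=st.lists(st.integers(0, 50), min_size=1, max_size=10),
        days=st.lists(st.integers(1, 365), min_size=10, max_size=10),
        c=st.integers(2, 7),
    )
    def test_scale_equivariance(self, counts, days, c):
        days = days[: len(counts)]
        base = compute_mppy(counts, days)
        scaled = compute_mppy([x * c for x in counts], [d * c for d in days])
        assert scaled.mppy == pytest.approx(base.mppy, rel=1e-12)

    @given(
        counts=st.lists(st.integers(0, 30), min_size=2, max_size=12),
        days=st.lists(st.integers(1, 365), min_size=12, max_size=12),
        split=st.integers(1, 11),
    )
    def test_merge_consistency(self, counts, days, split):
        days = days[: len(counts)]
        split = min(split, len(counts) - 1)
        pooled = compute_mppy(counts, days)
        a = compute_mppy(counts[:split], days[:split])
        b = compute_mppy(counts[split:], days[split:])
        ta, tb = sum(days[:split]), sum(days[split:])
        weighted = (a.mppy * ta + b.mppy * tb) / (ta + tb)
        assert pooled.mppy == pytest.approx(weighted, rel=1e-12)


@st.composite
def tiny_cohorts(draw):
    """Up to 5 patients with <=30-day windows and events inside them."""
    n = draw(st.integers(1, 5))
    patients = []
    for i in range(n):
        ndays = draw(st.integers(1, 30))
        n_events = draw(st.integers(0, 8))
        offsets = draw(
            st.lists(st.integers(-5, 35), min_size=n_events, max_size=n_events)
        )
        patients.append((ndays, offsets))
    return patients


@given(tiny_cohorts())
def test_mppy_matches_day_by_day_enumeration(cohort):
    """Pooled estimator equals brute-force enumeration of days and events."""
    origin = date(2018, 1, 1)
    counts, person_days = [], []
    brute_events = brute_days = 0
    for i, (ndays, offsets) in enumerate(cohort):
        start = origin
        end = origin + timedelta(days=ndays)
        interval = FollowUpInterval(f"P{i:04d}", "post", start, end)
        events = [
            ServiceEvent(f"P{i:04d}", "lab_test", origin + timedelta(days=o))
            for o in offsets
        ]
        counts.append(count_events(events, interval, "lab_test"))
        person_days.append(interval.person_days)
        # independent oracle: walk every exposed day, tally events dated there
        day = start
        while day < end:
            brute_days += 1
            brute_events += sum(1 for e in events if e.event_date == day)
            day += timedelta(days=1)
    est = compute_mppy(counts, person_days, service_type="lab_test")
    assert est.total_events == brute_events
    assert est.total_person_days == brute_days
    assert est.mppy == pytest.approx(brute_events / brute_days * 365, rel=1e-12)


class TestExactPoissonCI:
    def test_zero_events_closed_form(self):
        # upper endpoint is -ln(alpha/2)/T; lower is exactly 0
        for t in (1.0, 5.0, 586.0):
            low, high = exact_poisson_ci(0, t)
            assert low == 0.0
            assert high == pytest.approx(-math.log(0.025) / t, rel=1e-12)

    @pytest.mark.parametrize("events,years", [(10, 5.0), (3, 1.0), (1816, 586.0)])
    def test_endpoints_satisfy_tail_equations(self, events, years):
        low, high = exact_poisson_ci(events, years)
        assert low < events / years < high
        # P(X >= k | lambda = low*T) = 0.025 ; P(X <= k | lambda = high*T) = 0.025
        assert stats.poisson.sf(events - 1, low * years) == pytest.approx(0.025, abs=1e-9)
        assert stats.poisson.cdf(events, high * years) == pytest.approx(0.025, abs=1e-9)

    def test_matches_bisection_oracle(self):
        def bisect(tail, lo, hi, increasing, target=0.025, iters=200):
            for _ in range(iters):
                mid = (lo + hi) / 2
                if (tail(mid) > target) == increasing:
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2

        k, years = 10, 5.0
        low, high = exact_poisson_ci(k, years)
        oracle_low = bisect(lambda mu: stats.poisson.sf(k - 1, mu), 0.0, 50.0,
                            increasing=True) / years
        oracle_high = bisect(lambda mu: stats.poisson.cdf(k, mu), 0.0, 80.0,
                             increasing=False) / years
        assert low == pytest.approx(oracle_low, rel=1e-8)
        assert high == pytest.approx(oracle_high, rel=1e-8)

    def test_interval_brackets_rate_and_narrows_under_rescaling(self):
        low1, high1 = exact_poisson_ci(10, 5.0)
        low2, high2 = exact_poisson_ci(20, 10.0)
        assert low1 < 2.0 < high1 and low2 < 2.0 < high2
        assert (high2 - low2) < (high1 - low1)

    def test_width_strictly_decreases_with_person_time(self):
        rate = 3.0
        widths = []
        for years in (10, 40, 160, 640):
            low, high = exact_poisson_ci(int(rate * years), float(years))
            widths.append(high - low)
        assert all(b < a for a, b in zip(widths, widths[1:]))

    @pytest.mark.parametrize(
        "events,years,level",
        [(-1, 1.0, 0.95), (3, 0.0, 0.95), (3, 1.0, 0.0), (3, 1.0, 1.0)],
    )
    def test_invalid_inputs_rejected(self, events, years, level):
        with pytest.raises(ValidationError):
            exact_poisson_ci(events, years, level)


def test_parameter_recovery_quick():
    """True rate inside the exact CI for a handful of simulated cohorts."""
    rng = np.random.default_rng(99)
    rate, years = 3.1, 586.0
    covered = 0
    for _ in range(20):
        k = int(rng.poisson(rate * years))
        low, high = exact_poisson_ci(k, years)
        covered += low <= rate <= high
    assert covered >= 17
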