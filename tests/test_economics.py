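"""Cost aggregation, percent changes, ICER/cost-minimization logic."""

from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

from mppycost import (
    ACPPYComponent,
    MPPYEstimate,
    UndefinedChangeError,
    UnitCost,
    ValidationError,
    acppy,
    annual_cost_summary,
    build_cost_schedule,
    compare_periods,
    format_percent_change,
    icer,
    percent_change,
)
from mppycost.reference import (
    reference_comparison,
    reference_cost_schedule,
    reference_mppy_estimates,
    reference_summaries,
)


def _estimate(mppy, lo, hi, stype="outpatient_visit", period="post"):
    return MPPYEstimate(stype, period, mppy=mppy, ci_low=lo, ci_high=hi)


class TestAcppy:
    def test_scales_rate_and_ci_by_unit_cost(self):
        comp = acppy(_estimate(2.0, 1.9, 2.1), UnitCost("outpatient_visit", 96, "per_visit"))
        assert comp.acppy == Decimal("192.0")
        assert (comp.ci_low, comp.ci_high) == (Decimal("182.4"), Decimal("201.6"))
        # published figure uses the unrounded upstream rate, hence within 1 EUR
        assert abs(comp.acppy - 193) <= 1

    def test_zero_rate_keeps_upper_ci(self):
        comp = acppy(_estimate(0.0, 0.0, 0.5), UnitCost("outpatient_visit", 96, "per_visit"))
        assert comp.acppy == 0 and comp.ci_low == 0
        assert comp.ci_high == Decimal("48.0")

    def test_zero_unit_cost_zeroes_money(self):
        comp = acppy(_estimate(2.0, 1.9, 2.1), UnitCost("outpatient_visit", 0, "per_visit"))
        assert comp.acppy == comp.ci_low == comp.ci_high == 0

    def test_per_patient_year_basis_rejected(self):
        with pytest.raises(ValidationError, match="per_patient_year"):
            acppy(_estimate(2.0, 1.9, 2.1),
                  UnitCost("outpatient_visit", 1001, "per_patient_year"))

    def test_service_type_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            acppy(_estimate(2.0, 1.9, 2.1), UnitCost("lab_test", 3, "per_test"))


class TestAnnualCostSummary:
    def test_published_component_sums(self):
        pre, post = reference_summaries()
        assert pre.subtotal == 1092 and post.subtotal == 983
        assert pre.outpatient_services_total == 2093
        assert post.outpatient_services_total == 1984
        assert pre.grand_total == 12069 and post.grand_total == 11960

    def test_duplicate_component_rejected(self):
        schedule = reference_cost_schedule()
        comp = ACPPYComponent("lab_test", "pre", Decimal(1), Decimal(1), Decimal(1))
        with pytest.raises(ValidationError, match="duplicate|cover"):
            annual_cost_summary([comp, comp], schedule, "pre")

    def test_missing_component_rejected(self):
        schedule = reference_cost_schedule()
        comp = ACPPYComponent("lab_test", "pre", Decimal(1), Decimal(1), Decimal(1))
        with pytest.raises(ValidationError, match="cover"):
            annual_cost_summary([comp], schedule, "pre")

    def test_degenerate_zero_schedule(self):
        schedule = build_cost_schedule([], pharmacy_annual=0, arv_annual=0)
        summary = annual_cost_summary([], schedule, "pre")
        assert summary.grand_total == 0

    def test_additivity_is_exact_decimal(self):
        # 0.1-style floats would drift; decimals must not
        schedule = build_cost_schedule(
            [UnitCost("outpatient_visit", 0.1, "per_visit")],
            pharmacy_annual=0.2, arv_annual=0.3,
        )
        comp = acppy(_estimate(1.0, 0.5, 1.5, period="pre"),
                     schedule.unit_costs["outpatient_visit"])
        summary = annual_cost_summary([comp], schedule, "pre")
        assert summary.grand_total == Decimal("0.6")


class TestPercentChange:
    @pytest.mark.parametrize(
        "before, after, pct, rendered",
        [
            (3.1, 2.0, -35.48, "35% decrease"),
            (2.8, 1.7, -39.29, "39% decrease"),
            (5.0, 5.0, 0.0, "0%"),
            (2.0, 2.1, 5.0, "5% increase"),
        ],
    )
    def test_value_and_rendering(self, before, after, pct, rendered):
        value = percent_change(before, after)
        assert value == pytest.approx(pct, abs=0.005)
        assert format_percent_change(value) == rendered

    def test_zero_baseline_undefined(self):
        with pytest.raises(UndefinedChangeError):
            percent_change(0.0, 5.0)

    def test_rendering_rounds_half_up(self):
        assert format_percent_change(-34.5) == "35% decrease"
        assert format_percent_change(34.4) == "34% increase"


class TestIcer:
    def test_equivalent_outcomes_collapse_to_cost_minimization(self):
        result = icer(12069, 11960, outcome_a=500.0, outcome_b=500.0, mcid=0.0)
        assert result.classification == "cost_minimization"
        assert result.icer is None
        assert result.cost_difference == Decimal(-109)

    def test_direct_ratio(self):
        result = icer(1100, 1000, outcome_a=3.0, outcome_b=1.0, mcid=0.1)
        assert result.icer == pytest.approx(50.0)
        assert result.classification == "icer"

    def test_cheaper_and_better_dominates(self):
        result = icer(1100, 1000, outcome_a=1.0, outcome_b=2.0, mcid=0.1)
        assert result.classification == "cost_saving_dominant"

    def test_mcid_threshold_inclusive(self):
        result = icer(1100, 1000, outcome_a=1.0, outcome_b=1.5, mcid=0.5)
        assert result.classification == "cost_minimization"

    @given(
        cost_a=st.floats(0, 1e5), cost_b=st.floats(0, 1e5),
        outcome_a=st.floats(-50, 50), outcome_b=st.floats(-50, 50),
    )
    def test_sign_coherence_under_period_swap(self, cost_a, cost_b,
                                              outcome_a, outcome_b):
        forward = icer(cost_a, cost_b, outcome_a, outcome_b, mcid=0.0)
        backward = icer(cost_b, cost_a, outcome_b, outcome_a, mcid=0.0)
        assert (forward.icer is None) == (backward.icer is None)
        if forward.icer is not None:
            assert forward.icer == pytest.approx(backward.icer, rel=1e-9,
                                                 abs=1e-9)

    def test_negative_mcid_rejected(self):
        with pytest.raises(ValidationError):
            icer(1, 2, 0.0, 0.0, mcid=-1.0)


class TestComparePeriods:
    def test_published_percent_changes(self):
        cmp = reference_comparison()
        by_label = {r.label: r for r in cmp.rows}
        services = by_label["Average annual outpatient services costs"]
        assert format_percent_change(services.pct_change) == "5% decrease"
        grand = by_label["Total annual costs"]
        assert format_percent_change(grand.pct_change) == "1% decrease"
        visits = by_label["Mean outpatient visits (MPPY)"]
        assert format_percent_change(visits.pct_change) == "35% decrease"

    def test_published_arv_share(self):
        cmp = reference_comparison()
        assert round(cmp.arv_share_after) == 83
        assert cmp.arv_share_after == pytest.approx(9976 / 11960 * 100)

    def test_currency_mismatch_rejected(self):
        pre, post = reference_summaries()
        import dataclasses

        other = dataclasses.replace(post, currency="USD")
        with pytest.raises(ValidationError, match="currency"):
            compare_periods(pre, other)

    def test_linearity_under_unit_cost_scaling(self):
        """Scaling all money by c scales rows by c, percent changes fixed."""
        estimates = reference_mppy_estimates()
        base, scaled = [], []
        for factor in (1.0, 3.0):
            schedule = build_cost_schedule(
                [UnitCost("outpatient_visit", 96 * factor, "per_visit"),
                 UnitCost("lab_test", 3 * factor, "per_test"),
                 UnitCost("radiology", 18 * factor, "per_investigation")],
                pharmacy_annual=1001 * factor, arv_annual=9976 * factor,
            )
            summaries = {
                period: annual_cost_summary(
                    [acppy(est, schedule.unit_costs[stype])
                     for stype, est in estimates[period].items()],
                    schedule, period,
                )
                for period in ("pre", "post")
            }
            (base if factor == 1.0 else scaled).append(
                compare_periods(summaries["pre"], summaries["post"])
            )
        one, three = base[0], scaled[0]
        for r1, r3 in zip(one.rows, three.rows):
            if r1.kind == "cost":
                assert Decimal(r3.before) == 3 * Decimal(r1.before)
            else:
                assert r3.before == r1.before
            assert r3.pct_change == pytest.approx(r1.pct_change)
        assert three.arv_share_after == pytest.approx(one.arv_share_after)
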