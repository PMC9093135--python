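"""Discounted accrual, ICER logic and the supporting unit conversions."""

import numpy as np
import pytest

from mucea.economics import (
    ArmResult,
    ICERResult,
    accrue,
    cny_to_usd,
    default_schedule,
    discount_factor,
    icer,
    net_monetary_benefit,
    utility_from_qlqc30,
    weeks_to_months,
    IMAGING_INTERVAL_MONTHS,
    TREATMENT_DURATION_MONTHS,
)
from mucea.exceptions import ConfigurationError, InvalidInputError
from mucea.markov_engine import ModelSpec


def zero_values(**overrides):
    base = {
        "utility_pfs": 0.0,
        "utility_pd": 0.0,
        "cost_pdl1_test": 0.0,
        "cost_pretreatment": 0.0,
        "cost_ae_con": 0.0,
        "cost_ae_ave": 0.0,
        "cost_imaging": 0.0,
        "cost_pd_monthly": 0.0,
        "cost_drug_monthly": 0.0,
        "cost_bsc_ave_monthly": 0.0,
        "cost_bsc_con_monthly": 0.0,
        "annual_discount_rate": 0.0,
    }
    base.update(overrides)
    return base


def stay_in_pfs_trace(horizon):
    trace = np.zeros((horizon + 1, 3))
    trace[:, 0] = 1.0
    return trace


class TestUnits:
    @pytest.mark.parametrize("score, expected", [(0, 0.0), (126, 1.0), (100.8, 0.8)])
    def test_qlqc30_utility(self, score, expected):
        assert utility_from_qlqc30(score) == pytest.approx(expected, abs=1e-12)

    def test_qlqc30_out_of_range(self):
        with pytest.raises(InvalidInputError):
            utility_from_qlqc30(130)

    def test_cny_conversion(self):
        assert cny_to_usd(6.36) == pytest.approx(1.0, abs=1e-12)
        assert cny_to_usd(0.0) == 0.0
        assert cny_to_usd(1000.0) == pytest.approx(157.23270440, abs=1e-6)
        with pytest.raises(InvalidInputError):
            cny_to_usd(10, rate=0)

    def test_week_month_conversion(self):
        assert weeks_to_months(52.18) == pytest.approx(12.0, abs=1e-12)
        assert TREATMENT_DURATION_MONTHS["AVE"] == pytest.approx(24.9 * 12 / 52.18)
        assert IMAGING_INTERVAL_MONTHS == pytest.approx(8 * 12 / 52.18)

    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [(0.0, 7, 1.0), (0.03, 12, 1 / 1.03), (0.05, 0, 1.0)],
    )
    def test_discount_factor(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-12)


class TestAccrue:
    def test_all_zero_inputs(self):
        spec = ModelSpec(horizon=12, arm="AVE")
        res = accrue(stay_in_pfs_trace(12), zero_values(), default_schedule(), spec)
        assert res.total_cost == 0.0 and res.total_qalys == 0.0

    def test_single_cycle_qaly_hand_value(self):
        spec = ModelSpec(horizon=1, arm="CON")
        res = accrue(
            stay_in_pfs_trace(1), zero_values(utility_pfs=0.84),
            default_schedule(), spec,
        )
        assert res.total_qalys == pytest.approx(0.84 / 12, abs=1e-12)
        assert res.total_qalys == pytest.approx(0.07, abs=1e-12)

    def test_annuity_matches_geometric_series(self):
        h, c, r = 120, 137.5, 0.03
        spec = ModelSpec(horizon=h, arm="CON")
        values = zero_values(cost_bsc_con_monthly=c, annual_discount_rate=r)
        res = accrue(stay_in_pfs_trace(h), values, default_schedule(), spec)
        x = (1 + r) ** (-1 / 12)
        closed_form = c * (1 - x**h) / (1 - x)
        assert res.total_cost == pytest.approx(closed_form, abs=1e-9)

    def test_one_time_items_charged_once_per_arm(self):
        spec = ModelSpec(horizon=24, arm="AVE")
        values = zero_values(cost_pdl1_test=431.28, cost_ae_ave=111.68, cost_ae_con=74.89)
        res = accrue(stay_in_pfs_trace(24), values, default_schedule(), spec)
        assert res.total_cost == pytest.approx(431.28 + 111.68)  # CON AE not charged

    def test_drug_stops_at_treatment_duration(self):
        spec = ModelSpec(horizon=120, arm="AVE")
        values = zero_values(cost_drug_monthly=100.0)
        res = accrue(stay_in_pfs_trace(120), values, default_schedule(), spec)
        # full months up to the stop, plus the prorated partial month
        assert res.total_cost == pytest.approx(100.0 * TREATMENT_DURATION_MONTHS["AVE"])

    def test_imaging_accrues_at_monthly_equivalent(self):
        spec = ModelSpec(horizon=12, arm="CON")
        values = zero_values(cost_imaging=1137.67)
        res = accrue(stay_in_pfs_trace(12), values, default_schedule(), spec)
        assert res.total_cost == pytest.approx(12 * 1137.67 / IMAGING_INTERVAL_MONTHS)

    def test_pd_cost_follows_pd_occupancy(self):
        h = 10
        trace = np.zeros((h + 1, 3))
        trace[:, 1] = 0.5
        trace[:, 0] = 0.5
        spec = ModelSpec(horizon=h, arm="CON")
        res = accrue(trace, zero_values(cost_pd_monthly=200.0), default_schedule(), spec)
        assert res.total_cost == pytest.approx(200.0 * 0.5 * h)

    def test_superposition_in_utilities_and_costs(self):
        rng = np.random.default_rng(3)
        h = 30
        trace = np.zeros((h + 1, 3))
        occ = rng.dirichlet((3, 2, 1), size=h + 1)
        trace[:] = occ
        spec = ModelSpec(horizon=h, arm="AVE")
        sched = default_schedule()
        a = accrue(trace, zero_values(utility_pfs=0.5, annual_discount_rate=0.03), sched, spec)
        b = accrue(trace, zero_values(utility_pd=0.25, annual_discount_rate=0.03), sched, spec)
        both = accrue(
            trace,
            zero_values(utility_pfs=0.5, utility_pd=0.25, annual_discount_rate=0.03),
            sched, spec,
        )
        assert both.total_qalys == pytest.approx(a.total_qalys + b.total_qalys, abs=1e-12)
        c1 = accrue(trace, zero_values(cost_pd_monthly=50.0), sched, spec)
        c2 = accrue(trace, zero_values(cost_pd_monthly=100.0), sched, spec)
        assert c2.total_cost == pytest.approx(2 * c1.total_cost, abs=1e-9)

    def test_discounting_monotone_in_rate(self):
        h = 60
        spec = ModelSpec(horizon=h, arm="CON")
        totals = [
            accrue(
                stay_in_pfs_trace(h),
                zero_values(utility_pfs=0.8, cost_bsc_con_monthly=10, annual_discount_rate=r),
                default_schedule(), spec,
            )
            for r in (0.0, 0.03, 0.05, 0.10)
        ]
        costs = [t.total_cost for t in totals]
        qalys = [t.total_qalys for t in totals]
        assert np.all(np.diff(costs) < 0) and np.all(np.diff(qalys) < 0)

    def test_missing_schedule_item_rejected(self):
        from mucea.economics import CostSchedule, CostItem

        sched = CostSchedule(items=(CostItem("cost_pdl1_test", "one_time_at_entry"),))
        spec = ModelSpec(horizon=2, arm="AVE")
        with pytest.raises(ConfigurationError):
            accrue(stay_in_pfs_trace(2), zero_values(), sched, spec)


class TestICER:
    def test_ratio_and_flags(self):
        base = ArmResult(total_cost=100.0, total_qalys=1.0)
        better_cheaper = ArmResult(total_cost=50.0, total_qalys=2.0)
        worse_pricier = ArmResult(total_cost=200.0, total_qalys=0.5)
        assert icer(ArmResult(300.0, 2.0), base).icer == pytest.approx(200.0)
        assert icer(better_cheaper, base).flag == "dominant"
        assert icer(worse_pricier, base).flag == "dominated"
        sw = icer(ArmResult(50.0, 0.5), base)
        assert sw.flag == "southwest" and sw.icer == pytest.approx(100.0)
        same = icer(base, base)
        assert same.flag == "undefined" and same.icer is None

    def test_nmb_example(self):
        arm = ArmResult(total_cost=1971.13, total_qalys=0.21)
        assert net_monetary_benefit(arm, 150_000) == pytest.approx(29_528.87, abs=1e-9)
        assert net_monetary_benefit(arm, 0.0) == pytest.approx(-1971.13)

    def test_nmb_icer_equivalence(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            ave = ArmResult(rng.uniform(0, 1e5), rng.uniform(0.5, 3))
            con = ArmResult(rng.uniform(0, 1e5), rng.uniform(0.1, ave.total_qalys - 1e-6))
            wtp = rng.uniform(1e3, 3e5)
            res = icer(ave, con)
            nmb_gap = net_monetary_benefit(ave, wtp) - net_monetary_benefit(con, wtp)
            if res.icer is not None and res.delta_qalys > 0:
                assert (nmb_gap > 0) == (res.icer < wtp)
            elif res.flag == "dominant":
                assert nmb_gap > 0
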