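import math

import numpy as np
import pytest

from psmcea import (
    ArmOutcome,
    DrugComponent,
    ModelParams,
    accrue_outcomes,
    ae_burden,
    build_trace,
    discount_factor,
    first_line_strategy,
    icer,
    regimen_cost_per_admin,
)
from psmcea.psm import (
    _FOLFOX_BACKBONE,
    StrategySpec,
    pap_cycle_cost,
    subsequent_cycle_cost,
)
from psmcea.uncertainty import apply_scenario_pap
from psmcea.units import DAYS_PER_YEAR


def _zero_cost_params(**over):
    """Params with no costs and unit utilities, for occupancy oracles."""
    base = dict(
        discount_rate=0.0,
        u_pfs=1.0,
        u_pd=1.0,
        admin_cost=0.0,
        followup_cost=0.0,
        prices={"pembrolizumab": 0.0, "nivolumab": 0.0, "bevacizumab": 0.0,
                "cetuximab": 0.0, "oxaliplatin": 0.0, "leucovorin": 0.0,
                "fluorouracil": 0.0, "irinotecan": 0.0, "capecitabine": 0.0},
        subsequent_mix={"P": {}, "C": {}},
        firstline_mix_C={},
    )
    base.update(over)
    return ModelParams(**base)


class TestDiscount:
    def test_zero_time_and_zero_rate(self):
        assert discount_factor(0.0, 0.05) == 1.0
        assert discount_factor(1234.0, 0.0) == 1.0

    def test_one_year_closed_form(self):
        assert discount_factor(365.25, 0.05) == pytest.approx(1 / 1.05, rel=1e-9)


class TestTrace:
    def test_identical_curves_give_zero_pd(self, baseline_params):
        s = lambda t: math.exp(-t / 500.0)
        tr = build_trace(s, s, baseline_params)
        assert np.allclose(tr.pd, 0.0)
        assert tr.occupancy_check()

    def test_crossing_curves_clamped(self, baseline_params):
        s_pfs = lambda t: 0.9 if t > 0 else 1.0
        s_os = lambda t: math.exp(-t / 300.0)
        tr = build_trace(s_pfs, s_os, baseline_params)
        crossed = np.array([s_os(t) for t in tr.times]) < 0.9
        crossed[0] = False
        assert np.allclose(tr.pfs[crossed], 1.0 - tr.dead[crossed], atol=1e-12)
        assert np.all(tr.pd[crossed] == 0.0)
        assert tr.occupancy_check()

    def test_horizon_stops_below_one_percent_survivors(self, baseline_params):
        lam = math.log(2) / DAYS_PER_YEAR  # median OS 1 year
        s = lambda t: math.exp(-lam * t)
        tr = build_trace(s, s, baseline_params)
        t_stop_years = tr.times[-1] / DAYS_PER_YEAR
        # e^{-lam t} = 0.01 at t = log2(100) ~ 6.644 years; stop at the
        # first 42-day cycle past that point
        assert 6.644 <= t_stop_years <= 6.644 + 42 / DAYS_PER_YEAR + 1e-9
        assert s(tr.times[-1]) < 0.01 <= s(tr.times[-2])

    def test_evaluator_out_of_range_rejected(self, baseline_params):
        with pytest.raises(ValueError, match="outside"):
            build_trace(lambda t: 1.5, lambda t: 1.0, baseline_params)


class TestRegimenCost:
    def test_folfox_backbone_hand_arithmetic(self, baseline_params):
        total = sum(
            regimen_cost_per_admin(c, baseline_params.prices, 1.80, 65.0)
            for c in _FOLFOX_BACKBONE
        )
        assert total == pytest.approx(2161.80)

    def test_bevacizumab_per_kg(self, baseline_params):
        bev = DrugComponent("bevacizumab", "per_kg", 5.0, 3)
        assert regimen_cost_per_admin(bev, baseline_params.prices, 1.80, 65.0) \
            == pytest.approx(4875.00)

    def test_flat_zero_dose(self, baseline_params):
        zero = DrugComponent("pembrolizumab", "flat", 0.0, 2)
        assert regimen_cost_per_admin(zero, baseline_params.prices, 1.8, 65) == 0.0

    def test_missing_price_names_drug(self):
        comp = DrugComponent("oxaliplatin", "per_m2", 85.0, 3)
        with pytest.raises(KeyError, match="oxaliplatin"):
            regimen_cost_per_admin(comp, {}, 1.8, 65)


class TestAEBurden:
    def test_zero_incidence(self):
        assert ae_burden([{"incidence": 0, "cost": 100, "disutility": -0.1}]) == (0, 0)

    def test_pembrolizumab_arm_hand_arithmetic(self, baseline_params):
        cost, qaly = ae_burden(baseline_params.ae_set("P"))
        assert cost == pytest.approx(61.35, abs=0.01)
        assert qaly == pytest.approx(0.01045, abs=1e-6)


class TestAccrual:
    def test_exponential_life_years_oracle(self):
        lam = math.log(2) / DAYS_PER_YEAR
        s = lambda t: math.exp(-lam * t)
        params = _zero_cost_params()
        tr = build_trace(s, s, params)
        out = accrue_outcomes(tr, first_line_strategy("P", params), params)
        T = tr.times[-1]
        analytic = (1 - math.exp(-lam * T)) / (lam * DAYS_PER_YEAR)
        assert out.ly == pytest.approx(analytic, rel=0.005)
        assert out.qaly == pytest.approx(out.ly)

    def test_pembrolizumab_administration_cap(self):
        # everyone stays progression-free: acquisition = exactly 35 doses
        params = _zero_cost_params(horizon_cap_years=3.0)
        params.prices["pembrolizumab"] = 179.18
        s_one = lambda t: 1.0
        tr = build_trace(s_one, s_one, params)
        out = accrue_outcomes(tr, first_line_strategy("P", params), params)
        assert out.costs["acquisition"] == pytest.approx(35 * 200 * 179.18)

    def test_equal_utilities_make_qaly_proportional_to_ly(self, baseline_params):
        s = lambda t: math.exp(-t / 700.0)
        import copy

        params = copy.deepcopy(baseline_params)
        params.u_pd = params.u_pfs
        tr = build_trace(s, s, params)
        out = accrue_outcomes(tr, first_line_strategy("P", params), params)
        # AE loss is additive; compare before subtraction
        _, ae_q = ae_burden(params.ae_set("P"))
        assert out.qaly + ae_q == pytest.approx(params.u_pfs * out.ly, rel=1e-12)

    def test_discount_monotonicity(self, baseline_params, exp_model):
        import copy

        vals = []
        for rate in (0.0, 0.05, 0.08):
            p = copy.deepcopy(baseline_params)
            p.discount_rate = rate
            out = exp_model.arm_outcome("P", p)
            vals.append((out.total_cost, out.qaly))
        costs, qalys = zip(*vals)
        assert costs[0] >= costs[1] >= costs[2]
        assert qalys[0] >= qalys[1] >= qalys[2]

    def test_cost_scale_equivariance(self, baseline_params, exp_model):
        import copy

        base = exp_model.evaluate(baseline_params)
        p = copy.deepcopy(baseline_params)
        s = 3.0
        for drug in p.prices:
            p.prices[drug] *= s
        p.admin_cost *= s
        p.followup_cost *= s
        for ae in p.ae_cost:
            p.ae_cost[ae] *= s
        scaled = exp_model.evaluate(p)
        assert scaled.d_cost == pytest.approx(s * base.d_cost, rel=1e-12)
        assert scaled.icer_per_qaly == pytest.approx(s * base.icer_per_qaly, rel=1e-12)

    def test_horizon_threshold_insensitivity(self, fitted_model, baseline_params):
        import copy

        p1 = copy.deepcopy(baseline_params)
        p2 = copy.deepcopy(baseline_params)
        p2.horizon_threshold = 0.001
        for arm in ("P", "C"):
            q1 = fitted_model.arm_outcome(arm, p1).qaly
            q2 = fitted_model.arm_outcome(arm, p2).qaly
            assert abs(q2 - q1) / q1 < 0.01


class TestICER:
    def test_printed_base_case_incrementals(self):
        p = ArmOutcome("P", ly=9.22, ly_undiscounted=9.22, qaly=6.71,
                       qaly_undiscounted=6.71, costs={"total": 229698.49})
        c = ArmOutcome("C", ly=6.22, ly_undiscounted=6.22, qaly=4.13,
                       qaly_undiscounted=4.13, costs={"total": 151412.44})
        res = icer(p, c)
        assert res.d_ly == pytest.approx(3.00, abs=1e-9)
        assert res.d_qaly == pytest.approx(2.58, abs=1e-9)
        assert res.d_cost == pytest.approx(78286.04, abs=0.02)

    def test_identical_outcomes_flag_undefined(self):
        a = ArmOutcome("P", 1, 1, 1, 1, {"total": 10.0})
        b = ArmOutcome("C", 1, 1, 1, 1, {"total": 10.0})
        res = icer(a, b)
        assert res.status == "undefined" and res.icer_per_qaly is None

    def test_cheaper_and_better_is_dominant(self):
        a = ArmOutcome("P", 2, 2, 2, 2, {"total": 9.0})
        b = ArmOutcome("C", 1, 1, 1, 1, {"total": 10.0})
        assert icer(a, b).status == "dominant"


class TestPAP:
    def test_two_year_cap(self, baseline_params):
        import copy

        p = apply_scenario_pap(baseline_params)
        assert p.pap_enabled and not baseline_params.pap_enabled
        total = sum(pap_cycle_cost(p, k) for k in range(1, 40))
        assert total == pytest.approx(22400.0)

    def test_one_year_proration(self, baseline_params):
        p = apply_scenario_pap(baseline_params)
        cycles_per_year = DAYS_PER_YEAR / p.cycle_length_days
        full = int(cycles_per_year)
        frac = cycles_per_year - full
        total = sum(pap_cycle_cost(p, k) for k in range(1, full + 1))
        total += frac * pap_cycle_cost(p, full + 1)
        assert total == pytest.approx(11200.0, rel=1e-9)

    def test_absent_pap_config_is_noop(self, baseline_params):
        import copy

        p = copy.deepcopy(baseline_params)
        p.pap_annual_cost = None
        assert apply_scenario_pap(p) is p


def test_subsequent_ici_cost_expires_after_cap(baseline_params):
    early = subsequent_cycle_cost(baseline_params, "P", 1)
    late = subsequent_cycle_cost(baseline_params, "P", 100)
    assert late < early  # ICI share zeroed beyond the 2-year cap
    # chemo/VEGF/EGFR share persists
    assert late > 0
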