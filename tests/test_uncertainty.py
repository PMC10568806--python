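import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmcea import (
    PSADraw,
    beta_from_moments,
    ceac,
    dsa_bounds,
    gamma_from_moments,
    run_dsa,
    run_psa,
)
from psmcea.uncertainty import ParamDistribution


class TestBetaMoments:
    def test_symmetric_hand_calculation(self):
        a, b = beta_from_moments(0.5, 0.1)
        assert a == pytest.approx(12.0) and b == pytest.approx(12.0)

    def test_printed_pd_utility_parameters_recover_mean(self):
        # printed beta(137.658, 77.432) for the progressive-disease utility
        a, b = 137.658, 77.432
        assert a / (a + b) == pytest.approx(0.640, abs=5e-4)

    def test_small_se_concentrates(self):
        a, b = beta_from_moments(0.3, 1e-4)
        assert a + b > 1e6
        assert a / (a + b) == pytest.approx(0.3, rel=1e-9)

    def test_moment_condition_violation(self):
        with pytest.raises(ValueError, match="moment condition"):
            beta_from_moments(0.5, 0.6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(mean=st.floats(0.01, 0.99), cv=st.floats(0.01, 0.5))
    def test_round_trip(self, mean, cv):
        se = cv * math.sqrt(mean * (1 - mean))
        a, b = beta_from_moments(mean, se)
        m2 = a / (a + b)
        v2 = a * b / ((a + b) ** 2 * (a + b + 1))
        assert m2 == pytest.approx(mean, rel=1e-9)
        assert math.sqrt(v2) == pytest.approx(se, rel=1e-9)


class TestGammaMoments:
    def test_administration_cost_row(self):
        shape, scale = gamma_from_moments(310.16, 77.540)
        assert shape == pytest.approx(16.000, abs=1e-3)
        assert scale == pytest.approx(19.385, abs=1e-3)

    def test_oxaliplatin_row(self):
        shape, scale = gamma_from_moments(3.4, 0.85)
        assert shape == pytest.approx(16.0)
        assert scale == pytest.approx(0.2125)

    def test_se_equals_mean_gives_exponential(self):
        shape, _ = gamma_from_moments(5.0, 5.0)
        assert shape == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_moments(-1.0, 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(mean=st.floats(0.01, 1e4), cv=st.floats(0.01, 2.0))
    def test_round_trip(self, mean, cv):
        shape, scale = gamma_from_moments(mean, cv * mean)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert scale * math.sqrt(shape) == pytest.approx(cv * mean, rel=1e-9)


def test_dsa_default_range_rule():
    lo, hi = dsa_bounds(0.06)
    assert lo == pytest.approx(0.048) and hi == pytest.approx(0.072)


class TestDSA:
    def test_degenerate_range_gives_zero_width(self, baseline_params, exp_model):
        reg = [ParamDistribution(pid="u_pfs", kind="fixed", baseline=0.7825,
                                 dsa_low=0.7825, dsa_high=0.7825)]
        out = run_dsa(baseline_params, reg, exp_model)
        assert out["width"].iloc[0] == pytest.approx(0.0)

    def test_followup_cost_does_not_touch_effects(self, baseline_params, exp_model):
        base = exp_model.evaluate(baseline_params)
        for bound in (25.06, 37.60):
            res = exp_model.evaluate(baseline_params.with_value("followup_cost", bound))
            assert res.d_qaly == pytest.approx(base.d_qaly, rel=1e-12)

    def test_output_is_permutation_of_registry(self, baseline_params, registry,
                                               exp_model):
        out = run_dsa(baseline_params, registry, exp_model)
        assert sorted(out["param"]) == sorted(d.pid for d in registry)

    def test_discount_rate_raises_icer(self, baseline_params, registry, fitted_model):
        out = run_dsa(baseline_params, registry, fitted_model)
        row = out[out["param"] == "discount_rate"].iloc[0]
        assert row["icer_high"] > row["icer_low"]  # 0.08 vs 0


class TestPSA:
    def test_all_fixed_reproduces_base_case(self, baseline_params, exp_model):
        reg = [ParamDistribution(pid="u_pfs", kind="fixed", baseline=0.7825,
                                 dsa_low=0.7, dsa_high=0.9)]
        draws = run_psa(baseline_params, reg, 5, seed=1, model=exp_model)
        base = exp_model.evaluate(baseline_params)
        for d in draws:
            assert d.d_cost == pytest.approx(base.d_cost)
            assert d.d_qaly == pytest.approx(base.d_qaly)

    def test_same_seed_bitwise_identical(self, baseline_params, registry, exp_model):
        a = run_psa(baseline_params, registry, 20, seed=9, model=exp_model)
        b = run_psa(baseline_params, registry, 20, seed=9, model=exp_model)
        assert [(d.d_cost, d.d_qaly) for d in a] == [(d.d_cost, d.d_qaly) for d in b]

    def test_sampled_means_match_distributions(self, baseline_params, registry,
                                               exp_model):
        draws = run_psa(baseline_params, registry, 500, seed=3, model=exp_model)
        by_pid = {d.pid: d for d in registry if d.kind != "fixed"}
        for pid, dist in by_pid.items():
            samples = np.array([dr.sampled[pid] for dr in draws])
            mc_se = dist.dist_sd / math.sqrt(len(samples))
            assert abs(samples.mean() - dist.dist_mean) <= 3 * mc_se, pid

    def test_mixture_weights_renormalized(self, baseline_params, registry, exp_model):
        # capture the params actually evaluated
        seen = []

        def spy(params):
            seen.append(copy.deepcopy(params))
            return exp_model.evaluate(params)

        run_psa(baseline_params, registry, 3, seed=2, model=spy)
        for p in seen:
            for arm in ("P", "C"):
                assert sum(p.subsequent_mix[arm].values()) == pytest.approx(1.0)

    def test_disutilities_applied_negative(self, baseline_params, registry, exp_model):
        seen = []

        def spy(params):
            seen.append(copy.deepcopy(params))
            return exp_model.evaluate(params)

        run_psa(baseline_params, registry, 3, seed=2, model=spy)
        for p in seen:
            assert all(v <= 0 for v in p.ae_disutility.values())


class TestCEAC:
    def _draws(self):
        rng = np.random.default_rng(0)
        return [
            PSADraw(i + 1, {}, d_cost=float(c), d_qaly=float(q))
            for i, (c, q) in enumerate(
                zip(rng.normal(5e4, 2e4, 200), rng.normal(1.0, 0.8, 200))
            )
        ]

    def test_lambda_zero_is_fraction_cost_saving(self):
        draws = self._draws()
        pt = ceac(draws, [0.0])[0]
        assert pt.probability == pytest.approx(
            np.mean([d.d_cost < 0 for d in draws])
        )

    def test_lambda_huge_is_fraction_qaly_gaining(self):
        draws = self._draws()
        pt = ceac(draws, [1e12])[0]
        assert pt.probability == pytest.approx(
            np.mean([d.d_qaly > 0 for d in draws])
        )

    def test_degenerate_icer_steps_at_ratio(self):
        draws = [PSADraw(i, {}, d_cost=200.0, d_qaly=2.0) for i in range(10)]
        probs = [p.probability for p in ceac(draws, [99.0, 101.0])]
        assert probs == [0.0, 1.0]

    def test_probabilities_bounded(self, baseline_params, registry, exp_model):
        draws = run_psa(baseline_params, registry, 50, seed=5, model=exp_model)
        pts = ceac(draws, np.linspace(0, 6e4, 25))
        assert all(0.0 <= p.probability <= 1.0 for p in pts)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ceac(self._draws(), [])


def test_psa_median_property(baseline_params, registry, exp_model):
    """At the base-case ICER taken as the threshold, roughly half the
    draws should be cost-effective (median property, checked loosely)."""
    base = exp_model.evaluate(baseline_params)
    draws = run_psa(baseline_params, registry, 1500, seed=13, model=exp_model)
    prob = ceac(draws, [base.icer_per_qaly])[0].probability
    assert abs(prob - 0.5) <= 0.1
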