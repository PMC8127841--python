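"""Cohort engine: occupancy oracle equivalence, discounting, valuation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcrc_cea.cohort_engine import (
    TransitionParams,
    accumulate_cost,
    accumulate_qaly,
    closed_form_occupancy,
    discount_factor,
    evaluate_arm,
    occupancy_curves,
    run_trace,
)
from mcrc_cea.param_model import Realization, UtilitySet, ValidationError

PARAMS = TransitionParams(0.016, 0.002, 0.008)


def transition_strategy():
    return st.tuples(
        st.floats(0.0, 0.5), st.floats(0.0, 0.4), st.floats(0.0, 0.9)
    ).map(lambda t: TransitionParams(*t))


class TestOccupancy:
    def test_zero_step_is_initial_state(self):
        np.testing.assert_array_equal(closed_form_occupancy(PARAMS, 0), [1, 0, 0])

    def test_one_step_algebra(self):
        a, b, c = 0.1, 0.05, 0.2
        occ = closed_form_occupancy(TransitionParams(a, b, c), 1)
        np.testing.assert_allclose(occ, [1 - a - b, a, b], atol=1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            closed_form_occupancy(PARAMS, -1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(tp=transition_strategy())
    def test_trace_marginals_equal_matrix_power(self, tp):
        trace = run_trace(tp, horizon_weeks=60)
        for t in (0, 1, 7, 33, 60):
            oracle = closed_form_occupancy(tp, t)
            got = np.array([trace.pf[t], trace.pd_total[t], trace.dead[t]])
            np.testing.assert_allclose(got, oracle, atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(tp=transition_strategy())
    def test_conservation_and_monotone_death(self, tp):
        trace = run_trace(tp, horizon_weeks=80)
        trace.validate(atol=1e-12)

    def test_closed_form_curves_equal_matrix_power(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.uniform(0, 0.4, 2) / 2
            c = rng.uniform(0, 0.5)
            tp = TransitionParams(a, b, c)
            occ = occupancy_curves(tp, 100)
            for t in (0, 1, 50, 100):
                np.testing.assert_allclose(
                    occ[t], closed_form_occupancy(tp, t), atol=1e-12
                )

    def test_equal_rates_limit_case(self):
        tp = TransitionParams(0.02, 0.0, 0.02)  # q == c exactly
        occ = occupancy_curves(tp, 50)
        for t in (1, 25, 50):
            np.testing.assert_allclose(occ[t], closed_form_occupancy(tp, t), atol=1e-10)

    def test_pf_closed_form(self):
        trace = run_trace(PARAMS, horizon_weeks=520)
        t = np.arange(521)
        np.testing.assert_allclose(
            trace.pf, (1 - PARAMS.q_pf_exit) ** t, atol=1e-12
        )

    def test_inert_params_stay_progression_free(self):
        trace = run_trace(TransitionParams(0, 0, 0), horizon_weeks=30)
        assert (trace.pf == 1.0).all()

    def test_tunnel_pooling_conserves_mass(self):
        full = run_trace(PARAMS, horizon_weeks=200)
        capped = run_trace(PARAMS, horizon_weeks=200, pd_tunnel_cap=10)
        np.testing.assert_allclose(capped.pd_total, full.pd_total, atol=1e-12)
        capped.validate()


class TestDiscounting:
    def test_week_zero(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_one_year(self):
        assert discount_factor(52, 0.03) == pytest.approx(1 / 1.03, rel=1e-12)

    def test_zero_rate(self):
        weeks = np.arange(520)
        np.testing.assert_array_equal(discount_factor(weeks, 0.0), np.ones(520))


class TestQALY:
    def test_immortal_cohort_10_years(self):
        trace = run_trace(TransitionParams(0, 0, 0), horizon_weeks=520)
        u = UtilitySet(1.0, 1.0, 1.0, 0.0)
        q = accumulate_qaly(trace, u, 0.0, 52, 0.0)
        assert q == pytest.approx(10.0, abs=1e-12)

    def test_unit_utility_zero_rate_equals_life_years(self):
        trace = run_trace(PARAMS, horizon_weeks=520)
        u = UtilitySet(1.0, 1.0, 1.0, 0.0)
        q = accumulate_qaly(trace, u, 0.0, 52, 0.0)
        assert q == pytest.approx(trace.life_years(), abs=1e-10)

    def test_discounted_below_undiscounted(self, params):
        trace = run_trace(PARAMS, horizon_weeks=520)
        u = params.utilities()
        assert accumulate_qaly(trace, u, 0.1, 52, 0.03) < accumulate_qaly(
            trace, u, 0.1, 52, 0.0
        )

    def test_second_line_utility_product(self, params):
        u = params.utilities()
        assert round(u.second_line, 2) == 0.63

    def test_ae_decrement_monotone(self, params):
        trace = run_trace(PARAMS, horizon_weeks=520)
        base = params.utilities()
        doubled = UtilitySet(base.u_pf, base.r_pd, base.r_pall, 2 * base.d_ae)
        q1 = accumulate_qaly(trace, base, 0.4, 52, 0.03)
        q2 = accumulate_qaly(trace, doubled, 0.4, 52, 0.03)
        assert q2 < q1


def _priced_realization(params, overrides):
    base = params.base_realization()
    values = dict(base.values)
    values.update(overrides)
    return Realization(values=values, utilities=base.utilities, ae_probs=base.ae_probs)


class TestCost:
    def test_drug_component_linear_in_price(self, params):
        trace = run_trace(PARAMS, horizon_weeks=520)
        arm = params.arms["anti_egfr"]
        zeroed = {arm.backbone: 0.0, arm.second_line_drug: 0.0, arm.second_line_backbone: 0.0}
        c1 = accumulate_cost(
            trace, arm, _priced_realization(params, {**zeroed, "cetuximab": 1577.0}),
            52, 0.03,
        )
        c2 = accumulate_cost(
            trace, arm, _priced_realization(params, {**zeroed, "cetuximab": 3154.0}),
            52, 0.03,
        )
        assert c2["drug"] == pytest.approx(2 * c1["drug"], rel=1e-12)

    def test_admin_interval_scales_weekly_accrual(self, params):
        from dataclasses import replace

        trace = run_trace(PARAMS, horizon_weeks=520)
        arm2 = params.arms["anti_egfr"]
        arm3 = replace(arm2, admin_interval=3)
        zeroed = _priced_realization(
            params,
            {arm2.second_line_drug: 0.0, arm2.second_line_backbone: 0.0},
        )
        c2 = accumulate_cost(trace, arm2, zeroed, 52, 0.0)
        c3 = accumulate_cost(trace, arm3, zeroed, 52, 0.0)
        assert c3["drug"] == pytest.approx(c2["drug"] * 2 / 3, rel=1e-12)

    def test_degenerate_trace_costs_nothing(self, params):
        # immortal, cost-free world
        trace = run_trace(TransitionParams(0, 0, 0), horizon_weeks=10)
        zeros = {name: 0.0 for name in params.params}
        world = Realization(
            values=zeros,
            utilities=UtilitySet(0, 0, 0, 0),
            ae_probs={k: 0.0 for k in params.base_realization().ae_probs},
        )
        c = accumulate_cost(trace, params.arms["bev"], world, 52, 0.0)
        assert c["total"] == 0.0


class TestEvaluateArm:
    def test_components_sum_to_total(self, params):
        out = evaluate_arm(PARAMS, params.arms["anti_egfr"], params, params.settings)
        assert sum(out.components.values()) == pytest.approx(
            out.discounted_cost, abs=1e-9
        )
        assert out.discounted_qaly <= out.undiscounted_qaly

    def test_qaly_decreases_with_pf_death_rate(self, params):
        arm = params.arms["bev"]
        qalys = [
            evaluate_arm(
                TransitionParams(0.016, b, 0.008), arm, params, params.settings
            ).discounted_qaly
            for b in (0.001, 0.004, 0.012)
        ]
        assert qalys[0] > qalys[1] > qalys[2]

    def test_half_cycle_correction_flag(self, params):
        from dataclasses import replace

        hc = replace(params.settings, half_cycle_correction=True)
        out0 = evaluate_arm(PARAMS, params.arms["bev"], params, params.settings)
        out1 = evaluate_arm(PARAMS, params.arms["bev"], params, hc)
        # every transition moves mass to a lower-utility state, so the
        # utility-weighted occupancy is non-increasing within each cycle
        # and the mid-cycle average must value below the cycle start
        assert out1.discounted_qaly < out0.discounted_qaly
        assert out1.discounted_cost != out0.discounted_cost
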