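"""Incremental results, PSA, CEAC, tornado and price-threshold analyses."""

import numpy as np
import pandas as pd
import pytest

from mcrc_cea.cea_analysis import (
    ceac,
    cost_threshold,
    icer,
    one_way_tornado,
    run_psa,
)
from mcrc_cea.cohort_engine import ArmOutcome, evaluate_arm
from mcrc_cea.param_model import ValidationError


def outcome(name, cost, qaly):
    return ArmOutcome(
        arm=name,
        discounted_cost=cost,
        discounted_qaly=qaly,
        life_years=qaly,
        undiscounted_qaly=qaly,
    )


class TestICER:
    def test_ratio_case(self):
        res = icer(outcome("ref", 128_281, 1.69), outcome("cmp", 153_909, 1.93))
        assert res.flag is None
        assert res.icer == pytest.approx(res.inc_cost / res.inc_qaly)
        assert res.icer > 0

    def test_identical_outcomes_undefined(self):
        a = outcome("a", 100.0, 1.0)
        assert icer(a, a).flag == "undefined"

    def test_cheaper_more_effective_dominant(self):
        res = icer(outcome("ref", 100.0, 1.0), outcome("cmp", 90.0, 1.2))
        assert res.is_dominant and res.icer is None

    def test_mirror_flags_consistent(self):
        a, b = outcome("a", 100.0, 1.0), outcome("b", 90.0, 1.2)
        assert icer(a, b).is_dominant and icer(b, a).is_dominated

    def test_both_negative_increments_still_a_ratio(self):
        res = icer(outcome("ref", 100.0, 1.2), outcome("cmp", 80.0, 1.0))
        assert res.flag is None and res.icer == pytest.approx(100.0)


class TestPSA:
    def test_degenerate_psa_equals_base_case(self, fitted_strategies, params):
        psa = run_psa(fitted_strategies, params, n_reps=1, degenerate=True)
        for s in fitted_strategies:
            base = evaluate_arm(s.draws.median(), s.arm, params, params.settings)
            rep = psa.replications[psa.replications["strategy"] == s.name].iloc[0]
            assert rep["cost"] == pytest.approx(base.discounted_cost, abs=1e-9)
            assert rep["qaly"] == pytest.approx(base.discounted_qaly, abs=1e-9)

    def test_fixed_seed_reproducible(self, fitted_strategies, params):
        p1 = run_psa(fitted_strategies, params, n_reps=40, seed=5)
        p2 = run_psa(fitted_strategies, params, n_reps=40, seed=5)
        assert p1.replications.equals(p2.replications)

    def test_reps_beyond_draws_need_resample_flag(self, fitted_strategies, params):
        n_draws = min(len(s.draws) for s in fitted_strategies)
        with pytest.raises(ValidationError, match="resample"):
            run_psa(fitted_strategies, params, n_reps=n_draws + 1)
        psa = run_psa(fitted_strategies, params, n_reps=5, resample=True, seed=1)
        assert len(psa.replications) == 10

    def test_infinite_wtp_probability_is_positive_qaly_fraction(
        self, fitted_strategies, params
    ):
        psa = run_psa(fitted_strategies, params, n_reps=100, seed=2)
        ref, comp = psa.strategies
        qaly = psa.replications.pivot(index="rep", columns="strategy", values="qaly")
        frac = float((qaly[comp] > qaly[ref]).mean())
        assert psa.prob_cost_effective(1e12, comp) == pytest.approx(frac, abs=0.01)

    def test_summary_percentiles_ordered(self, fitted_strategies, params):
        psa = run_psa(fitted_strategies, params, n_reps=60, seed=3)
        s = psa.summary()
        assert (s["lower"] <= s["median"]).all() and (s["median"] <= s["upper"]).all()


class TestCEAC:
    def make_reps(self, costs_a, qalys_a, costs_b, qalys_b):
        rows = []
        for i, (ca, qa, cb, qb) in enumerate(zip(costs_a, qalys_a, costs_b, qalys_b)):
            rows.append({"rep": i, "strategy": "A", "cost": ca, "qaly": qa})
            rows.append({"rep": i, "strategy": "B", "cost": cb, "qaly": qb})
        return pd.DataFrame(rows)

    def test_identical_strategies_split_ties(self):
        reps = self.make_reps([10, 10], [1, 1], [10, 10], [1, 1])
        curve = ceac(reps, np.array([0.0, 50.0, 1e6]))
        assert (curve["probability"] == 0.5).all()

    def test_zero_wtp_rewards_min_cost(self):
        reps = self.make_reps([10, 10], [1, 1], [5, 20], [9, 9])
        curve = ceac(reps, np.array([0.0]))
        pb = curve[curve["strategy"] == "B"]["probability"].iloc[0]
        assert pb == 0.5  # B cheaper in rep 0, dearer in rep 1

    def test_probabilities_sum_to_one(self, fitted_strategies, params):
        psa = run_psa(fitted_strategies, params, n_reps=50, seed=4)
        curve = psa.ceac(np.array([0, 50_000, 97_832, 200_000], dtype=float))
        sums = curve.groupby("wtp")["probability"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_monotone_when_qaly_superior_everywhere(self):
        reps = self.make_reps(
            [10, 12, 9], [1.0, 1.1, 0.9], [30, 25, 28], [1.5, 1.6, 1.3]
        )
        grid = np.linspace(0, 200, 21)
        curve = ceac(reps, grid)
        pb = curve[curve["strategy"] == "B"]["probability"].to_numpy()
        assert np.all(np.diff(pb) >= 0)


class TestTornado:
    def test_sorted_by_range_and_zero_width_param(self, fitted_strategies, params):
        from dataclasses import replace as dreplace

        # pin one parameter's one-way range to its base value
        p = params["xelox"]
        pinned = dreplace(p, low=p.base, high=p.base)
        new_params = dreplace(params, params={**params.params, "xelox": pinned})
        table = one_way_tornado(fitted_strategies, new_params)
        widths = table["width"].to_numpy(dtype=float)
        finite = widths[~np.isnan(widths)]
        assert np.all(np.diff(finite) <= 1e-12)
        xelox = table[table["parameter"] == "xelox"].iloc[0]
        assert xelox["width"] == pytest.approx(0.0, abs=1e-9)

    def test_icer_increases_with_anti_egfr_price(self, fitted_strategies, params):
        from mcrc_cea.cea_analysis import _scale_drug_price

        ref, comp = fitted_strategies
        tps = {s.name: s.draws.median() for s in fitted_strategies}
        icers = []
        for m in (0.75, 1.0, 1.25):
            econ = _scale_drug_price(params, comp.arm.first_line_drug, m)
            o_ref = evaluate_arm(tps[ref.name], ref.arm, econ, econ.settings)
            o_cmp = evaluate_arm(tps[comp.name], comp.arm, econ, econ.settings)
            res = icer(o_ref, o_cmp)
            assert res.flag is None
            icers.append(res.icer)
        assert icers[0] < icers[1] < icers[2]


class TestCostThreshold:
    def test_unit_multiplier_reproduces_plain_psa(self, fitted_strategies, params):
        wtp = params.settings.wtp
        table = cost_threshold(
            fitted_strategies, params, price_multipliers=(1.0,), n_reps=60, seed=6
        )
        psa = run_psa(
            fitted_strategies, params, n_reps=60, wtp_grid=np.array([wtp]), seed=6
        )
        comp = fitted_strategies[-1].name
        assert table["fraction_cost_effective"].iloc[0] == pytest.approx(
            psa.prob_cost_effective(wtp, comp)
        )

    def test_fraction_monotone_in_price(self, fitted_strategies, params):
        table = cost_threshold(
            fitted_strategies,
            params,
            price_multipliers=(0.5, 0.7, 0.9, 1.0),
            n_reps=80,
            seed=7,
        )
        f = table["fraction_cost_effective"].to_numpy()
        assert np.all(np.diff(f) <= 1e-12)

    def test_multiplier_domain(self, fitted_strategies, params):
        with pytest.raises(ValidationError):
            cost_threshold(fitted_strategies, params, price_multipliers=(0.0, 1.0))
        with pytest.raises(ValidationError):
            cost_threshold(fitted_strategies, params, price_multipliers=(1.2,))
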