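"""Incremental cost-effectiveness results and the sensitivity-analysis suite.

Covers the deterministic ICER with dominance handling, probabilistic
sensitivity analysis (joint resampling of every economic/utility/AE
parameter plus a posterior transition draw per strategy), the
cost-effectiveness acceptability curve (net-monetary-benefit win
fractions over a willingness-to-pay grid), one-way tornado analysis at
the published low/high extremes, and price-threshold sweeps for the
anti-EGFR biologic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import ArmOutcome, TransitionParams, evaluate_arm
from .param_model import (
    ArmSpec,
    EconParam,
    ParameterSet,
    Realization,
    UtilitySet,
    ValidationError,
)
from .transition_fit import PosteriorDraws

__all__ = [
    "CEAResult",
    "Strategy",
    "PSAResult",
    "icer",
    "run_psa",
    "ceac",
    "one_way_tornado",
    "cost_threshold",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = np.arange(0, 300_001, 2_500, dtype=float)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost, incremental QALY and the ICER or a dominance flag.

    ``flag`` is None when the ratio is well defined (cost and QALY
    increments share sign and the QALY increment is nonzero);
    'dominant' means the comparator is cheaper and at least as effective,
    'dominated' the reverse, 'undefined' a degenerate tie.
    """

    inc_cost: float
    inc_qaly: float
    icer: float | None
    flag: str | None = None

    @property
    def is_dominant(self) -> bool:
        return self.flag == DOMINANT

    @property
    def is_dominated(self) -> bool:
        return self.flag == DOMINATED


def icer(reference: ArmOutcome, comparator: ArmOutcome) -> CEAResult:
    """Incremental result of ``comparator`` versus ``reference``."""
    dc = comparator.discounted_cost - reference.discounted_cost
    dq = comparator.discounted_qaly - reference.discounted_qaly
    if dq == 0.0:
        if dc > 0:
            return CEAResult(dc, dq, None, DOMINATED)
        if dc < 0:
            return CEAResult(dc, dq, None, DOMINANT)
        return CEAResult(dc, dq, None, UNDEFINED)
    if dq > 0 and dc <= 0:
        return CEAResult(dc, dq, None, DOMINANT)
    if dq < 0 and dc >= 0:
        return CEAResult(dc, dq, None, DOMINATED)
    return CEAResult(dc, dq, dc / dq, None)


@dataclass(frozen=True)
class Strategy:
    """A named arm together with its fitted transition posterior."""

    arm: ArmSpec
    draws: PosteriorDraws

    @property
    def name(self) -> str:
        return self.arm.name


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis replications and summaries."""

    replications: pd.DataFrame  # columns: rep, strategy, cost, qaly
    strategies: tuple[str, ...]
    wtp_grid: np.ndarray
    seed: int | None = None

    def _pivot(self, col: str) -> pd.DataFrame:
        return self.replications.pivot(index="rep", columns="strategy", values=col)

    def summary(self) -> pd.DataFrame:
        """Medians with 2.5/97.5 percentile intervals (means for reference)."""
        rows = []
        cost = self._pivot("cost")
        qaly = self._pivot("qaly")
        for s in self.strategies:
            for metric, series in (("cost", cost[s]), ("qaly", qaly[s])):
                rows.append(
                    {
                        "strategy": s,
                        "metric": metric,
                        "median": series.median(),
                        "lower": series.quantile(0.025),
                        "upper": series.quantile(0.975),
                        "mean": series.mean(),
                    }
                )
        if len(self.strategies) == 2:
            ref, comp = self.strategies
            inc_cost = cost[comp] - cost[ref]
            inc_qaly = qaly[comp] - qaly[ref]
            for metric, series in (("inc_cost", inc_cost), ("inc_qaly", inc_qaly)):
                rows.append(
                    {
                        "strategy": f"{comp} vs {ref}",
                        "metric": metric,
                        "median": series.median(),
                        "lower": series.quantile(0.025),
                        "upper": series.quantile(0.975),
                        "mean": series.mean(),
                    }
                )
            pos = inc_qaly > 0
            ratios = inc_cost[pos] / inc_qaly[pos]
            if len(ratios):
                rows.append(
                    {
                        "strategy": f"{comp} vs {ref}",
                        "metric": "icer",
                        "median": ratios.median(),
                        "lower": ratios.quantile(0.025),
                        "upper": ratios.quantile(0.975),
                        "mean": ratios.mean(),
                    }
                )
        return pd.DataFrame(rows)

    def icer_distribution(self) -> dict:
        """Per-replication ICER restricted to positive incremental QALYs."""
        if len(self.strategies) != 2:
            raise ValidationError("ICER distribution requires exactly two strategies")
        ref, comp = self.strategies
        cost = self._pivot("cost")
        qaly = self._pivot("qaly")
        inc_cost = cost[comp] - cost[ref]
        inc_qaly = qaly[comp] - qaly[ref]
        pos = inc_qaly > 0
        ratios = (inc_cost[pos] / inc_qaly[pos]).to_numpy()
        return {
            "ratios": ratios,
            "n_nonpositive_inc_qaly": int((~pos).sum()),
        }

    def ceac(self, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
        return ceac(self.replications, self.wtp_grid if wtp_grid is None else wtp_grid)

    def prob_cost_effective(self, wtp: float, strategy: str | None = None) -> float:
        """Fraction of replications the (last) strategy wins at ``wtp``."""
        strategy = strategy or self.strategies[-1]
        curve = ceac(self.replications, np.array([float(wtp)]))
        row = curve[(curve["strategy"] == strategy)]
        return float(row["probability"].iloc[0])


def run_psa(
    strategies: Sequence[Strategy],
    econ: ParameterSet,
    n_reps: int = 10_000,
    wtp_grid: np.ndarray | None = None,
    seed: int = 0,
    degenerate: bool = False,
    resample: bool = False,
) -> PSAResult:
    """Monte Carlo PSA: one joint parameter world per replication.

    Economic, utility and AE parameters are drawn once per replication and
    shared across strategies; each strategy additionally receives one of
    its posterior transition draws (without replacement unless
    ``resample``).  ``degenerate=True`` pins every parameter at its base
    value and every strategy at its posterior median (the deterministic
    base case), which is useful for validation.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    names = tuple(s.name for s in strategies)
    if len(set(names)) != len(names):
        raise ValidationError("strategy names must be unique")
    wtp_grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, float)
    rng = np.random.default_rng(seed)

    idx: dict[str, np.ndarray] = {}
    for s in strategies:
        n_draws = len(s.draws)
        if degenerate:
            idx[s.name] = np.zeros(n_reps, dtype=int)
        elif resample:
            idx[s.name] = rng.integers(0, n_draws, size=n_reps)
        else:
            if n_reps > n_draws:
                raise ValidationError(
                    f"{n_reps} replications exceed {n_draws} posterior draws "
                    f"for strategy {s.name!r}; pass resample=True"
                )
            idx[s.name] = rng.permutation(n_draws)[:n_reps]

    rows = []
    settings = econ.settings
    medians = {s.name: s.draws.median() for s in strategies}
    for rep in range(n_reps):
        world = econ.base_realization() if degenerate else econ.sample_realization(rng)
        for s in strategies:
            tp = medians[s.name] if degenerate else s.draws[int(idx[s.name][rep])]
            out = evaluate_arm(tp, s.arm, world, settings)
            rows.append(
                {
                    "rep": rep,
                    "strategy": s.name,
                    "cost": out.discounted_cost,
                    "qaly": out.discounted_qaly,
                }
            )
    return PSAResult(
        replications=pd.DataFrame(rows),
        strategies=names,
        wtp_grid=wtp_grid,
        seed=seed,
    )


def ceac(replications: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA replications.

    At each willingness-to-pay the strategy with the highest net monetary
    benefit (wtp * QALY - cost) wins the replication; exact ties share
    the win equally.  Probabilities across strategies sum to one.
    """
    if replications.empty:
        raise ValidationError("no replications")
    cost = replications.pivot(index="rep", columns="strategy", values="cost")
    qaly = replications.pivot(index="rep", columns="strategy", values="qaly")
    strategies = list(cost.columns)
    c = cost.to_numpy()
    qq = qaly.to_numpy()
    rows = []
    for w in np.asarray(wtp_grid, dtype=float):
        nmb = w * qq - c
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        for s, p in zip(strategies, probs):
            rows.append({"wtp": w, "strategy": s, "probability": float(p)})
    return pd.DataFrame(rows)


def _tornado_item(name: str, low: CEAResult, high: CEAResult) -> dict:
    def val(r: CEAResult):
        return r.icer if r.flag is None else r.flag

    width = (
        abs(high.icer - low.icer)
        if (low.flag is None and high.flag is None)
        else np.nan
    )
    return {
        "parameter": name,
        "icer_low": val(low),
        "icer_high": val(high),
        "width": width,
    }


def one_way_tornado(
    strategies: Sequence[Strategy],
    econ: ParameterSet,
    transition_level: float = 0.95,
) -> pd.DataFrame:
    """One-way (univariable) sensitivity of the ICER.

    Every parameter-table row is set alone to its low and high extreme;
    AE incidences are varied over their beta 2.5/97.5 quantiles; each
    transition coordinate of each strategy is varied over its posterior
    2.5/97.5 interval.  Rows are sorted by ICER range (widest first);
    dominance at an extreme is recorded as a flag, not a number.
    """
    if len(strategies) != 2:
        raise ValidationError("tornado requires exactly two strategies")
    ref, comp = strategies
    settings = econ.settings
    base_tp = {s.name: s.draws.median() for s in strategies}

    def evaluate(world: Realization, tps: Mapping[str, TransitionParams]) -> CEAResult:
        out_ref = evaluate_arm(tps[ref.name], ref.arm, world, settings)
        out_comp = evaluate_arm(tps[comp.name], comp.arm, world, settings)
        return icer(out_ref, out_comp)

    base_world = econ.base_realization()
    items = []

    # parameter-table rows at their one-way extremes
    for name, p in econ.params.items():
        results = []
        for v in (p.low, p.high):
            values = dict(base_world.values)
            values[name] = v
            utilities = UtilitySet(
                u_pf=values["progression_free"],
                r_pd=values["progressed_relative"],
                r_pall=values["palliative_relative"],
                d_ae=values["ae_decrement"],
            )
            world = Realization(
                values=values, utilities=utilities, ae_probs=base_world.ae_probs
            )
            results.append(evaluate(world, base_tp))
        items.append(_tornado_item(name, *results))

    # AE incidences over their beta 95% quantiles
    alpha = (1.0 - transition_level) / 2.0
    for s in strategies:
        for ae in s.arm.ae_profile:
            results = []
            for qtl in (alpha, 1.0 - alpha):
                probs = dict(base_world.ae_probs)
                probs[(s.name, ae.name)] = ae.prob_dist.ppf(qtl)
                world = Realization(
                    values=base_world.values,
                    utilities=base_world.utilities,
                    ae_probs=probs,
                )
                results.append(evaluate(world, base_tp))
            items.append(_tornado_item(f"{s.name}:ae_{ae.name}", *results))

    # transition coordinates over their posterior intervals
    for s in strategies:
        lo, hi = s.draws.interval(transition_level)
        med = base_tp[s.name]
        for j, coord in enumerate(("p_pf_pd", "p_pf_dead", "p_pd_dead")):
            results = []
            for v in (lo[j], hi[j]):
                d = med.as_dict()
                d[coord] = float(v)
                tps = dict(base_tp)
                try:
                    tps[s.name] = TransitionParams(**d)
                except ValidationError:
                    continue
                results.append(evaluate(base_world, tps))
            if len(results) == 2:
                items.append(_tornado_item(f"{s.name}:{coord}", *results))

    df = pd.DataFrame(items)
    return df.sort_values("width", ascending=False, na_position="last").reset_index(
        drop=True
    )


def _scale_drug_price(econ: ParameterSet, drug: str, multiplier: float) -> ParameterSet:
    """Scale a drug's acquisition price (base, range and gamma scale)."""
    p = econ[drug]
    scaled = EconParam(
        name=p.name,
        base=p.base * multiplier,
        low=p.low * multiplier,
        high=p.high * multiplier,
        dist=replace(p.dist, b=p.dist.b * multiplier),
        unit=p.unit,
    )
    params = dict(econ.params)
    params[drug] = scaled
    return replace(econ, params=params)


def cost_threshold(
    strategies: Sequence[Strategy],
    econ: ParameterSet,
    price_multipliers: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_reps: int = 1_000,
    wtp: float | None = None,
    seed: int = 0,
    resample: bool = False,
) -> pd.DataFrame:
    """Price-threshold sweep for the comparator's first-line biologic.

    The acquisition price of the last strategy's first-line drug is
    scaled by each multiplier; the PSA is re-run with the same seed
    (common random numbers), and the fraction of replications in which
    that strategy attains the higher net monetary benefit at ``wtp`` is
    reported.  Common random numbers make the fraction exactly monotone
    non-increasing in the multiplier.
    """
    if any(not (0.0 < m <= 1.0) for m in price_multipliers):
        raise ValidationError("price multipliers must lie in (0, 1]")
    wtp = econ.settings.wtp if wtp is None else float(wtp)
    if wtp <= 0:
        raise ValidationError("wtp must be positive")
    comp = strategies[-1]
    rows = []
    for m in price_multipliers:
        scaled = _scale_drug_price(econ, comp.arm.first_line_drug, float(m))
        psa = run_psa(
            strategies, scaled, n_reps=n_reps, wtp_grid=np.array([wtp]),
            seed=seed, resample=resample,
        )
        rows.append(
            {
                "multiplier": float(m),
                "fraction_cost_effective": psa.prob_cost_effective(wtp, comp.name),
            }
        )
    return pd.DataFrame(rows)
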