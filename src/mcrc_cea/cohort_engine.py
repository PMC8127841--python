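"""Weekly-cycle three-state Markov cohort engine.

States: progression-free (PF), progressed disease (PD), dead.  PF and PD
are recurrent, death is absorbing, and the three weekly transition
probabilities (PF->PD, PF->dead, PD->dead) are constant.  The cohort
starts entirely progression-free and is propagated deterministically over
a 10-year horizon (520 weekly cycles by default).

PD occupancy is expanded by weeks-since-entry ("tunnel" accounting) so
that second-line therapy and palliative care can be costed and valued
differently by sojourn time, while the transition structure itself stays
memoryless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .param_model import (
    ArmSpec,
    ModelSettings,
    ParameterSet,
    Realization,
    UtilitySet,
    ValidationError,
)

__all__ = [
    "TransitionParams",
    "CohortTrace",
    "ArmOutcome",
    "closed_form_occupancy",
    "occupancy_curves",
    "run_trace",
    "discount_factor",
    "accumulate_qaly",
    "accumulate_cost",
    "evaluate_arm",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class TransitionParams:
    """The three constant weekly transition probabilities of the chain."""

    p_pf_pd: float
    p_pf_dead: float
    p_pd_dead: float

    def __post_init__(self) -> None:
        for fname in ("p_pf_pd", "p_pf_dead", "p_pd_dead"):
            v = getattr(self, fname)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{fname}={v} outside [0, 1]")
        if self.p_pf_pd + self.p_pf_dead > 1.0:
            raise ValidationError(
                "p_pf_pd + p_pf_dead exceeds 1: "
                f"{self.p_pf_pd} + {self.p_pf_dead}"
            )

    @property
    def q_pf_exit(self) -> float:
        """Weekly probability of leaving the progression-free state."""
        return self.p_pf_pd + self.p_pf_dead

    def matrix(self) -> np.ndarray:
        """Row-stochastic one-week transition matrix over (PF, PD, dead)."""
        a, b, c = self.p_pf_pd, self.p_pf_dead, self.p_pd_dead
        return np.array(
            [[1.0 - a - b, a, b], [0.0, 1.0 - c, c], [0.0, 0.0, 1.0]]
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "p_pf_pd": self.p_pf_pd,
            "p_pf_dead": self.p_pf_dead,
            "p_pd_dead": self.p_pd_dead,
        }

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "TransitionParams":
        return cls(float(m["p_pf_pd"]), float(m["p_pf_dead"]), float(m["p_pd_dead"]))


def closed_form_occupancy(params: TransitionParams, t: int) -> np.ndarray:
    """t-step occupancy (PF, PD, dead) from initial (1, 0, 0).

    Computed as a transition-matrix power; serves as the analytic oracle
    for :func:`run_trace` and for the survival likelihood.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    out = np.zeros(3)
    out[0] = 1.0
    return out @ np.linalg.matrix_power(params.matrix(), t)


def occupancy_curves(params: TransitionParams, t_max: int) -> np.ndarray:
    """Vectorised occupancy for t = 0..t_max, shape (t_max+1, 3).

    Uses the closed-form solution of the chain: PF(t) = (1-q)^t and
    PD(t) = a * ((1-c)^t - (1-q)^t) / (q - c), with the usual l'Hopital
    limit a*t*(1-q)^(t-1) when the two geometric rates coincide.
    """
    a, b, c = params.p_pf_pd, params.p_pf_dead, params.p_pd_dead
    q = a + b
    t = np.arange(t_max + 1, dtype=float)
    pf = (1.0 - q) ** t
    if abs(q - c) > 1e-9:
        pd_ = a * ((1.0 - c) ** t - (1.0 - q) ** t) / (q - c)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            pd_ = a * t * (1.0 - q) ** np.maximum(t - 1.0, 0.0)
        pd_[0] = 0.0
    pd_ = np.clip(pd_, 0.0, 1.0)
    dead = np.clip(1.0 - pf - pd_, 0.0, 1.0)
    return np.column_stack([pf, pd_, dead])


@dataclass
class CohortTrace:
    """Per-cycle state occupancy with PD expanded by weeks since entry.

    ``pd_by_age[t, j]`` is the cohort fraction that at cycle ``t`` has
    spent ``j + 1`` completed weeks in PD (the last column pools all
    sojourns at or beyond the tunnel cap).
    """

    pf: np.ndarray
    pd_by_age: np.ndarray
    dead: np.ndarray
    params: TransitionParams

    @property
    def horizon(self) -> int:
        return len(self.pf) - 1

    @property
    def pd_total(self) -> np.ndarray:
        return self.pd_by_age.sum(axis=1)

    def pd_split(self, second_line_duration: int) -> tuple[np.ndarray, np.ndarray]:
        """PD mass on second-line therapy (sojourn <= duration) vs palliative."""
        k = min(second_line_duration, self.pd_by_age.shape[1])
        return self.pd_by_age[:, :k].sum(axis=1), self.pd_by_age[:, k:].sum(axis=1)

    def life_years(self) -> float:
        """Undiscounted life expectancy over the horizon (years)."""
        alive = 1.0 - self.dead[:-1]
        return float(alive.sum() / WEEKS_PER_YEAR)

    def validate(self, atol: float = 1e-12) -> None:
        total = self.pf + self.pd_total + self.dead
        if np.max(np.abs(total - 1.0)) > atol:
            raise ValidationError("occupancy does not conserve mass")
        if np.any(np.diff(self.dead) < -atol):
            raise ValidationError("dead fraction must be non-decreasing")

    def to_frame(self, second_line_duration: int | None = None) -> pd.DataFrame:
        sl = second_line_duration or self.pd_by_age.shape[1]
        on_sl, pall = self.pd_split(sl)
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.pf)),
                "pf": self.pf,
                "pd_on_second_line": on_sl,
                "pd_palliative": pall,
                "dead": self.dead,
            }
        )


def run_trace(
    params: TransitionParams,
    horizon_weeks: int = 520,
    pd_tunnel_cap: int | None = None,
) -> CohortTrace:
    """Propagate the cohort for ``horizon_weeks`` weekly cycles.

    Within a cycle the PF cohort splits multinomially (progress, die,
    stay); there is no same-week PF->PD->dead chaining.
    """
    if horizon_weeks < 1:
        raise ValidationError("horizon must be at least one week")
    cap = pd_tunnel_cap if pd_tunnel_cap is not None else horizon_weeks
    if cap < 1:
        raise ValidationError("pd_tunnel_cap must be >= 1")
    a, b, c = params.p_pf_pd, params.p_pf_dead, params.p_pd_dead

    pf = np.zeros(horizon_weeks + 1)
    pd_by_age = np.zeros((horizon_weeks + 1, cap))
    dead = np.zeros(horizon_weeks + 1)
    pf[0] = 1.0

    for t in range(horizon_weeks):
        row = pd_by_age[t]
        nxt = pd_by_age[t + 1]
        nxt[1:] = row[:-1] * (1.0 - c)
        nxt[-1] += row[-1] * (1.0 - c)  # pooled tail
        nxt[0] = pf[t] * a
        pf[t + 1] = pf[t] * (1.0 - a - b)
        dead[t + 1] = dead[t] + pf[t] * b + row.sum() * c

    return CohortTrace(pf=pf, pd_by_age=pd_by_age, dead=dead, params=params)


def discount_factor(
    week: int | np.ndarray, annual_rate: float
) -> float | np.ndarray:
    """Continuous-compounding-free weekly discount: (1+r)^(-week/52)."""
    return (1.0 + annual_rate) ** (-np.asarray(week, dtype=float) / WEEKS_PER_YEAR)


def _state_series(
    trace: CohortTrace, second_line_duration: int, half_cycle: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle (pf, pd second line, pd palliative, discount week index)."""
    on_sl, pall = trace.pd_split(second_line_duration)
    h = trace.horizon
    if half_cycle:
        pf = 0.5 * (trace.pf[:-1] + trace.pf[1:])
        sl = 0.5 * (on_sl[:-1] + on_sl[1:])
        pl = 0.5 * (pall[:-1] + pall[1:])
    else:
        pf = trace.pf[:-1]
        sl = on_sl[:-1]
        pl = pall[:-1]
    weeks = np.arange(h)
    return pf, sl, pl, weeks


def accumulate_qaly(
    trace: CohortTrace,
    utilities: UtilitySet,
    ae_fraction: float,
    second_line_duration: int,
    annual_rate: float,
    ae_decrement_duration: int = 4,
    half_cycle: bool = False,
) -> float:
    """Discounted QALYs of a trace.

    Each week contributes (1/52) * discount * (state mass x state
    utility).  The grade 3-4 AE decrement ``d_ae`` applies to the
    AE-affected PF fraction for the first ``ae_decrement_duration`` weeks
    of treatment.
    """
    pf, sl, pl, weeks = _state_series(trace, second_line_duration, half_cycle)
    df = discount_factor(weeks, annual_rate)

    u_pf = np.full_like(pf, utilities.u_pf)
    dur = min(ae_decrement_duration, len(u_pf))
    u_pf[:dur] -= ae_fraction * utilities.d_ae
    per_week = pf * u_pf + sl * utilities.second_line + pl * utilities.palliative
    return float((df * per_week).sum() / WEEKS_PER_YEAR)


def accumulate_cost(
    trace: CohortTrace,
    arm: ArmSpec,
    econ: ParameterSet | Realization,
    second_line_duration: int,
    annual_rate: float,
    imaging_interval: int = 8,
    half_cycle: bool = False,
) -> dict[str, float]:
    """Discounted cost breakdown of a trace for one treatment arm.

    Per-administration charges are spread per week (cost / interval).
    Active-therapy states (PF on first line, PD on second line) accrue
    drug + backbone, per-visit administration charges (consultation +
    laboratory test), periodic imaging, and per-visit indirect costs
    (one day of patient time + one round trip).  PD beyond the
    second-line duration accrues palliative care at its per-day charge.
    AE management is a one-off expected cost at treatment start.
    Returns components ``drug, administration, procedures, indirect,
    palliative, ae`` plus their ``total``.
    """
    if isinstance(econ, ParameterSet):
        econ = econ.base_realization()
    pf, sl, pl, weeks = _state_series(trace, second_line_duration, half_cycle)
    df = discount_factor(weeks, annual_rate)

    v = econ.value
    fl_weekly = (v(arm.first_line_drug) + v(arm.backbone)) / arm.admin_interval
    sl_weekly = (
        v(arm.second_line_drug) + v(arm.second_line_backbone)
    ) / arm.second_line_interval
    visit_charge = v("consultation") + v("laboratory_test")
    indirect_visit = v("time_cost_per_day") + v("transportation_round_trip")

    drug = (df * (pf * fl_weekly + sl * sl_weekly)).sum()
    active_fl = df * pf / arm.admin_interval
    active_sl = df * sl / arm.second_line_interval
    administration = ((active_fl + active_sl) * visit_charge).sum()
    procedures = (
        (df * (pf + sl)).sum() * v("radiographic_test") / imaging_interval
    )
    indirect = ((active_fl + active_sl) * indirect_visit).sum()
    palliative = (df * pl).sum() * v("palliative_care_per_day") * 7.0

    ae = sum(
        econ.ae_probability(arm.name, a.name) * v(a.cost_name)
        for a in arm.ae_profile
    ) * trace.pf[0]

    out = {
        "drug": float(drug),
        "administration": float(administration),
        "procedures": float(procedures),
        "indirect": float(indirect),
        "palliative": float(palliative),
        "ae": float(ae),
    }
    out["total"] = float(sum(out.values()))
    return out


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted cost and QALYs for one strategy, with cost components."""

    arm: str
    discounted_cost: float
    discounted_qaly: float
    life_years: float
    undiscounted_qaly: float
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discounted_qaly > self.undiscounted_qaly + 1e-9:
            raise ValidationError("discounted QALY exceeds undiscounted QALY")
        comp_sum = sum(vv for k, vv in self.components.items() if k != "total")
        if self.components and abs(comp_sum - self.discounted_cost) > 1e-6:
            raise ValidationError("cost components do not sum to the total")


def evaluate_arm(
    params: TransitionParams,
    arm: ArmSpec,
    econ: ParameterSet | Realization,
    settings: ModelSettings,
    utilities: UtilitySet | None = None,
) -> ArmOutcome:
    """Run the cohort and value it: the end-to-end deterministic model."""
    realization = econ.base_realization() if isinstance(econ, ParameterSet) else econ
    if utilities is None:
        utilities = realization.utilities

    trace = run_trace(params, settings.horizon_weeks)
    ae_probs = {
        a.name: realization.ae_probability(arm.name, a.name) for a in arm.ae_profile
    }
    ae_fraction = arm.any_ae_probability(ae_probs)

    qaly = accumulate_qaly(
        trace,
        utilities,
        ae_fraction,
        settings.second_line_duration_weeks,
        settings.annual_discount_rate,
        ae_decrement_duration=settings.ae_decrement_duration_weeks,
        half_cycle=settings.half_cycle_correction,
    )
    qaly0 = accumulate_qaly(
        trace,
        utilities,
        ae_fraction,
        settings.second_line_duration_weeks,
        0.0,
        ae_decrement_duration=settings.ae_decrement_duration_weeks,
        half_cycle=settings.half_cycle_correction,
    )
    costs = accumulate_cost(
        trace,
        arm,
        realization,
        settings.second_line_duration_weeks,
        settings.annual_discount_rate,
        imaging_interval=settings.imaging_interval_weeks,
        half_cycle=settings.half_cycle_correction,
    )
    total = costs.pop("total")
    return ArmOutcome(
        arm=arm.name,
        discounted_cost=total,
        discounted_qaly=qaly,
        life_years=trace.life_years(),
        undiscounted_qaly=qaly0,
        components=costs,
    )
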