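"""Synthetic two-arm trial generator with known weekly transition truths.

Patient paths follow the same discrete-time three-state chain as the
cohort model: while progression-free a patient progresses or dies each
week; once progressed, a weekly death probability applies.  Censoring is
purely administrative: patients accrue uniformly over a configurable
window and share a common data cutoff.  The generator emits digitized-
style Kaplan-Meier curves (time/survival pairs) plus number-at-risk
tables per endpoint and arm, standing in for published trial figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort_engine import TransitionParams
from .param_model import ValidationError

__all__ = [
    "DigitizedKM",
    "TrialFixture",
    "simulate_cohort",
    "observed_endpoint",
    "km_estimate",
    "make_trial_fixture",
    "median_from_curve",
]

ENDPOINTS = ("PFS", "OS")


@dataclass(frozen=True)
class DigitizedKM:
    """A survival curve as read off a published figure.

    ``points`` are (time in weeks, survival probability) pairs starting at
    (0, 1); ``risk_table`` gives the number at risk at anchor times.
    """

    points: tuple[tuple[float, float], ...]
    risk_table: tuple[tuple[float, int], ...]
    n_total: int
    endpoint: str = "PFS"
    arm: str = ""

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if not self.points:
            raise ValidationError("curve needs at least one point")
        times = [t for t, _ in self.points]
        survs = [s for _, s in self.points]
        # the origin is (0, 1.0) except in the degenerate case of events
        # at time zero, which lower the value at the origin itself
        if times[0] != 0 or survs[0] > 1.0 or survs[0] < 0.0:
            raise ValidationError("curve must start at time 0 with survival <= 1")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("curve times must be strictly increasing")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValidationError("survival must be non-increasing")
        r_times = [t for t, _ in self.risk_table]
        r_n = [n for _, n in self.risk_table]
        if any(t2 <= t1 for t1, t2 in zip(r_times, r_times[1:])):
            raise ValidationError("risk-table times must be strictly increasing")
        if any(n2 > n1 for n1, n2 in zip(r_n, r_n[1:])):
            raise ValidationError("number at risk must be non-increasing")
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")

    def survival_at(self, t: float) -> float:
        """Step-function value of the curve at time ``t``."""
        s = 1.0
        for ti, si in self.points:
            if ti <= t:
                s = si
            else:
                break
        return s

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points])


def simulate_cohort(
    truth: TransitionParams,
    n: int,
    max_follow_up: int,
    accrual_weeks: int = 0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate ``n`` patient paths of the weekly chain.

    Returns one row per patient with ``pf_exit_week`` (inf if never),
    ``pf_exit_cause`` ('progression'/'death'), ``death_week`` (inf if
    alive at infinity) and the administrative ``censor_week`` implied by
    uniform accrual over ``accrual_weeks`` and a common cutoff at
    ``max_follow_up`` weeks after the first enrolment.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if accrual_weeks >= max_follow_up:
        raise ValidationError("accrual window must end before the data cutoff")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a, b, c = truth.p_pf_pd, truth.p_pf_dead, truth.p_pd_dead
    q = a + b

    if q > 0:
        pf_exit = rng.geometric(q, size=n).astype(float)
        cause_death = rng.random(n) < (b / q)
    else:
        pf_exit = np.full(n, np.inf)
        cause_death = np.zeros(n, dtype=bool)

    if c > 0:
        pd_sojourn = rng.geometric(c, size=n).astype(float)
    else:
        pd_sojourn = np.full(n, np.inf)

    death = np.where(cause_death, pf_exit, pf_exit + pd_sojourn)
    entry = rng.integers(0, accrual_weeks + 1, size=n) if accrual_weeks > 0 else np.zeros(n, dtype=int)
    censor = max_follow_up - entry

    cause = np.where(
        np.isinf(pf_exit), "", np.where(cause_death, "death", "progression")
    )
    return pd.DataFrame(
        {
            "pf_exit_week": pf_exit,
            "pf_exit_cause": cause,
            "death_week": death,
            "censor_week": censor.astype(int),
        }
    )


def observed_endpoint(paths: pd.DataFrame, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    """Observed (time, event) pairs for PFS or OS under the censoring scheme."""
    if endpoint == "PFS":
        raw = paths["pf_exit_week"].to_numpy()
    elif endpoint == "OS":
        raw = paths["death_week"].to_numpy()
    else:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    censor = paths["censor_week"].to_numpy()
    event = raw <= censor
    time = np.where(event, raw, censor).astype(int)
    return time, event.astype(int)


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    risk_times: Sequence[float],
    endpoint: str = "PFS",
    arm: str = "",
) -> DigitizedKM:
    """Product-limit estimate packaged as a digitized curve.

    ``risk_times`` are the anchor times at which the number at risk is
    reported (as in a published figure's risk table).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty input")
    if times.size != events.size:
        raise ValidationError("times and events must have equal length")
    if np.any(times < 0):
        raise ValidationError("times must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]

    points: list[tuple[float, float]] = [(0.0, 1.0)]
    prev = 1.0
    for t, s in sf.items():
        if t <= 0:
            if s < prev - 1e-12:  # events at time zero lower the origin
                points[0] = (0.0, float(s))
                prev = float(s)
            continue
        if s < prev - 1e-12:
            points.append((float(t), float(s)))
            prev = float(s)

    risk = tuple(
        (float(rt), int(np.sum(times >= rt))) for rt in risk_times
    )
    return DigitizedKM(
        points=tuple(points),
        risk_table=risk,
        n_total=int(times.size),
        endpoint=endpoint,
        arm=arm,
    )


def median_from_curve(curve: DigitizedKM) -> float:
    """First time at which the curve drops to 0.5 or below (inf if never)."""
    for t, s in curve.points:
        if s <= 0.5:
            return t
    return float("inf")


@dataclass
class TrialFixture:
    """Four digitized curves (PFS/OS x 2 arms) plus the generating truth."""

    curves: dict[tuple[str, str], DigitizedKM]  # keyed (arm, endpoint)
    truth: dict[str, TransitionParams]
    n_per_arm: int
    seed: int

    def curve(self, arm: str, endpoint: str) -> DigitizedKM:
        return self.curves[(arm, endpoint)]

    def to_csv(self, out_dir: str | Path) -> None:
        """Write curve/risk-table CSVs and a ground-truth JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve_rows, risk_rows = [], []
        for (arm, ep), c in self.curves.items():
            for t, s in c.points:
                curve_rows.append(
                    {"endpoint": ep, "arm": arm, "time_weeks": t, "survival": s}
                )
            for t, n in c.risk_table:
                risk_rows.append(
                    {"endpoint": ep, "arm": arm, "time_weeks": t, "n_at_risk": n}
                )
        pd.DataFrame(curve_rows).to_csv(out / "km_curves.csv", index=False)
        pd.DataFrame(risk_rows).to_csv(out / "risk_tables.csv", index=False)
        truth = {
            "n_per_arm": self.n_per_arm,
            "seed": self.seed,
            "transitions": {a: tp.as_dict() for a, tp in self.truth.items()},
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    @classmethod
    def from_csv(cls, out_dir: str | Path) -> "TrialFixture":
        out = Path(out_dir)
        curves_df = pd.read_csv(out / "km_curves.csv", float_precision="round_trip")
        risk_df = pd.read_csv(out / "risk_tables.csv")
        truth_doc = json.loads((out / "ground_truth.json").read_text())
        curves = {}
        for (arm, ep), grp in curves_df.groupby(["arm", "endpoint"], sort=False):
            rt = risk_df[(risk_df["arm"] == arm) & (risk_df["endpoint"] == ep)]
            n_total = int(rt["n_at_risk"].iloc[0]) if len(rt) else truth_doc["n_per_arm"]
            curves[(arm, ep)] = DigitizedKM(
                points=tuple(zip(grp["time_weeks"], grp["survival"])),
                risk_table=tuple(zip(rt["time_weeks"], rt["n_at_risk"].astype(int))),
                n_total=n_total,
                endpoint=ep,
                arm=arm,
            )
        truth = {
            a: TransitionParams.from_mapping(tp)
            for a, tp in truth_doc["transitions"].items()
        }
        return cls(
            curves=curves,
            truth=truth,
            n_per_arm=truth_doc["n_per_arm"],
            seed=truth_doc["seed"],
        )


def make_trial_fixture(
    truth: Mapping[str, TransitionParams],
    n_per_arm: int,
    seed: int = 0,
    accrual_weeks: int = 78,
    max_follow_up: int = 312,
    risk_interval: int = 26,
) -> TrialFixture:
    """Simulate a two-arm trial and package its digitized KM curves.

    The default follow-up and accrual mimic a modern first-line mCRC
    trial; risk-table anchors are reported every ``risk_interval`` weeks.
    """
    if n_per_arm < 1:
        raise ValidationError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    risk_times = np.arange(0, max_follow_up + 1, risk_interval)

    curves: dict[tuple[str, str], DigitizedKM] = {}
    for arm, tp in truth.items():
        paths = simulate_cohort(
            tp, n_per_arm, max_follow_up, accrual_weeks=accrual_weeks, seed=rng
        )
        for ep in ENDPOINTS:
            t, e = observed_endpoint(paths, ep)
            curves[(arm, ep)] = km_estimate(t, e, risk_times, endpoint=ep, arm=arm)
    return TrialFixture(
        curves=curves, truth=dict(truth), n_per_arm=n_per_arm, seed=seed
    )
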