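"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Given a published survival curve (time/survival pairs) and its
number-at-risk table, the interval algorithm reconstructs per-patient
(time, event) records whose product-limit estimate matches the input
curve and whose number at risk matches the risk table exactly at every
anchor.  Within an anchor interval, censoring is assumed uniform; event
counts are obtained by inverting the KM steps with integer rounding, and
ties within a week are resolved events-before-censorings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .param_model import ValidationError
from .synthetic_trial import DigitizedKM, km_estimate

__all__ = ["PseudoIPD", "reconstruct_ipd", "km_of", "sup_norm_distance"]


@dataclass
class PseudoIPD:
    """Reconstructed per-patient records: times (weeks) and event flags."""

    times: np.ndarray
    events: np.ndarray
    endpoint: str = "PFS"
    arm: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.size != self.events.size:
            raise ValidationError("times and events must have equal length")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": self.arm,
                "endpoint": self.endpoint,
                "time_weeks": self.times,
                "event": self.events,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PseudoIPD":
        arm = str(df["arm"].iloc[0]) if len(df) else ""
        ep = str(df["endpoint"].iloc[0]) if len(df) else "PFS"
        return cls(
            times=df["time_weeks"].to_numpy(),
            events=df["event"].to_numpy(),
            endpoint=ep,
            arm=arm,
        )


def _iround(x: float) -> int:
    """Deterministic half-up rounding."""
    return int(np.floor(x + 0.5))


def _walk_interval(
    pts: list[tuple[float, float]],
    n_start: int,
    s_start: float,
    censor_weeks: np.ndarray,
) -> tuple[list[tuple[float, int]], float, int]:
    """Assign event counts to curve steps given censor placements.

    Censors at week ``w`` are processed after events at ``w`` (ties:
    events before censorings).  Returns (events per time, running KM
    value, n remaining at interval end).
    """
    n = n_start
    s_prev = s_start
    used = 0
    out: list[tuple[float, int]] = []
    for t_i, s_i in pts:
        before = int(np.sum(censor_weeks < t_i)) - used
        n -= before
        used += before
        if n <= 0 or s_prev <= 0:
            out.append((t_i, 0))
            continue
        d = _iround(n * (1.0 - s_i / s_prev))
        d = max(0, min(d, n))
        if d > 0:
            s_prev *= 1.0 - d / n
            n -= d
        out.append((t_i, d))
    n -= int(censor_weeks.size) - used
    return out, s_prev, n


def _uniform_censors(c: int, lo: float, hi: float) -> np.ndarray:
    """``c`` censor weeks spread uniformly over [lo, hi), integer-rounded."""
    if c <= 0:
        return np.zeros(0)
    raw = lo + (np.arange(1, c + 1) / (c + 1)) * (hi - lo)
    return np.clip(np.floor(raw + 0.5), lo, max(lo, hi - 1))


def reconstruct_ipd(curve: DigitizedKM, total_events: int | None = None) -> PseudoIPD:
    """Invert a digitized KM curve + risk table into pseudo-IPD.

    Within each inter-anchor interval the number of censorings is solved
    iteratively so that the reconstructed number at risk hits the next
    anchor exactly while the KM steps reproduce the input survival
    ratios.  If ``total_events`` is given, the final interval's event
    count is adjusted to honor it.  When the risk table has fewer than
    two anchors a single-interval fallback is used (censoring only after
    the last event) and flagged in the output metadata.
    """
    anchors = list(curve.risk_table)
    if anchors and anchors[0][0] != 0:
        anchors.insert(0, (0.0, curve.n_total))
    fallback = len(anchors) < 2

    pts_all = [(t, s) for t, s in curve.points if t > 0]
    last_time = curve.points[-1][0]

    event_times: list[float] = []
    censor_times: list[float] = []
    s_run = 1.0

    if fallback:
        n = curve.n_total
        ev, s_run, n = _walk_interval(pts_all, n, s_run, np.zeros(0))
        for t, d in ev:
            event_times.extend([t] * d)
        if total_events is not None:
            event_times = _adjust_total(event_times, total_events, last_time)
            n = curve.n_total - len(event_times)
        censor_times.extend([last_time] * n)
        meta = {"fallback_single_interval": True, "anchors": ()}
        return PseudoIPD(
            times=np.array(event_times + censor_times),
            events=np.array([1] * len(event_times) + [0] * len(censor_times)),
            endpoint=curve.endpoint,
            arm=curve.arm,
            meta=meta,
        )

    n_cur = int(anchors[0][1])
    if n_cur != curve.n_total:
        raise ValidationError("risk table at time 0 must equal n_total")

    for k in range(len(anchors) - 1):
        tau0, _ = anchors[k]
        tau1, n_next = anchors[k + 1]
        n_next = int(n_next)
        pts = [(t, s) for t, s in pts_all if tau0 <= t < tau1]

        # fixed-point iteration on the interval censor count, starting
        # from the no-censoring solution
        c = 0
        seen: set[int] = set()
        for _ in range(40):
            cw = _uniform_censors(c, tau0, tau1)
            ev, s_end, n_end = _walk_interval(pts, n_cur, s_run, cw)
            d_total = sum(d for _, d in ev)
            c_new = n_cur - n_next - d_total
            c_new = max(0, min(c_new, n_cur))
            if c_new == c or c_new in seen:
                c = c_new
                break
            seen.add(c)
            c = c_new
        cw = _uniform_censors(c, tau0, tau1)
        ev, s_end, n_end = _walk_interval(pts, n_cur, s_run, cw)
        d_total = sum(d for _, d in ev)

        # force the anchor exactly: trim events if even c=0 overshoots
        overshoot = (d_total + c) - (n_cur - n_next)
        if overshoot > 0:
            trimmed = []
            for t, d in reversed(ev):
                take = min(d, overshoot)
                trimmed.append((t, d - take))
                overshoot -= take
            ev = list(reversed(trimmed))
            d_total = sum(d for _, d in ev)
            c = n_cur - n_next - d_total
            cw = _uniform_censors(c, tau0, tau1)
            # recompute running KM with trimmed events
            _, s_end, _ = _walk_interval(pts, n_cur, s_run, cw)
            s_end = _km_value(ev, cw, n_cur, s_run)

        for t, d in ev:
            event_times.extend([t] * d)
        censor_times.extend(cw.tolist())
        s_run = s_end
        n_cur = n_next

    # residual tail beyond the last anchor
    tau_last = anchors[-1][0]
    pts_tail = [(t, s) for t, s in pts_all if t >= tau_last]
    ev, s_run, n_cur = _walk_interval(pts_tail, n_cur, s_run, np.zeros(0))
    for t, d in ev:
        event_times.extend([t] * d)

    if total_events is not None:
        event_times = _adjust_total(event_times, total_events, max(last_time, tau_last))
        n_cur = curve.n_total - len(event_times) - len(censor_times)
        if n_cur < 0:
            raise ValidationError("total_events inconsistent with risk table")
    if n_cur > 0:
        censor_times.extend([max(last_time, tau_last)] * n_cur)

    meta = {
        "fallback_single_interval": False,
        "anchors": tuple((t, int(n)) for t, n in anchors),
    }
    return PseudoIPD(
        times=np.array(event_times + censor_times),
        events=np.array([1] * len(event_times) + [0] * len(censor_times)),
        endpoint=curve.endpoint,
        arm=curve.arm,
        meta=meta,
    )


def _km_value(
    ev: list[tuple[float, int]], cw: np.ndarray, n_start: int, s_start: float
) -> float:
    n, s = n_start, s_start
    used = 0
    for t, d in ev:
        before = int(np.sum(cw < t)) - used
        n -= before
        used += before
        if d > 0 and n > 0:
            s *= 1.0 - d / n
            n -= d
    return s


def _adjust_total(
    event_times: list[float], total_events: int, last_time: float
) -> list[float]:
    """Trim or pad the reconstructed events to honor a reported total."""
    ev = sorted(event_times)
    if len(ev) > total_events:
        return ev[:total_events]
    ev.extend([last_time] * (total_events - len(ev)))
    return ev


def km_of(ipd: PseudoIPD, risk_times: Iterable[float] | None = None) -> DigitizedKM:
    """Product-limit curve of pseudo data (the round-trip validator)."""
    if len(ipd) == 0:
        raise ValidationError("empty pseudo-IPD")
    if risk_times is None:
        anchors = ipd.meta.get("anchors") or ()
        risk_times = [t for t, _ in anchors] or [0.0]
    return km_estimate(
        ipd.times, ipd.events, risk_times, endpoint=ipd.endpoint, arm=ipd.arm
    )


def sup_norm_distance(a: DigitizedKM, b: DigitizedKM, t_max: float | None = None) -> float:
    """Max absolute difference of two step curves on the integer-week grid."""
    if t_max is None:
        t_max = min(a.points[-1][0], b.points[-1][0])
    grid = np.arange(0, int(t_max) + 1)
    sa = np.array([a.survival_at(t) for t in grid])
    sb = np.array([b.survival_at(t) for t in grid])
    return float(np.max(np.abs(sa - sb)))
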