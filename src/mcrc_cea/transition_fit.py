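"""Posterior estimation of the weekly transition probabilities.

The three-state chain implies a discrete-time likelihood for the
reconstructed PFS and OS records: PFS exit times are geometric with
weekly rate q = p_pf_pd + p_pf_dead, and OS death times follow the
death-state occupancy increments of the chain.  The two pseudo-datasets
are treated as independent (reconstruction from separately published
curves loses the patient linkage).

Sampling is a Metropolis-Hastings random walk on logit-transformed
coordinates with flat priors over the constrained probability region
(p_pf_pd + p_pf_dead <= 1); the proposal scale is adapted during burn-in
only, so the kept chain is a valid MH chain, reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_engine import TransitionParams, occupancy_curves
from .km_reconstruct import PseudoIPD
from .param_model import ValidationError
from .synthetic_trial import DigitizedKM

__all__ = [
    "TransitionParams",
    "PosteriorDraws",
    "CalibrationBand",
    "loglik",
    "mcmc_fit",
    "calibration_curves",
]

COORDS = ("p_pf_pd", "p_pf_dead", "p_pd_dead")


def _counts(times: np.ndarray, flags: np.ndarray, want: int) -> tuple[np.ndarray, np.ndarray]:
    t = times[flags == want].astype(int)
    if t.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    uniq, cnt = np.unique(t, return_counts=True)
    return uniq, cnt


@dataclass
class _SuffStats:
    """Sufficient statistics of the paired PFS/OS pseudo-datasets."""

    pfs_ev_t: np.ndarray
    pfs_ev_n: np.ndarray
    pfs_ce_t: np.ndarray
    pfs_ce_n: np.ndarray
    os_ev_t: np.ndarray
    os_ev_n: np.ndarray
    os_ce_t: np.ndarray
    os_ce_n: np.ndarray
    t_max: int

    @classmethod
    def build(cls, pfs: PseudoIPD, os: PseudoIPD) -> "_SuffStats":
        if len(pfs) == 0 or len(os) == 0:
            raise ValidationError("pseudo-IPD must be non-empty")
        pe_t, pe_n = _counts(pfs.times, pfs.events, 1)
        pc_t, pc_n = _counts(pfs.times, pfs.events, 0)
        oe_t, oe_n = _counts(os.times, os.events, 1)
        oc_t, oc_n = _counts(os.times, os.events, 0)
        t_max = int(
            max(
                [arr.max(initial=0) for arr in (pe_t, pc_t, oe_t, oc_t)]
            )
        )
        return cls(pe_t, pe_n, pc_t, pc_n, oe_t, oe_n, oc_t, oc_n, t_max)

    def loglik(self, a: float, b: float, c: float) -> float:
        q = a + b
        if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0 and 0.0 <= c <= 1.0 and q <= 1.0):
            return -np.inf

        ll = 0.0
        # PFS: geometric exit from the progression-free state
        if self.pfs_ev_t.size:
            if q <= 0.0 or np.any(self.pfs_ev_t < 1):
                return -np.inf
            if q >= 1.0:
                if np.any(self.pfs_ev_t > 1):
                    return -np.inf
            else:
                ll += float(
                    self.pfs_ev_n.sum() * np.log(q)
                    + (self.pfs_ev_n * (self.pfs_ev_t - 1)).sum() * np.log1p(-q)
                )
        if self.pfs_ce_t.size:
            tw = float((self.pfs_ce_n * self.pfs_ce_t).sum())
            if tw > 0:
                if q >= 1.0:
                    return -np.inf
                ll += tw * np.log1p(-q)

        # OS: increments of the death-state occupancy D(t)
        if self.os_ev_t.size or self.os_ce_t.size:
            occ = occupancy_curves(TransitionParams(a, b, c), self.t_max)
            dead = occ[:, 2]
            if self.os_ev_t.size:
                if np.any(self.os_ev_t < 1):
                    return -np.inf
                inc = dead[self.os_ev_t] - dead[self.os_ev_t - 1]
                if np.any(inc <= 0.0):
                    return -np.inf
                ll += float((self.os_ev_n * np.log(inc)).sum())
            if self.os_ce_t.size:
                surv = 1.0 - dead[self.os_ce_t]
                if np.any(surv <= 0.0):
                    return -np.inf
                ll += float((self.os_ce_n * np.log(surv)).sum())
        return ll


def loglik(params: TransitionParams, pfs: PseudoIPD, os: PseudoIPD) -> float:
    """Joint log-likelihood of PFS and OS pseudo-data under the chain.

    Impossible data under ``params`` yield ``-inf`` rather than raising.
    """
    ss = _SuffStats.build(pfs, os)
    return ss.loglik(params.p_pf_pd, params.p_pf_dead, params.p_pd_dead)


@dataclass
class PosteriorDraws:
    """Kept MCMC draws of the transition probabilities plus diagnostics."""

    draws: np.ndarray  # (n, 3) columns = COORDS
    acceptance_rate: float
    ess: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.draws.shape[0])

    def __getitem__(self, i: int) -> TransitionParams:
        return TransitionParams(*self.draws[i])

    def median(self) -> TransitionParams:
        return TransitionParams(*np.median(self.draws, axis=0))

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        lo = np.quantile(self.draws, (1 - level) / 2, axis=0)
        hi = np.quantile(self.draws, 1 - (1 - level) / 2, axis=0)
        return lo, hi

    @property
    def flags(self) -> list[str]:
        out = []
        if self.acceptance_rate > 0.9:
            out.append("acceptance rate above 0.9 (proposal scale too small)")
        if self.acceptance_rate < 0.05:
            out.append("acceptance rate below 0.05 (proposal scale too large)")
        if np.any(self.ess < 100):
            out.append("effective sample size below 100 for some coordinate")
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(COORDS))
        df.insert(0, "draw_index", np.arange(len(df)))
        return df

    def diagnostics(self) -> dict:
        return {
            "acceptance_rate": float(self.acceptance_rate),
            "ess": {k: float(v) for k, v in zip(COORDS, self.ess)},
            "n_draws": len(self),
            "flags": self.flags,
            **self.meta,
        }


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    n = x.size
    if n < 4 or np.all(x == x[0]):
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _init_point(ss: _SuffStats) -> np.ndarray:
    """Crude moment estimates to start the chain."""
    pfs_events = ss.pfs_ev_n.sum()
    pfs_weeks = float((ss.pfs_ev_n * ss.pfs_ev_t).sum() + (ss.pfs_ce_n * ss.pfs_ce_t).sum())
    q0 = pfs_events / pfs_weeks if pfs_weeks > 0 else 0.02
    q0 = float(np.clip(q0, 1e-4, 0.5))
    os_events = ss.os_ev_n.sum()
    os_weeks = float((ss.os_ev_n * ss.os_ev_t).sum() + (ss.os_ce_n * ss.os_ce_t).sum())
    c0 = os_events / os_weeks if os_weeks > 0 else 0.02
    c0 = float(np.clip(c0, 1e-4, 0.5))
    return np.array([0.85 * q0, 0.15 * q0, c0])


def mcmc_fit(
    pfs: PseudoIPD,
    os: PseudoIPD,
    iterations: int = 52_000,
    burn_in: int = 2_000,
    thinning: int = 5,
    proposal_scale: float | np.ndarray = 0.12,
    seed: int = 0,
    adapt: bool = True,
) -> PosteriorDraws:
    """Metropolis-Hastings random walk over the transition probabilities.

    Flat priors on the valid region; Gaussian proposals on the logit
    scale with per-coordinate scales.  Kept draws number
    ``(iterations - burn_in) / thinning``.
    """
    if iterations <= burn_in:
        raise ValidationError("iterations must exceed burn_in")
    ss = _SuffStats.build(pfs, os)
    if ss.pfs_ev_t.size == 0 and ss.os_ev_t.size == 0:
        raise ValidationError("degenerate data: no events in either endpoint")

    rng = np.random.default_rng(seed)
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), (3,)).copy()

    p = _init_point(ss)
    x = _logit(p)

    def logpost(xv: np.ndarray) -> float:
        pv = _expit(xv)
        ll = ss.loglik(pv[0], pv[1], pv[2])
        if not np.isfinite(ll):
            return -np.inf
        # Jacobian of the logit transform => flat prior on the probabilities
        return ll + float(np.sum(np.log(pv) + np.log1p(-pv)))

    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValidationError("could not initialise the chain at a finite posterior")

    kept = []
    accepted_post = 0
    post_iters = 0
    acc_window = 0
    for it in range(iterations):
        prop = x + scale * rng.standard_normal(3)
        lp_prop = logpost(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
        if it < burn_in:
            acc_window += accept
            if adapt and (it + 1) % 50 == 0:
                rate = acc_window / 50.0
                scale *= np.exp(0.7 * (rate - 0.3))
                acc_window = 0
        else:
            post_iters += 1
            accepted_post += accept
            if (it - burn_in) % thinning == thinning - 1:
                kept.append(_expit(x))

    draws = np.array(kept)
    ess = np.array([_ess(draws[:, j]) for j in range(3)])
    return PosteriorDraws(
        draws=draws,
        acceptance_rate=accepted_post / max(post_iters, 1),
        ess=ess,
        seed=seed,
        meta={
            "iterations": iterations,
            "burn_in": burn_in,
            "thinning": thinning,
            "final_scale": scale.tolist(),
        },
    )


@dataclass
class CalibrationBand:
    """Pointwise posterior band of an analytic survival curve."""

    time: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    endpoint: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_weeks": self.time,
                "endpoint": self.endpoint,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def covers(
        self,
        curve: DigitizedKM,
        times: np.ndarray | None = None,
        atol: float | None = None,
    ) -> float:
        """Fraction of anchor times at which the curve lies inside the band.

        ``atol`` widens the band by an absolute allowance; the default is
        one KM step (1/n), the discretization error of a digitized curve.
        """
        if times is None:
            times = np.array([t for t, _ in curve.risk_table])
        if atol is None:
            atol = 1.0 / curve.n_total
        times = times[times <= self.time[-1]]
        inside = 0
        for t in times:
            s = curve.survival_at(t)
            i = int(t)
            if self.lower[i] - atol <= s <= self.upper[i] + atol:
                inside += 1
        return inside / max(len(times), 1)


def _survival_matrix(draws: np.ndarray, horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Analytic PFS and OS survival for every draw, shape (n, horizon+1)."""
    a = draws[:, 0:1]
    b = draws[:, 1:2]
    c = draws[:, 2:3]
    q = a + b
    t = np.arange(horizon + 1, dtype=float)[None, :]
    s_pfs = (1.0 - q) ** t
    denom = q - c
    safe = np.abs(denom) > 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        pd_gen = a * ((1.0 - c) ** t - (1.0 - q) ** t) / np.where(safe, denom, 1.0)
        pd_lim = a * t * (1.0 - q) ** np.maximum(t - 1.0, 0.0)
    pd_ = np.where(safe, pd_gen, pd_lim)
    s_os = np.clip(s_pfs + pd_, 0.0, 1.0)
    return s_pfs, s_os


def calibration_curves(
    draws: PosteriorDraws, horizon: int, max_draws: int = 4_000
) -> tuple[CalibrationBand, CalibrationBand]:
    """Posterior median and 95% pointwise bands for PFS and OS survival."""
    if len(draws) == 0:
        raise ValidationError("no posterior draws")
    d = draws.draws
    if len(d) > max_draws:
        idx = np.linspace(0, len(d) - 1, max_draws).astype(int)
        d = d[idx]
    s_pfs, s_os = _survival_matrix(d, horizon)
    t = np.arange(horizon + 1)
    bands = []
    for s, ep in ((s_pfs, "PFS"), (s_os, "OS")):
        qs = np.percentile(s, [50, 2.5, 97.5], axis=0)
        bands.append(
            CalibrationBand(time=t, median=qs[0], lower=qs[1], upper=qs[2], endpoint=ep)
        )
    return bands[0], bands[1]
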