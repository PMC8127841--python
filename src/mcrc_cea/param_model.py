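"""Economic and health-utility parameters of the decision model.

Every monetary and utility input carries a base value, a one-way
sensitivity range (low/high) and a probabilistic-sensitivity-analysis
distribution: gamma(shape, scale) for costs, beta(alpha, beta) for
utilities and probabilities.  Drug acquisition costs are stored per
administration, already scaled to a reference patient (55.6 kg,
1.6 m^2 body surface area); no dose arithmetic is performed here.

The canonical on-disk representation is a single YAML document keyed by
row names, with a mirrored flat-CSV export for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DistributionSpec",
    "EconParam",
    "UtilitySet",
    "AdverseEvent",
    "ArmSpec",
    "ModelSettings",
    "ParameterSet",
    "Realization",
    "ParameterError",
    "MissingParameterError",
    "ValidationError",
    "dist_mean",
    "sample_param",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]

FAMILIES = ("gamma", "beta")
UNITS = ("per_administration", "per_day", "per_round_trip", "per_episode", "unitless")

#: the four utility rows every parameter set must provide
UTILITY_NAMES = (
    "progression_free",
    "progressed_relative",
    "palliative_relative",
    "ae_decrement",
)

#: cost rows the cohort engine reads directly (drugs are referenced via arms)
ENGINE_COST_NAMES = (
    "laboratory_test",
    "radiographic_test",
    "consultation",
    "palliative_care_per_day",
    "time_cost_per_day",
    "transportation_round_trip",
)


class ParameterError(Exception):
    """Base class for parameter-table problems."""


class MissingParameterError(ParameterError, KeyError):
    """A required named parameter is absent from the configuration."""


class ValidationError(ParameterError, ValueError):
    """A parameter violates its declared invariants."""


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution: ``gamma(shape, scale)`` or ``beta(a, b)``."""

    family: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if not (self.a > 0 and self.b > 0):
            raise ValidationError(
                f"distribution parameters must be positive, got ({self.a}, {self.b})"
            )

    def mean(self) -> float:
        if self.family == "gamma":
            return self.a * self.b
        return self.a / (self.a + self.b)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        return rng.beta(self.a, self.b, size=size)

    def ppf(self, q: float) -> float:
        if self.family == "gamma":
            return float(stats.gamma.ppf(q, self.a, scale=self.b))
        return float(stats.beta.ppf(q, self.a, self.b))


def dist_mean(spec: DistributionSpec) -> float:
    """Analytic mean of a sampling distribution (``a*b`` or ``a/(a+b)``)."""
    return spec.mean()


def sample_param(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw from ``spec``; reproducible under a fixed generator state."""
    return spec.sample(rng, size=size)


@dataclass(frozen=True)
class EconParam:
    """One row of the parameter table.

    ``base`` is the deterministic value, ``low``/``high`` the one-way
    sensitivity extremes, ``dist`` the PSA distribution.  Beta-distributed
    rows are utilities or probabilities and must live in [0, 1].
    """

    name: str
    base: float
    low: float
    high: float
    dist: DistributionSpec
    unit: str = "per_administration"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"{self.name}: unknown unit {self.unit!r}")
        if self.base < 0:
            raise ValidationError(f"{self.name}: base value must be >= 0")
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.name}: require low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.dist.family == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValidationError(
                    f"{self.name}: beta-distributed values must lie in [0, 1]"
                )
        if self.dist.family == "gamma" and self.unit == "unitless":
            raise ValidationError(
                f"{self.name}: gamma distributions are reserved for cost parameters"
            )


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities of the three-state model.

    ``u_pf`` is the progression-free (first-line) utility; progressed and
    palliative states are expressed relative to it (``r_pd``, ``r_pall``);
    ``d_ae`` is the temporary decrement for grade 3-4 adverse events.
    """

    u_pf: float = 0.72
    r_pd: float = 0.88
    r_pall: float = 0.50
    d_ae: float = 0.07

    def __post_init__(self) -> None:
        for fname in ("u_pf", "r_pd", "r_pall", "d_ae"):
            v = getattr(self, fname)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"utility {fname}={v} outside [0, 1]")
        if self.u_pf - self.d_ae < 0:
            raise ValidationError("AE decrement exceeds progression-free utility")

    @property
    def second_line(self) -> float:
        """Utility while progressed and on second-line therapy (u_pf * r_pd)."""
        return self.u_pf * self.r_pd

    @property
    def palliative(self) -> float:
        """Utility while progressed and on palliative care (u_pf * r_pall)."""
        return self.u_pf * self.r_pall


@dataclass(frozen=True)
class AdverseEvent:
    """A grade 3-4 adverse event: incidence, its beta spread, and the name
    of the management-cost row in the parameter table."""

    name: str
    probability: float
    prob_dist: DistributionSpec
    cost_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"AE {self.name}: probability outside [0, 1]")
        if self.prob_dist.family != "beta":
            raise ValidationError(f"AE {self.name}: incidence must be beta-distributed")


@dataclass(frozen=True)
class ArmSpec:
    """A treatment strategy: first-line biologic + chemotherapy backbone,
    the crossover second-line regimen, and the arm's AE profile."""

    name: str
    first_line_drug: str
    admin_interval: int
    backbone: str
    second_line_drug: str
    second_line_backbone: str
    second_line_interval: int = 2
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.admin_interval not in (2, 3):
            raise ValidationError(
                f"arm {self.name}: admin_interval must be 2 or 3 weeks"
            )
        if self.second_line_interval not in (2, 3):
            raise ValidationError(
                f"arm {self.name}: second_line_interval must be 2 or 3 weeks"
            )

    def any_ae_probability(self, probs: Mapping[str, float] | None = None) -> float:
        """Probability of at least one grade 3-4 AE, assuming independence."""
        p_none = 1.0
        for ae in self.ae_profile:
            p = ae.probability if probs is None else probs[ae.name]
            p_none *= 1.0 - p
        return 1.0 - p_none


@dataclass(frozen=True)
class ModelSettings:
    """Global model constants: weekly cycles over a 10-year horizon,
    3%/year discounting, WTP at twice GDP per capita (US$97,832)."""

    horizon_weeks: int = 520
    annual_discount_rate: float = 0.03
    wtp: float = 97_832.0
    second_line_duration_weeks: int = 52
    ae_decrement_duration_weeks: int = 4
    imaging_interval_weeks: int = 8
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_weeks < 1:
            raise ValidationError("horizon must be at least one week")
        if self.annual_discount_rate < 0:
            raise ValidationError("discount rate must be >= 0")


@dataclass(frozen=True)
class Realization:
    """One joint draw (or the base-case assignment) of every economic and
    utility parameter, plus per-arm AE incidences."""

    values: Mapping[str, float]
    utilities: UtilitySet
    ae_probs: Mapping[tuple[str, str], float]

    def value(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise MissingParameterError(name) from None

    def ae_probability(self, arm: str, ae: str) -> float:
        return self.ae_probs[(arm, ae)]


@dataclass(frozen=True)
class ParameterSet:
    """The full parameter table plus arm definitions and model settings."""

    params: Mapping[str, EconParam]
    arms: Mapping[str, ArmSpec]
    settings: ModelSettings = field(default_factory=ModelSettings)
    populations: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict
    )
    trial: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in UTILITY_NAMES + ENGINE_COST_NAMES:
            if name not in self.params:
                raise MissingParameterError(name)
        for arm in self.arms.values():
            for ref in (
                arm.first_line_drug,
                arm.backbone,
                arm.second_line_drug,
                arm.second_line_backbone,
            ):
                if ref not in self.params:
                    raise MissingParameterError(ref)
            for ae in arm.ae_profile:
                if ae.cost_name not in self.params:
                    raise MissingParameterError(ae.cost_name)

    def __getitem__(self, name: str) -> EconParam:
        try:
            return self.params[name]
        except KeyError:
            raise MissingParameterError(name) from None

    def utilities(self) -> UtilitySet:
        return UtilitySet(
            u_pf=self["progression_free"].base,
            r_pd=self["progressed_relative"].base,
            r_pall=self["palliative_relative"].base,
            d_ae=self["ae_decrement"].base,
        )

    # -- realizations -------------------------------------------------

    def base_realization(self) -> Realization:
        values = {name: p.base for name, p in self.params.items()}
        ae = {
            (arm.name, a.name): a.probability
            for arm in self.arms.values()
            for a in arm.ae_profile
        }
        return Realization(values=values, utilities=self.utilities(), ae_probs=ae)

    def sample_realization(self, rng: np.random.Generator) -> Realization:
        """Jointly resample every parameter from its PSA distribution.

        Iteration order is the (insertion-ordered) table order, so a fixed
        generator state yields an identical realization.
        """
        values = {
            name: float(sample_param(p.dist, rng)) for name, p in self.params.items()
        }
        utilities = UtilitySet(
            u_pf=values["progression_free"],
            r_pd=values["progressed_relative"],
            r_pall=values["palliative_relative"],
            d_ae=values["ae_decrement"],
        )
        ae = {
            (arm.name, a.name): float(sample_param(a.prob_dist, rng))
            for arm in self.arms.values()
            for a in arm.ae_profile
        }
        return Realization(values=values, utilities=utilities, ae_probs=ae)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        def p_row(p: EconParam) -> dict:
            return {
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "family": p.dist.family,
                "a": p.dist.a,
                "b": p.dist.b,
                "unit": p.unit,
            }

        return {
            "parameters": {name: p_row(p) for name, p in self.params.items()},
            "arms": {
                arm.name: {
                    "first_line_drug": arm.first_line_drug,
                    "admin_interval_weeks": arm.admin_interval,
                    "backbone": arm.backbone,
                    "second_line_drug": arm.second_line_drug,
                    "second_line_backbone": arm.second_line_backbone,
                    "second_line_interval_weeks": arm.second_line_interval,
                    "ae_profile": {
                        ae.name: {
                            "probability": ae.probability,
                            "a": ae.prob_dist.a,
                            "b": ae.prob_dist.b,
                            "cost": ae.cost_name,
                        }
                        for ae in arm.ae_profile
                    },
                }
                for arm in self.arms.values()
            },
            "settings": {
                "horizon_weeks": self.settings.horizon_weeks,
                "annual_discount_rate": self.settings.annual_discount_rate,
                "wtp": self.settings.wtp,
                "second_line_duration_weeks": self.settings.second_line_duration_weeks,
                "ae_decrement_duration_weeks": self.settings.ae_decrement_duration_weeks,
                "imaging_interval_weeks": self.settings.imaging_interval_weeks,
                "half_cycle_correction": self.settings.half_cycle_correction,
            },
            "populations": {
                pop: {arm: dict(tp) for arm, tp in arms.items()}
                for pop, arms in self.populations.items()
            },
            "trial": dict(self.trial),
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat mirror of the parameter table (one row per named parameter)."""
        rows = [
            {
                "name": p.name,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "family": p.dist.family,
                "a": p.dist.a,
                "b": p.dist.b,
                "unit": p.unit,
            }
            for p in self.params.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _param_from_row(name: str, row: Mapping) -> EconParam:
    missing = {"base", "low", "high", "family", "a", "b"} - set(row)
    if missing:
        raise MissingParameterError(f"{name}: missing fields {sorted(missing)}")
    return EconParam(
        name=name,
        base=float(row["base"]),
        low=float(row["low"]),
        high=float(row["high"]),
        dist=DistributionSpec(str(row["family"]), float(row["a"]), float(row["b"])),
        unit=str(row.get("unit", "per_administration")),
    )


def from_dict(doc: Mapping) -> ParameterSet:
    if "parameters" not in doc:
        raise MissingParameterError("parameters")
    params = {
        name: _param_from_row(name, row) for name, row in doc["parameters"].items()
    }
    arms = {}
    for arm_name, a in doc.get("arms", {}).items():
        ae_profile = tuple(
            AdverseEvent(
                name=ae_name,
                probability=float(ae["probability"]),
                prob_dist=DistributionSpec("beta", float(ae["a"]), float(ae["b"])),
                cost_name=str(ae["cost"]),
            )
            for ae_name, ae in a.get("ae_profile", {}).items()
        )
        arms[arm_name] = ArmSpec(
            name=arm_name,
            first_line_drug=str(a["first_line_drug"]),
            admin_interval=int(a["admin_interval_weeks"]),
            backbone=str(a["backbone"]),
            second_line_drug=str(a["second_line_drug"]),
            second_line_backbone=str(a["second_line_backbone"]),
            second_line_interval=int(a.get("second_line_interval_weeks", 2)),
            ae_profile=ae_profile,
        )
    s = doc.get("settings", {})
    settings = ModelSettings(
        horizon_weeks=int(s.get("horizon_weeks", 520)),
        annual_discount_rate=float(s.get("annual_discount_rate", 0.03)),
        wtp=float(s.get("wtp", 97_832.0)),
        second_line_duration_weeks=int(s.get("second_line_duration_weeks", 52)),
        ae_decrement_duration_weeks=int(s.get("ae_decrement_duration_weeks", 4)),
        imaging_interval_weeks=int(s.get("imaging_interval_weeks", 8)),
        half_cycle_correction=bool(s.get("half_cycle_correction", False)),
    )
    return ParameterSet(
        params=params,
        arms=arms,
        settings=settings,
        populations=doc.get("populations", {}),
        trial=doc.get("trial", {}),
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter configuration from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{path}: not a mapping document")
    return from_dict(doc)


def save_parameters(pset: ParameterSet, path: str | Path) -> None:
    """Write a parameter set back to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(pset.to_dict(), fh, sort_keys=False)


def default_parameters() -> ParameterSet:
    """The parameter set shipped with the package (the published table)."""
    ref = resources.files("mcrc_cea").joinpath("data/default_config.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)
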