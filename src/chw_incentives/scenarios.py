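"""The scenario engine: per-incentive monthly earnings under the four
perfect/actual worker × household models, with category and grand totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .catalog import Category, IncentiveDefinition, Scaling
from .errors import ConfigurationError, ContractError, SchemaError
from .incidence import Catchment, DemographicRates, beneficiary_incidence

__all__ = [
    "Mode",
    "RoundingMode",
    "ScenarioSpec",
    "RateSet",
    "EarningsProjection",
    "effective_rate",
    "effective_incidence",
    "project_incentive",
    "project_all",
    "convert_currency",
    "sweep_catchments",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (halves away from zero), used for presentation
    and for the published one-decimal incidence chains."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class Mode(str, Enum):
    PERFECT = "PERFECT"
    ACTUAL = "ACTUAL"


class RoundingMode(str, Enum):
    #: keep every intermediate at double precision (default)
    FULL_PRECISION = "FULL_PRECISION"
    #: round the effective incidence of actual-mode population incentives to
    #: one decimal before multiplying by the amount, reproducing the printed
    #: worked-example chains (e.g. 1.36 × 0.66 -> 0.9 -> 0.9 × 300 = 270)
    PAPER_ROUNDING = "PAPER_ROUNDING"


_SHORT_CODES = {
    "pp": (Mode.PERFECT, Mode.PERFECT),
    "pa": (Mode.PERFECT, Mode.ACTUAL),
    "ap": (Mode.ACTUAL, Mode.PERFECT),
    "aa": (Mode.ACTUAL, Mode.ACTUAL),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four projection scenarios.

    ``chw_mode`` governs worker actions, ``household_mode`` household
    behaviors; the two-letter code puts the worker first (``pa`` = perfect
    worker, actual household).
    """

    chw_mode: Mode
    household_mode: Mode

    @classmethod
    def parse(cls, code: str) -> "ScenarioSpec":
        try:
            chw, hh = _SHORT_CODES[code.lower()]
        except KeyError:
            raise ContractError(f"unknown scenario code {code!r}; expected one of pp/pa/ap/aa")
        return cls(chw, hh)

    @property
    def code(self) -> str:
        return ("p" if self.chw_mode == Mode.PERFECT else "a") + (
            "p" if self.household_mode == Mode.PERFECT else "a"
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        label = {Mode.PERFECT: "perfect", Mode.ACTUAL: "actual"}
        return f"{label[self.chw_mode]} worker–{label[self.household_mode]} household"


ALL_SCENARIOS = tuple(ScenarioSpec.parse(c) for c in ("pp", "pa", "ap", "aa"))


@dataclass
class RateSet(Mapping[str, float]):
    """Named probabilities for worker actions and conditional household
    behaviors, each tagged with its provenance (survey name or SYNTHETIC)."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {k!r} must be a probability in [0, 1], got {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateSet":
        df = pd.read_csv(path)
        if not {"key", "value"}.issubset(df.columns):
            raise SchemaError(f"{path}: rate CSV needs columns key,value[,provenance]")
        values = dict(zip(df["key"].astype(str), df["value"].astype(float)))
        prov = (
            dict(zip(df["key"].astype(str), df["provenance"].astype(str)))
            if "provenance" in df.columns
            else {k: "UNKNOWN" for k in values}
        )
        return cls(values, prov)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "key": list(self.values),
                "value": list(self.values.values()),
                "provenance": [self.provenance.get(k, "UNKNOWN") for k in self.values],
            }
        ).to_csv(path, index=False)


def effective_rate(mode: Mode, keys: Sequence[str], rates: Mapping[str, float]) -> float:
    """Joint completion probability for a set of rate keys under one mode.

    PERFECT mode is the identity (probability 1). ACTUAL mode multiplies the
    named rates, treating the actions/behaviors as independent. An empty key
    list yields 1 in both modes.
    """
    if mode == Mode.PERFECT or not keys:
        return 1.0
    product = 1.0
    for key in keys:
        try:
            product *= rates[key]
        except KeyError:
            raise ConfigurationError(f"rate key {key!r} missing from rate set") from None
    return product


def effective_incidence(
    incentive: IncentiveDefinition,
    scenario: ScenarioSpec,
    rates: Mapping[str, float],
    demo: DemographicRates,
    catchment: Catchment,
    rounding_mode: RoundingMode = RoundingMode.FULL_PRECISION,
) -> float:
    """Claimable events per month: beneficiary incidence × worker action
    rate × household behavior rate.

    In PAPER_ROUNDING mode the chain is rounded to one decimal before the
    amount multiplication — but only for population-scaled incentives where
    an actual rate below 1 entered the chain, which is exactly where the
    published worked examples round (perfect chains and fixed routine
    activities are printed unrounded).
    """
    base = beneficiary_incidence(incentive, demo, catchment)
    a = effective_rate(scenario.chw_mode, incentive.action_keys, rates)
    h = effective_rate(scenario.household_mode, incentive.behavior_keys, rates)
    eff = base * a * h
    if (
        rounding_mode == RoundingMode.PAPER_ROUNDING
        and incentive.scaling == Scaling.POPULATION
        and a * h < 1.0
    ):
        eff = round_half_up(eff, 1)
    return eff


def project_incentive(
    incentive: IncentiveDefinition,
    scenario: ScenarioSpec,
    rates: Mapping[str, float],
    demo: DemographicRates,
    catchment: Catchment,
    rounding_mode: RoundingMode = RoundingMode.FULL_PRECISION,
) -> float:
    """Projected monthly earnings (INR) from one incentive in one scenario.

    Incentives with no behavior keys are unaffected by the household mode;
    incentives with no action keys are unaffected by the worker mode.
    """
    eff = effective_incidence(incentive, scenario, rates, demo, catchment, rounding_mode)
    return eff * incentive.amount


@dataclass
class EarningsProjection:
    """Per-incentive, per-category, and total monthly earnings for one
    scenario and catchment."""

    scenario: ScenarioSpec
    catchment: Catchment
    per_incentive: dict[str, float]
    per_category: dict[Category, float]
    total: float
    rounding_mode: RoundingMode = RoundingMode.FULL_PRECISION

    def to_frame(self, catalog: Iterable[IncentiveDefinition] | None = None) -> pd.DataFrame:
        cat_of = {d.id: d.category.value for d in catalog} if catalog else {}
        return pd.DataFrame(
            {
                "incentive_id": list(self.per_incentive),
                "category": [cat_of.get(i) for i in self.per_incentive],
                "scenario": self.scenario.code,
                "monthly_inr": list(self.per_incentive.values()),
            }
        )


def project_all(
    catalog: Sequence[IncentiveDefinition],
    scenario: ScenarioSpec,
    rates: Mapping[str, float],
    demo: DemographicRates,
    catchment: Catchment = Catchment(),
    rounding_mode: RoundingMode = RoundingMode.FULL_PRECISION,
) -> EarningsProjection:
    """Project the whole catalog under one scenario.

    Category subtotals are sums of their member incentives and the grand
    total is the sum of the subtotals; everything is deterministic in the
    inputs.
    """
    per_incentive: dict[str, float] = {}
    per_category: dict[Category, float] = {c: 0.0 for c in Category}
    for d in catalog:
        value = project_incentive(d, scenario, rates, demo, catchment, rounding_mode)
        per_incentive[d.id] = value
        per_category[d.category] += value
    return EarningsProjection(
        scenario=scenario,
        catchment=catchment,
        per_incentive=per_incentive,
        per_category=per_category,
        total=float(sum(per_category.values())),
        rounding_mode=rounding_mode,
    )


def convert_currency(amount_inr: float, inr_per_usd: float) -> int:
    """INR -> USD at a fixed configurable rate, presentation-rounded to
    whole dollars (the published conversions use slightly different implied
    rates across statements, so the rate is always explicit)."""
    if inr_per_usd <= 0:
        raise ContractError(f"conversion rate must be > 0, got {inr_per_usd}")
    return int(round_half_up(amount_inr / inr_per_usd))


def sweep_catchments(
    catalog: Sequence[IncentiveDefinition],
    rates: Mapping[str, float],
    demo: DemographicRates,
    populations: Sequence[float],
    scenarios: Sequence[ScenarioSpec] = ALL_SCENARIOS,
    rounding_mode: RoundingMode = RoundingMode.FULL_PRECISION,
) -> pd.DataFrame:
    """Scenario totals over a grid of catchment sizes (population-scaled
    incentives grow linearly; fixed routine incentives stay flat)."""
    rows = []
    for pop in populations:
        for scen in scenarios:
            proj = project_all(catalog, scen, rates, demo, Catchment(pop), rounding_mode)
            row = {"population": pop, "scenario": scen.code, "total_inr": proj.total}
            row.update({f"cat_{c.value}": v for c, v in proj.per_category.items()})
            rows.append(row)
    return pd.DataFrame(rows)
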