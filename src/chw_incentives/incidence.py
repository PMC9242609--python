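"""Beneficiary incidence: annual demographic rates -> monthly events per catchment."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .catalog import ROUTINE_BASIS, IncentiveDefinition, Scaling
from .errors import ConfigurationError, ContractError, SchemaError

__all__ = [
    "RateBasis",
    "DemographicRate",
    "DemographicRates",
    "Catchment",
    "monthly_incidence",
    "beneficiary_incidence",
]

MONTHS_PER_YEAR = 12.0


class RateBasis(str, Enum):
    PER_1000_PER_YEAR = "PER_1000_PER_YEAR"
    PROPORTION = "PROPORTION"


@dataclass(frozen=True)
class DemographicRate:
    value: float
    basis: RateBasis
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.basis == RateBasis.PER_1000_PER_YEAR and self.value < 0:
            raise ValueError(f"PER_1000_PER_YEAR rate must be >= 0, got {self.value}")
        if self.basis == RateBasis.PROPORTION and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"PROPORTION rate must be in [0, 1], got {self.value}")


@dataclass
class DemographicRates(Mapping[str, DemographicRate]):
    """Named table of demographic rates (crude birth rate, mortality rates,
    population proportions, ...)."""

    entries: dict[str, DemographicRate] = field(default_factory=dict)

    def __getitem__(self, key: str) -> DemographicRate:
        return self.entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DemographicRates":
        df = pd.read_csv(path)
        required = {"key", "value", "basis"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"{path}: demographic-rates CSV needs columns {sorted(required)}, "
                f"found {sorted(df.columns)}"
            )
        entries = {}
        for row in df.to_dict(orient="records"):
            try:
                basis = RateBasis(row["basis"])
            except ValueError as exc:
                raise SchemaError(f"{path}: key {row['key']!r}: {exc}") from exc
            entries[str(row["key"])] = DemographicRate(
                value=float(row["value"]),
                basis=basis,
                description=str(row.get("description", "") or ""),
                source=str(row.get("source", "") or ""),
            )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "key": k,
                    "value": e.value,
                    "basis": e.basis.value,
                    "description": e.description,
                    "source": e.source,
                }
                for k, e in self.entries.items()
            ]
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class Catchment:
    """The population one worker serves (the analysis default is 1,000)."""

    population: float = 1000.0

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"catchment population must be > 0, got {self.population}")


def monthly_incidence(rate: DemographicRate, catchment: Catchment) -> float:
    """Events per month in the catchment for an annual per-1,000 rate.

    ``value × (population / 1000) / 12`` at full precision; e.g. a crude
    birth rate of 27.28 in a catchment of 1,000 gives 2.2733 pregnant
    women per month.
    """
    if rate.basis != RateBasis.PER_1000_PER_YEAR:
        raise ContractError(
            f"monthly_incidence requires a PER_1000_PER_YEAR rate, got {rate.basis.value}"
        )
    return rate.value * (catchment.population / 1000.0) / MONTHS_PER_YEAR


def beneficiary_incidence(
    incentive: IncentiveDefinition, demo: DemographicRates, catchment: Catchment
) -> float:
    """Monthly beneficiary incidence for one incentive.

    ROUTINE incentives have exactly one event per month regardless of
    catchment size. PER_1000_PER_YEAR bases convert annually and scale with
    population; PROPORTION bases multiply population directly and then apply
    the incentive's per-month event conversion (default one event per
    beneficiary per year).
    """
    if incentive.incidence_basis == ROUTINE_BASIS:
        return 1.0
    try:
        entry = demo[incentive.incidence_basis]
    except KeyError:
        raise ConfigurationError(
            f"incentive {incentive.id!r}: incidence basis {incentive.incidence_basis!r} "
            f"not found in demographic rates (available: {sorted(demo)})"
        ) from None
    if entry.basis == RateBasis.PER_1000_PER_YEAR:
        base = monthly_incidence(entry, catchment)
    else:
        per_month = incentive.monthly_events_per_beneficiary
        if per_month is None:
            per_month = 1.0 / MONTHS_PER_YEAR
        base = entry.value * catchment.population * per_month
    if incentive.scaling != Scaling.POPULATION:
        raise ContractError(
            f"incentive {incentive.id!r}: FIXED scaling with non-ROUTINE basis"
        )
    return base
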