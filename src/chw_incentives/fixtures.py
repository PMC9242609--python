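"""Bundled fixture inputs: the 23-incentive catalog, demographic rates,
rate set, observed payments, published scenario totals, and synthetic series
distributions.

Amounts and rates flagged as placeholders stand in for unpublished
supplementary values; the handful of published amounts (institutional
delivery 300, first-year immunization 100, monthly recordkeeping 100) and
rates (0.6, 0.66, 0.75) are verbatim.
"""

from __future__ import annotations

import json
from contextlib import ExitStack
from importlib import resources
from pathlib import Path

from .catalog import IncentiveDefinition, ObservedPayments, load_catalog
from .incidence import DemographicRates
from .relaxation import SeriesDistribution, load_series_distributions
from .scenarios import RateSet

__all__ = [
    "fixture_path",
    "fixture_catalog",
    "fixture_demographic_rates",
    "fixture_rates",
    "fixture_observed_payments",
    "fixture_scenario_totals",
    "fixture_series_distributions",
]

_stack = ExitStack()


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    ref = resources.files("chw_incentives") / "data" / name
    return _stack.enter_context(resources.as_file(ref))


def fixture_catalog() -> list[IncentiveDefinition]:
    return load_catalog(fixture_path("catalog.json"))


def fixture_demographic_rates() -> DemographicRates:
    return DemographicRates.from_csv(fixture_path("demographic_rates.csv"))


def fixture_rates() -> RateSet:
    return RateSet.from_csv(fixture_path("rates.csv"))


def fixture_observed_payments() -> ObservedPayments:
    return ObservedPayments.from_csv(fixture_path("observed_payments.csv"))


def fixture_scenario_totals() -> dict[str, float]:
    """Published grand totals {pp, pa, aa, observed_total}; the inputs behind
    them are not public, so only arithmetic identities are checked on them."""
    payload = json.loads(fixture_path("scenario_totals.json").read_text())
    return {k: float(v) for k, v in payload.items() if k != "comment"}


def fixture_series_distributions() -> dict[str, SeriesDistribution]:
    return load_series_distributions(fixture_path("series_distributions.csv"))
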