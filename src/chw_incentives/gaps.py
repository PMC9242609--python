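"""Gap decomposition: differences among scenario totals and observed payments.

Three headline statistics:

* design gap       = potential (PP) − achievable (PA)
* lost opportunity = achievable (PA) − modeled actual (AA)
* implementation gap (overpayment when positive) = observed − modeled actual
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .catalog import Category, ObservedPayments
from .errors import ContractError
from .scenarios import EarningsProjection, round_half_up

__all__ = [
    "GapReport",
    "lost_opportunity",
    "overpayment",
    "category_shares",
    "gap_report",
]


def lost_opportunity(pa_total: float, aa_total: float) -> float:
    """Achievable minus modeled-actual earnings — what workers forgo by not
    completing the actions under their control."""
    gap = pa_total - aa_total
    if gap < 0:
        warnings.warn(
            f"negative lost opportunity ({gap:.2f}): modeled actual exceeds achievable",
            stacklevel=2,
        )
    return gap


def overpayment(observed: float, aa_total: float) -> float:
    """Observed payments minus modeled-actual earnings (signed; positive
    suggests payment for unmet criteria)."""
    return observed - aa_total


def category_shares(
    values: Mapping[Category, float] | Mapping[str, float],
) -> tuple[dict, dict]:
    """Percent share of each category in the total.

    Returns ``(rounded, unrounded)`` maps; rounded values are
    nearest-integer percents for presentation, unrounded retain full
    precision (and sum to exactly 100).
    """
    total = float(sum(values.values()))
    if total <= 0:
        raise ContractError(f"category shares need a positive total, got {total}")
    unrounded = {k: 100.0 * v / total for k, v in values.items()}
    rounded = {k: int(round_half_up(s)) for k, s in unrounded.items()}
    return rounded, unrounded


@dataclass
class GapReport:
    """Gap decomposition for one scope (the grand total or one category)."""

    scope: str
    potential: float  # PP total
    achievable: float  # PA total
    modeled_actual: float  # AA total
    observed: float | None = None
    design_gap: float = field(init=False)
    lost_opportunity: float = field(init=False)
    implementation_gap: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.design_gap = self.potential - self.achievable
        self.lost_opportunity = lost_opportunity(self.achievable, self.modeled_actual)
        self.implementation_gap = (
            overpayment(self.observed, self.modeled_actual) if self.observed is not None else None
        )

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "potential": self.potential,
            "achievable": self.achievable,
            "modeled_actual": self.modeled_actual,
            "observed": self.observed,
            "design_gap": self.design_gap,
            "lost_opportunity": self.lost_opportunity,
            "implementation_gap": self.implementation_gap,
        }


@dataclass
class GapReportBundle:
    """Total-scope report, per-category reports, and category share tables."""

    total: GapReport
    per_category: dict[Category, GapReport]
    potential_shares: dict[Category, int]
    observed_shares: dict[Category, int] | None

    def to_frame(self) -> pd.DataFrame:
        rows = [self.total.to_dict()] + [r.to_dict() for r in self.per_category.values()]
        return pd.DataFrame(rows)


def gap_report(
    projections: Mapping[str, EarningsProjection],
    observed: ObservedPayments | None = None,
) -> GapReportBundle:
    """Build the full decomposition from the four scenario projections
    (keyed by code ``pp``/``pa``/``ap``/``aa``) and optional observed
    payments.

    All projections must share a catchment; gap statistics are additive, so
    each per-category statistic sums to the total-scope statistic.
    """
    for code in ("pp", "pa", "aa"):
        if code not in projections:
            raise ContractError(f"gap_report needs projections for pp, pa and aa (missing {code!r})")
    pops = {p.catchment.population for p in projections.values()}
    if len(pops) != 1:
        raise ContractError(f"projections use different catchments: {sorted(pops)}")
    pp, pa, aa = projections["pp"], projections["pa"], projections["aa"]

    total = GapReport(
        scope="TOTAL",
        potential=pp.total,
        achievable=pa.total,
        modeled_actual=aa.total,
        observed=observed.total if observed is not None else None,
    )
    per_category = {
        cat: GapReport(
            scope=cat.value,
            potential=pp.per_category.get(cat, 0.0),
            achievable=pa.per_category.get(cat, 0.0),
            modeled_actual=aa.per_category.get(cat, 0.0),
            observed=observed.per_category.get(cat, 0.0) if observed is not None else None,
        )
        for cat in Category
    }
    potential_shares, _ = category_shares(pp.per_category)
    observed_shares = None
    if observed is not None and observed.total > 0:
        observed_shares, _ = category_shares(observed.per_category)
    return GapReportBundle(
        total=total,
        per_category=per_category,
        potential_shares=potential_shares,
        observed_shares=observed_shares,
    )
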