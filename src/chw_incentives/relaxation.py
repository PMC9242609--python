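"""Relaxed completion thresholds for series incentives.

Series incentives pay a single lump sum for completing a set of component
activities. Observed payments often exceed the strict-rule expectation; this
module models payment under a relaxed threshold k (pay the full amount when
at least k of the K components are completed) and finds the threshold that
best explains an observed mean monthly payment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import IncentiveDefinition
from .errors import ContractError, SchemaError

__all__ = [
    "SeriesDistribution",
    "RelaxationResult",
    "expected_series_payment",
    "fit_relaxation",
    "load_series_distributions",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class SeriesDistribution:
    """Distribution over completion counts 0..K for one series incentive."""

    incentive_id: str
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size < 2:
            raise ValueError("series distribution needs at least counts 0 and 1")
        if (p < -_PROB_TOL).any():
            raise ValueError(f"{self.incentive_id}: negative completion probabilities")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.incentive_id}: completion probabilities sum to {p.sum():.6f}, not 1"
            )

    @property
    def n_components(self) -> int:
        return len(self.probabilities) - 1

    def survival(self, k: int) -> float:
        """P(completion count >= k)."""
        if not 0 <= k <= self.n_components:
            raise ContractError(f"k={k} outside [0, {self.n_components}]")
        return float(np.sum(self.probabilities[k:]))

    @classmethod
    def from_counts(cls, incentive_id: str, counts: Sequence[int], n_components: int) -> "SeriesDistribution":
        """Empirical distribution from observed completion counts."""
        arr = np.asarray(counts, dtype=int)
        if arr.size == 0:
            raise ContractError("cannot build a series distribution from zero counts")
        hist = np.bincount(arr, minlength=n_components + 1).astype(float)
        return cls(incentive_id, tuple(hist / hist.sum()))


@dataclass
class RelaxationResult:
    """Best-matching relaxed threshold for one incentive, with the full
    candidate table retained for reporting."""

    incentive_id: str
    fitted_threshold: int
    expected_payment: float
    observed_payment: float
    discrepancy: float
    candidates: list[tuple[int, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.candidates, columns=["threshold", "expected_payment"]).assign(
            incentive_id=self.incentive_id,
            observed_payment=self.observed_payment,
            fitted=lambda df: df["threshold"] == self.fitted_threshold,
        )


def _check_series(incentive: IncentiveDefinition, dist: SeriesDistribution) -> None:
    if incentive.series is None:
        raise ContractError(f"incentive {incentive.id!r} has no series specification")
    if dist.n_components != incentive.series.n_components:
        raise ContractError(
            f"distribution spans counts 0..{dist.n_components} but incentive "
            f"{incentive.id!r} has {incentive.series.n_components} components"
        )


def expected_series_payment(
    incentive: IncentiveDefinition,
    dist: SeriesDistribution,
    threshold: int,
    incidence: float,
) -> float:
    """Expected monthly payment when the lump sum is paid for completing at
    least ``threshold`` components: ``incidence × P(count >= k) × amount``.

    At ``threshold == full_threshold`` this is the designed (strict)
    expectation. ``incidence`` is claim-eligible beneficiary events per month
    (already scaled by any worker contact rate).
    """
    _check_series(incentive, dist)
    if not 1 <= threshold <= incentive.series.n_components:
        raise ContractError(
            f"threshold {threshold} outside [1, {incentive.series.n_components}]"
        )
    if incidence < 0:
        raise ContractError(f"incidence must be >= 0, got {incidence}")
    return incidence * dist.survival(threshold) * incentive.amount


def fit_relaxation(
    incentive: IncentiveDefinition,
    dist: SeriesDistribution,
    incidence: float,
    observed: float,
) -> RelaxationResult:
    """Find the completion threshold whose expected payment is closest to the
    observed mean monthly payment.

    Candidates are k = 1..full_threshold; ties break toward the largest
    (least relaxed) k, i.e. the explanation closest to the designed rule.
    """
    _check_series(incentive, dist)
    if observed < 0:
        raise ContractError(f"observed payment must be >= 0, got {observed}")
    k_full = incentive.series.full_threshold
    candidates = [
        (k, expected_series_payment(incentive, dist, k, incidence)) for k in range(1, k_full + 1)
    ]
    # scan from the largest k so that equal discrepancies keep the larger k
    best_k, best_expected = k_full, candidates[-1][1]
    best_gap = abs(best_expected - observed)
    for k, expected in reversed(candidates[:-1]):
        gap = abs(expected - observed)
        if gap < best_gap:
            best_k, best_expected, best_gap = k, expected, gap
    return RelaxationResult(
        incentive_id=incentive.id,
        fitted_threshold=best_k,
        expected_payment=best_expected,
        observed_payment=observed,
        discrepancy=best_gap,
        candidates=candidates,
    )


def load_series_distributions(path: str | Path) -> dict[str, SeriesDistribution]:
    """Read CSV (incentive_id, count, probability) into distributions."""
    df = pd.read_csv(path)
    required = {"incentive_id", "count", "probability"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: series CSV needs columns {sorted(required)}")
    out: dict[str, SeriesDistribution] = {}
    for inc_id, group in df.groupby("incentive_id", sort=False):
        group = group.sort_values("count")
        counts = group["count"].to_numpy()
        if not np.array_equal(counts, np.arange(len(counts))):
            raise SchemaError(f"{path}: {inc_id}: counts must be contiguous 0..K")
        out[str(inc_id)] = SeriesDistribution(str(inc_id), tuple(group["probability"].astype(float)))
    return out
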