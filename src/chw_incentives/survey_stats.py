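"""Descriptive survey statistics: rate estimation from household microdata
and worker questionnaire summaries (awareness, payment delays, claim
experience)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ContractError
from .scenarios import RateSet
from .synthetic_data import RECENCY_LABELS

__all__ = [
    "SurveySummary",
    "estimate_rates",
    "claim_experience_summary",
    "awareness_summary",
]

#: below this denominator the large-sample interval is replaced by the exact one
_SMALL_N = 40


@dataclass(frozen=True)
class SurveySummary:
    """One estimated proportion with its binomial 95% interval."""

    item: str
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, item: str, numerator: int, denominator: int) -> "SurveySummary":
        if denominator <= 0:
            raise ContractError(f"{item}: denominator must be > 0")
        # Wilson score interval for n >= 40, Clopper-Pearson below; both
        # always contain the point estimate
        method = "wilson" if denominator >= _SMALL_N else "beta"
        low, high = proportion_confint(numerator, denominator, alpha=0.05, method=method)
        return cls(item, numerator, denominator, numerator / denominator, float(low), float(high))


def estimate_rates(households: pd.DataFrame, catalog=None) -> RateSet:
    """Re-estimate the worker action and conditional household behavior
    rates from long-format household microdata.

    Action rates are the share of eligible beneficiaries with the contact
    flag set. Behavior rates are conditional: the share with the outcome
    among beneficiaries whose required contacts all occurred. A behavior key
    with an empty conditioning stratum is omitted with a warning rather than
    reported as 0/0.

    When a catalog is given, the behavior rate of a series incentive is
    estimated from its completion counts as P(count >= full_threshold) among
    contacted beneficiaries (the completion count is the behavior there).
    """
    if households.empty:
        raise ContractError("cannot estimate rates from empty microdata")
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}

    actions = households[households["kind"] == "action"]
    for key, grp in actions.groupby("key"):
        values[key] = float(grp["value"].mean())
        provenance[key] = "SYNTHETIC:estimated"

    # beneficiaries whose every required contact occurred
    contacted = (
        actions.groupby("beneficiary_id")["value"].min().rename("contacted").astype(bool)
    )
    behaviors = households[households["kind"] == "behavior"]
    for key, grp in behaviors.groupby("key"):
        merged = grp.join(contacted, on="beneficiary_id")
        # beneficiaries with no action rows require no contact
        stratum = merged[merged["contacted"].fillna(True).astype(bool)]
        if stratum.empty:
            warnings.warn(
                f"behavior rate {key!r} omitted: no beneficiary with full contact",
                stacklevel=2,
            )
            continue
        values[key] = float(stratum["value"].mean())
        provenance[key] = "SYNTHETIC:estimated"

    if catalog is not None:
        series_rows = households[households["kind"] == "series"]
        for d in catalog:
            if d.series is None or len(d.behavior_keys) != 1:
                continue
            key = d.behavior_keys[0]
            if key in values:
                continue
            grp = series_rows[series_rows["incentive_id"] == d.id].join(
                contacted, on="beneficiary_id"
            )
            stratum = grp[grp["contacted"].fillna(True).astype(bool)]
            if stratum.empty:
                warnings.warn(
                    f"series behavior rate {key!r} omitted: no contacted beneficiaries",
                    stacklevel=2,
                )
                continue
            values[key] = float((stratum["value"] >= d.series.full_threshold).mean())
            provenance[key] = "SYNTHETIC:estimated-from-series"
    return RateSet(values, provenance)


def claim_experience_summary(chws: pd.DataFrame, items: list[str] | None = None) -> list[SurveySummary]:
    """One proportion summary per claim-experience item (payment difficulty,
    delays, unknown breakup, partial payment, ...). Categorical payment
    recency expands to one summary per category, which sum to 100%."""
    if chws.empty:
        raise ContractError("no questionnaire responses present")
    if items is None:
        skip = {"chw_id", "payment_recency"}
        items = [
            c
            for c in chws.columns
            if c not in skip and not c.startswith(("aware_", "amount_answer_"))
        ]
    summaries = [
        SurveySummary.from_counts(item, int(chws[item].sum()), int(chws[item].notna().sum()))
        for item in items
    ]
    if "payment_recency" in chws.columns:
        n = int(chws["payment_recency"].notna().sum())
        for label in RECENCY_LABELS:
            k = int((chws["payment_recency"] == label).sum())
            summaries.append(SurveySummary.from_counts(f"payment_recency_{label}", k, n))
    return summaries


def awareness_summary(chws: pd.DataFrame, correct_amounts: dict[str, float] | None = None) -> list[SurveySummary]:
    """Per incentive item: share aware, share answering the exact amount,
    and the modal wrong answer with its share.

    An amount answer from a respondent flagged unaware violates the
    exact-implies-aware invariant and raises a validation error.
    """
    aware_cols = [c for c in chws.columns if c.startswith("aware_")]
    if not aware_cols:
        raise ContractError("no awareness items present")
    correct_amounts = correct_amounts or {}
    summaries: list[SurveySummary] = []
    for col in aware_cols:
        item = col[len("aware_"):]
        aware = chws[col].astype(int)
        n = len(aware)
        answers = chws.get(f"amount_answer_{item}")
        summaries.append(SurveySummary.from_counts(f"{item}_aware", int(aware.sum()), n))
        if answers is None:
            continue
        if (answers.notna() & (aware == 0)).any():
            raise ContractError(
                f"{item}: amount answers present for unaware respondents "
                "(exact-amount-correct must imply aware)"
            )
        correct = correct_amounts.get(item)
        if correct is None and answers.notna().any():
            # default: most common answer is not assumed correct; require caller
            # to name it, else fall back to the smallest distinct answer
            correct = float(np.nanmin(answers.to_numpy(dtype=float)))
        exact = int((answers == correct).sum())
        summaries.append(SurveySummary.from_counts(f"{item}_exact_amount", exact, n))
        wrong = answers[answers.notna() & (answers != correct)]
        if not wrong.empty:
            modal = wrong.mode().iloc[0]
            summaries.append(
                SurveySummary.from_counts(
                    f"{item}_modal_wrong_{modal:g}", int((wrong == modal).sum()), n
                )
            )
    return summaries
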