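"""Synthetic linked household + worker survey microdata and payment records.

Generates, under a fixed seed, the statistical structure the analysis
assumes: per-worker catchments with beneficiary incidence driven by
demographic rates, Bernoulli worker-contact indicators, household behaviors
conditional on contact (plus non-claimable background behavior without
contact), series-completion counts, payment records under strict or
partial-completion rules, and worker questionnaire responses at stated
proportions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .catalog import Category, IncentiveDefinition, ObservedPayments, ROUTINE_BASIS
from .errors import ConfigurationError
from .incidence import Catchment, DemographicRates, beneficiary_incidence
from .scenarios import RateSet

__all__ = [
    "AwarenessScenario",
    "GeneratorConfig",
    "SyntheticData",
    "generate",
    "write_microdata",
    "read_microdata",
    "observed_from_payments",
    "mean_monthly_payment",
]

#: strict payment rule sentinel — pay only at the designed full threshold
STRICT = "STRICT"

RECENCY_LABELS = ("last_month", "two_months_ago", "earlier")


class AwarenessScenario(BaseModel):
    """Optional awareness generator reproducing the striking published
    pattern: everyone knows the incentive exists, few know its amount, and
    the modal wrong answer is the bundled series amount."""

    item: str = "institutional_delivery"
    correct_amount: float = 300.0
    aware_p: float = 1.0
    exact_p: float = 0.30
    modal_wrong_amount: float = 600.0
    modal_wrong_p: float = 0.68
    other_wrong_amount: float = 500.0

    @model_validator(mode="after")
    def _mass_fits(self) -> "AwarenessScenario":
        for name in ("aware_p", "exact_p", "modal_wrong_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exact_p + self.modal_wrong_p > self.aware_p + 1e-12:
            raise ValueError(
                "exact_p + modal_wrong_p cannot exceed aware_p "
                "(answers are only elicited from aware respondents)"
            )
        return self


class GeneratorConfig(BaseModel):
    """Everything the generator needs besides the catalog, demographic
    rates, and true rate set. A fixed seed gives byte-identical output."""

    seed: int
    n_chw: int = Field(gt=0)
    months: int = Field(default=12, gt=0)
    catchment_population: float = Field(default=1000.0, gt=0)
    #: no-contact ("background") household behavior rates, keyed like the
    #: behavior rate keys; behaviors occurring without contact are never paid
    background_rates: dict[str, float] = Field(default_factory=dict)
    default_background_rate: float = 0.0
    #: per series incentive: completion-count distribution given contact,
    #: probabilities for counts 0..K
    series_params: dict[str, list[float]] = Field(default_factory=dict)
    #: per series incentive: relaxed threshold k, or absent/"STRICT" for the
    #: designed full threshold
    payment_rules: dict[str, int | Literal["STRICT"]] = Field(default_factory=dict)
    count_distribution: Literal["poisson", "negative_binomial"] = "poisson"
    nb_dispersion: float = Field(default=1.0, gt=0)
    questionnaire_props: dict[str, float] = Field(default_factory=dict)
    recency_props: Optional[list[float]] = None
    n_questionnaire: int = Field(default=1502, ge=0)
    awareness: Optional[AwarenessScenario] = None

    @model_validator(mode="after")
    def _proportions_valid(self) -> "GeneratorConfig":
        for k, v in {**self.background_rates, **self.questionnaire_props}.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"proportion {k!r} must be in [0, 1], got {v}")
        if not 0.0 <= self.default_background_rate <= 1.0:
            raise ValueError("default_background_rate must be in [0, 1]")
        if self.recency_props is not None:
            if len(self.recency_props) != len(RECENCY_LABELS) or abs(sum(self.recency_props) - 1) > 1e-9:
                raise ValueError(
                    f"recency_props must be {len(RECENCY_LABELS)} probabilities summing to 1"
                )
        for inc_id, probs in self.series_params.items():
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"series_params[{inc_id!r}] must be a probability vector")
        return self

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticData:
    """Generator output: long-format household rows, worker questionnaire
    rows, per worker-month-incentive payment records, and a manifest."""

    households: pd.DataFrame
    chws: pd.DataFrame
    payments: pd.DataFrame
    manifest: dict

    HOUSEHOLD_COLUMNS = (
        "chw_id",
        "month",
        "beneficiary_id",
        "incentive_id",
        "beneficiary_type",
        "kind",
        "key",
        "value",
    )
    PAYMENT_COLUMNS = ("chw_id", "month", "incentive_id", "category", "amount_paid")


def _draw_counts(rng: np.random.Generator, mean: float, size: int, config: GeneratorConfig) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if config.count_distribution == "poisson":
        return rng.poisson(mean, size=size)
    # negative binomial parametrized by mean and dispersion r (var = m + m^2/r)
    r = config.nb_dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _resolve_threshold(incentive: IncentiveDefinition, config: GeneratorConfig) -> int | None:
    if incentive.series is None:
        return None
    rule = config.payment_rules.get(incentive.id, STRICT)
    if rule == STRICT:
        return incentive.series.full_threshold
    k = int(rule)
    if not 1 <= k <= incentive.series.n_components:
        raise ConfigurationError(
            f"payment rule for {incentive.id!r}: threshold {k} outside "
            f"[1, {incentive.series.n_components}]"
        )
    return k


def generate(
    catalog: Sequence[IncentiveDefinition],
    demo: DemographicRates,
    true_rates: Mapping[str, float],
    config: GeneratorConfig,
) -> SyntheticData:
    """Simulate linked microdata for ``n_chw`` workers over ``months`` months.

    Per worker-month and incentive, beneficiary counts are drawn with mean
    equal to the analytic monthly incidence; contact flags are independent
    Bernoulli draws at the true action rates; behaviors are drawn at the
    conditional rate given full contact and at the background rate otherwise;
    series completion counts come from ``series_params`` given contact (zero
    without contact). A payment is recorded only when every required contact
    and behavior occurred and, for series incentives, the completion count
    met the payment rule's threshold — so background behavior is never paid.
    """
    # validate config against the catalog before any sampling
    by_id = {d.id: d for d in catalog}
    for inc_id, probs in config.series_params.items():
        d = by_id.get(inc_id)
        if d is None or d.series is None:
            raise ConfigurationError(f"series_params references non-series incentive {inc_id!r}")
        if len(probs) != d.series.n_components + 1:
            raise ConfigurationError(
                f"series_params[{inc_id!r}] must have {d.series.n_components + 1} entries"
            )
    for d in catalog:
        if d.series is not None and d.id not in config.series_params:
            raise ConfigurationError(f"series incentive {d.id!r} missing from series_params")
        for key in d.action_keys:
            if key not in true_rates:
                raise ConfigurationError(f"action rate {key!r} missing from true rates")
        # for series incentives the completion count IS the household
        # behavior, so behavior keys are only drawn for non-series incentives
        if d.series is None:
            for key in d.behavior_keys:
                if key not in true_rates:
                    raise ConfigurationError(f"behavior rate {key!r} missing from true rates")
        _resolve_threshold(d, config)

    rng = np.random.default_rng(config.seed)
    catchment = Catchment(config.catchment_population)
    n_cm = config.n_chw * config.months
    cm_chw = np.repeat(np.arange(config.n_chw), config.months)
    cm_month = np.tile(np.arange(1, config.months + 1), config.n_chw)

    hh_parts: list[pd.DataFrame] = []
    pay_parts: list[pd.DataFrame] = []
    next_beneficiary = 0

    for d in catalog:
        mean_inc = beneficiary_incidence(d, demo, catchment)
        if d.incidence_basis == ROUTINE_BASIS:
            counts = np.ones(n_cm, dtype=np.int64)
        else:
            counts = _draw_counts(rng, mean_inc, n_cm, config)
        n_b = int(counts.sum())
        b_chw = np.repeat(cm_chw, counts)
        b_month = np.repeat(cm_month, counts)
        b_ids = np.arange(next_beneficiary, next_beneficiary + n_b)
        next_beneficiary += n_b

        action_flags = {
            key: (rng.random(n_b) < true_rates[key]).astype(np.int64) for key in d.action_keys
        }
        contacted = np.ones(n_b, dtype=bool)
        for flags in action_flags.values():
            contacted &= flags.astype(bool)

        behavior_flags = {}
        if d.series is None:
            for key in d.behavior_keys:
                p_bg = config.background_rates.get(key, config.default_background_rate)
                p = np.where(contacted, true_rates[key], p_bg)
                behavior_flags[key] = (rng.random(n_b) < p).astype(np.int64)

        series_count = None
        if d.series is not None:
            probs = np.asarray(config.series_params[d.id], dtype=float)
            cdf = np.cumsum(probs)
            draws = np.searchsorted(cdf, rng.random(n_b), side="right")
            series_count = np.where(contacted, draws, 0).astype(np.int64)

        claim = contacted.copy()
        for flags in behavior_flags.values():
            claim &= flags.astype(bool)
        if series_count is not None:
            claim &= series_count >= _resolve_threshold(d, config)

        # long-format household rows: one per (beneficiary, flag)
        kinds, keys, values = [], [], []
        for key, flags in action_flags.items():
            kinds.append(np.full(n_b, "action", dtype=object))
            keys.append(np.full(n_b, key, dtype=object))
            values.append(flags)
        for key, flags in behavior_flags.items():
            kinds.append(np.full(n_b, "behavior", dtype=object))
            keys.append(np.full(n_b, key, dtype=object))
            values.append(flags)
        if series_count is not None:
            kinds.append(np.full(n_b, "series", dtype=object))
            keys.append(np.full(n_b, "completion_count", dtype=object))
            values.append(series_count)
        if kinds:
            reps = len(kinds)
            hh_parts.append(
                pd.DataFrame(
                    {
                        "chw_id": np.tile(b_chw, reps),
                        "month": np.tile(b_month, reps),
                        "beneficiary_id": np.tile(b_ids, reps),
                        "incentive_id": d.id,
                        "beneficiary_type": d.incidence_basis,
                        "kind": np.concatenate(kinds),
                        "key": np.concatenate(keys),
                        "value": np.concatenate(values).astype(np.int64),
                    }
                )
            )

        paid = np.bincount(
            np.repeat(np.arange(n_cm), counts)[claim], minlength=n_cm
        ) * float(d.amount)
        pay_parts.append(
            pd.DataFrame(
                {
                    "chw_id": cm_chw,
                    "month": cm_month,
                    "incentive_id": d.id,
                    "category": d.category.value,
                    "amount_paid": paid,
                }
            )
        )

    households = (
        pd.concat(hh_parts, ignore_index=True)
        if hh_parts
        else pd.DataFrame(columns=list(SyntheticData.HOUSEHOLD_COLUMNS))
    )
    payments = (
        pd.concat(pay_parts, ignore_index=True)
        if pay_parts
        else pd.DataFrame(columns=list(SyntheticData.PAYMENT_COLUMNS))
    )
    chws = _generate_questionnaire(rng, config)

    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_chw": config.n_chw,
        "months": config.months,
        "catchment_population": config.catchment_population,
        "n_households_rows": int(len(households)),
        "n_questionnaire": int(len(chws)),
    }
    return SyntheticData(households=households, chws=chws, payments=payments, manifest=manifest)


def _generate_questionnaire(rng: np.random.Generator, config: GeneratorConfig) -> pd.DataFrame:
    n = config.n_questionnaire
    data: dict[str, np.ndarray] = {"chw_id": np.arange(n)}
    for item, p in config.questionnaire_props.items():
        data[item] = (rng.random(n) < p).astype(np.int64)
    if config.recency_props is not None:
        cdf = np.cumsum(config.recency_props)
        idx = np.searchsorted(cdf, rng.random(n), side="right").clip(0, len(RECENCY_LABELS) - 1)
        data["payment_recency"] = np.asarray(RECENCY_LABELS, dtype=object)[idx]
    if config.awareness is not None:
        aw = config.awareness
        aware = (rng.random(n) < aw.aware_p).astype(np.int64)
        u = rng.random(n)
        # conditional answer mix among the aware; non-aware give no answer
        p_exact = aw.exact_p / aw.aware_p if aw.aware_p > 0 else 0.0
        p_modal = aw.modal_wrong_p / aw.aware_p if aw.aware_p > 0 else 0.0
        answer = np.where(
            u < p_exact,
            aw.correct_amount,
            np.where(u < p_exact + p_modal, aw.modal_wrong_amount, aw.other_wrong_amount),
        )
        answer = np.where(aware == 1, answer, np.nan)
        data[f"aware_{aw.item}"] = aware
        data[f"amount_answer_{aw.item}"] = answer
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# summaries and I/O


def mean_monthly_payment(payments: pd.DataFrame) -> float:
    """Mean total payment per worker-month across all incentives."""
    if payments.empty:
        return 0.0
    n_cm = payments[["chw_id", "month"]].drop_duplicates().shape[0]
    return float(payments["amount_paid"].sum() / n_cm)


def observed_from_payments(payments: pd.DataFrame, fiscal_year: str = "SYNTHETIC") -> ObservedPayments:
    """Collapse simulated payment records to per-category mean monthly
    payments (the shape of the government payment data)."""
    n_cm = payments[["chw_id", "month"]].drop_duplicates().shape[0]
    per_cat = payments.groupby("category")["amount_paid"].sum() / max(n_cm, 1)
    return ObservedPayments(
        per_category={Category(c): float(v) for c, v in per_cat.items()},
        fiscal_year=fiscal_year,
        source="synthetic generator",
    )


def write_microdata(data: SyntheticData, directory: str | Path) -> dict[str, Path]:
    """Write households/chws/payments CSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    try:
        for name, df in (
            ("households", data.households),
            ("chws", data.chws),
            ("payments", data.payments),
        ):
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        manifest_path = directory / "manifest.json"
        manifest_path.write_text(json.dumps(data.manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = manifest_path
    except OSError as exc:
        raise OSError(f"failed writing microdata under {directory}: {exc}") from exc
    return paths


def read_microdata(directory: str | Path) -> SyntheticData:
    directory = Path(directory)
    try:
        households = pd.read_csv(directory / "households.csv")
        chws = pd.read_csv(directory / "chws.csv")
        payments = pd.read_csv(directory / "payments.csv")
        manifest = json.loads((directory / "manifest.json").read_text())
    except OSError as exc:
        raise OSError(f"failed reading microdata under {directory}: {exc}") from exc
    return SyntheticData(households=households, chws=chws, payments=payments, manifest=manifest)


def estimate_true_rateset(true_rates: Mapping[str, float]) -> RateSet:
    """Wrap a plain mapping as a RateSet tagged SYNTHETIC (convenience)."""
    return RateSet(dict(true_rates), {k: "SYNTHETIC" for k in true_rates})
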