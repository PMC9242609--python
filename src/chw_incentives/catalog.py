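"""Incentive catalog: definitions, loading, validation, serialization.

The catalog is the list of incentives a worker can claim, each tied to a
rupee amount, a beneficiary-incidence basis, the worker actions required,
and (optionally) the household behaviors and series-completion rules that
condition payment.
"""

from __future__ import annotations

import json
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pydantic
from pydantic import BaseModel, Field, model_validator

from .errors import CatalogValidationError, SchemaError

__all__ = [
    "Category",
    "Scaling",
    "SeriesSpec",
    "IncentiveDefinition",
    "ObservedPayments",
    "load_catalog",
    "save_catalog",
    "catalog_to_frame",
    "validate_against_rates",
    "ROUTINE_BASIS",
]

#: Sentinel incidence basis for fixed monthly activities (one event per month).
ROUTINE_BASIS = "ROUTINE"

_KEY_RE = re.compile(r"^[a-z][a-z0-9_]*$")

SCHEMA_VERSION = 1


class Category(str, Enum):
    """The five incentive categories of the analysis."""

    ANC_ID = "ANC_ID"
    PNC = "PNC"
    FP = "FP"
    IMMUNIZATION = "IMMUNIZATION"
    ROUTINE = "ROUTINE"


class Scaling(str, Enum):
    #: earnings scale linearly with catchment population
    POPULATION = "POPULATION"
    #: earnings are independent of catchment size
    FIXED = "FIXED"


class SeriesSpec(BaseModel):
    """A lump-sum incentive paid on completing ``full_threshold`` of
    ``n_components`` component activities (e.g. 4 antenatal check-ups)."""

    n_components: int = Field(gt=0)
    full_threshold: int = Field(gt=0)

    @model_validator(mode="after")
    def _threshold_in_range(self) -> "SeriesSpec":
        if not 1 <= self.full_threshold <= self.n_components:
            raise ValueError(
                f"full_threshold must be in [1, n_components]; got "
                f"full_threshold={self.full_threshold}, n_components={self.n_components}"
            )
        return self


class IncentiveDefinition(BaseModel):
    """One claimable incentive.

    Parameters
    ----------
    id
        Short unique key, e.g. ``"institutional_delivery"``.
    amount
        Rupees paid per claimable unit. Must be positive.
    incidence_basis
        Key into the demographic-rate table giving beneficiary incidence,
        or ``"ROUTINE"`` for a fixed one-event-per-month activity.
    action_keys, behavior_keys
        Rate-set keys for the worker actions and (conditional) household
        behaviors required for a claim.
    monthly_events_per_beneficiary
        For ``PROPORTION``-based incidence only: events per beneficiary per
        month (default 1/12, i.e. one event per beneficiary per year).
    """

    id: str = Field(min_length=1)
    name: str
    category: Category
    amount: float = Field(gt=0)
    incidence_basis: str = Field(min_length=1)
    action_keys: list[str] = Field(default_factory=list)
    behavior_keys: list[str] = Field(default_factory=list)
    series: Optional[SeriesSpec] = None
    scaling: Scaling = Scaling.POPULATION
    monthly_events_per_beneficiary: Optional[float] = None
    amount_is_placeholder: bool = False

    @model_validator(mode="after")
    def _check_invariants(self) -> "IncentiveDefinition":
        for key in [*self.action_keys, *self.behavior_keys]:
            if not _KEY_RE.match(key):
                raise ValueError(f"invalid rate key {key!r} (must match {_KEY_RE.pattern})")
        routine = self.incidence_basis == ROUTINE_BASIS
        fixed = self.scaling == Scaling.FIXED
        if routine != fixed:
            raise ValueError(
                f"incentive {self.id!r}: incidence_basis ROUTINE requires scaling FIXED "
                f"and vice versa (got basis={self.incidence_basis!r}, scaling={self.scaling.value})"
            )
        return self


class ObservedPayments(BaseModel):
    """Mean monthly government payments, by category."""

    per_category: dict[Category, float]
    fiscal_year: str = ""
    source: str = ""

    @model_validator(mode="after")
    def _nonnegative(self) -> "ObservedPayments":
        for cat, v in self.per_category.items():
            if v < 0:
                raise ValueError(f"observed payment for {cat.value} is negative: {v}")
        return self

    @property
    def total(self) -> float:
        return float(sum(self.per_category.values()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedPayments":
        """Read a CSV with columns category, fiscal_year, mean_monthly_inr[, source]."""
        df = pd.read_csv(path)
        required = {"category", "fiscal_year", "mean_monthly_inr"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"{path}: observed-payments CSV needs columns {sorted(required)}, "
                f"found {sorted(df.columns)}"
            )
        try:
            per_cat = {Category(row.category): float(row.mean_monthly_inr) for row in df.itertuples()}
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
        fy = str(df["fiscal_year"].iloc[0]) if len(df) else ""
        source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else ""
        return cls(per_category=per_cat, fiscal_year=fy, source=source)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "category": [c.value for c in self.per_category],
                "fiscal_year": self.fiscal_year,
                "mean_monthly_inr": list(self.per_category.values()),
                "source": self.source,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading / serialization


def _definitions_from_records(records: Iterable[dict], origin: str) -> list[IncentiveDefinition]:
    defs: list[IncentiveDefinition] = []
    violations: list[str] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        try:
            d = IncentiveDefinition.model_validate(rec)
        except pydantic.ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(p) for p in err["loc"]) or "<record>"
                violations.append(f"{origin} record {i} ({rec.get('id', '?')}): {loc}: {err['msg']}")
            continue
        if d.id in seen:
            violations.append(f"{origin} record {i}: duplicate incentive id {d.id!r}")
            continue
        seen.add(d.id)
        defs.append(d)
    if violations:
        raise CatalogValidationError(violations)
    return defs


def load_catalog(path: str | Path) -> list[IncentiveDefinition]:
    """Load and validate an incentive catalog from JSON or CSV.

    JSON is the native format (``{"schema_version": 1, "incentives": [...]}``);
    CSV is a flat import with one row per incentive and optional series columns.
    All invariant violations are collected and reported together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return _load_catalog_csv(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "incentives" not in payload:
        raise SchemaError(f"{path}: expected an object with an 'incentives' array")
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unsupported schema_version {payload.get('schema_version')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    return _definitions_from_records(payload["incentives"], str(path))


def _load_catalog_csv(path: Path) -> list[IncentiveDefinition]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    records = []
    for row in df.to_dict(orient="records"):
        rec: dict = {
            k: row[k]
            for k in ("id", "name", "category", "amount", "incidence_basis", "scaling")
            if k in row and not pd.isna(row[k])
        }
        for keycol in ("action_keys", "behavior_keys"):
            raw = row.get(keycol)
            rec[keycol] = [] if pd.isna(raw) or not str(raw) else str(raw).split(";")
        n_comp, thresh = row.get("series_n_components"), row.get("series_full_threshold")
        if not pd.isna(n_comp) and not pd.isna(thresh):
            rec["series"] = {"n_components": int(n_comp), "full_threshold": int(thresh)}
        mep = row.get("monthly_events_per_beneficiary")
        if mep is not None and not pd.isna(mep):
            rec["monthly_events_per_beneficiary"] = float(mep)
        flag = row.get("amount_is_placeholder")
        if flag is not None and not pd.isna(flag):
            rec["amount_is_placeholder"] = bool(flag)
        records.append(rec)
    return _definitions_from_records(records, str(path))


def save_catalog(catalog: list[IncentiveDefinition], path: str | Path) -> None:
    """Serialize a catalog to its native JSON schema (round-trips with load_catalog)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "incentives": [d.model_dump(mode="json", exclude_none=True) for d in catalog],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def catalog_to_frame(catalog: list[IncentiveDefinition]) -> pd.DataFrame:
    """Flat one-row-per-incentive view (also the CSV export layout)."""
    rows = []
    for d in catalog:
        rows.append(
            {
                "id": d.id,
                "name": d.name,
                "category": d.category.value,
                "amount": d.amount,
                "incidence_basis": d.incidence_basis,
                "action_keys": ";".join(d.action_keys),
                "behavior_keys": ";".join(d.behavior_keys),
                "series_n_components": d.series.n_components if d.series else None,
                "series_full_threshold": d.series.full_threshold if d.series else None,
                "scaling": d.scaling.value,
                "monthly_events_per_beneficiary": d.monthly_events_per_beneficiary,
                "amount_is_placeholder": d.amount_is_placeholder,
            }
        )
    return pd.DataFrame(rows)


def validate_against_rates(catalog: list[IncentiveDefinition], rates) -> list[str]:
    """Report every action/behavior key the catalog references but the rate
    set lacks. An empty report means the catalog is projectable in ACTUAL modes.
    """
    missing: set[str] = set()
    for d in catalog:
        for key in [*d.action_keys, *d.behavior_keys]:
            if key not in rates:
                missing.add(key)
    return sorted(missing)
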