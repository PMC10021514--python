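"""Country policy records: data model, file I/O and missing-data handling.

One :class:`CountryRecord` holds everything the index needs for one
jurisdiction: the raw measures for the five policy domains (trading
hours/days, outlet density, pricing, marketing, drink driving), the
beverage market shares used as weights in the pricing domain, and the
outcome variable (recorded alcohol per-capita consumption, litres of
pure alcohol per person aged 15+).

Validation is strict and never coerces silently: a record that violates
a field invariant raises at construction, and :func:`read_cohort` maps
such failures back to the offending row and column.
"""

from __future__ import annotations

import json
import math
import statistics
import warnings
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "BEVERAGES",
    "MARKETING_MODES",
    "REGULATION_LEVELS",
    "N_MARKETING_MODES",
    "TradingHoursRecord",
    "OutletDensityRecord",
    "PricingRecord",
    "MarketingRecord",
    "DrinkDrivingRecord",
    "CountryRecord",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "impute_missing_rbt",
]

BEVERAGES = ("beer", "wine", "spirits")

#: The five modes of marketing for which legislated restrictions are scored.
MARKETING_MODES = ("traditional", "digital", "sponsorship", "promotions", "placement")

#: Number of observed marketing modes in the environment schedule.
N_MARKETING_MODES = 25

RegulationLevel = Literal["none_or_self_regulation", "partial_ban", "total_ban"]
REGULATION_LEVELS = ("none_or_self_regulation", "partial_ban", "total_ban")

# short forms used in CSV serialisation
_LEVEL_TO_SHORT = {
    "none_or_self_regulation": "none",
    "partial_ban": "partial",
    "total_ban": "total",
}
_SHORT_TO_LEVEL = {v: k for k, v in _LEVEL_TO_SHORT.items()}


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class TradingHoursRecord(_Frozen):
    """Legal and actual daily trading hours and 7-day opening, on/off premise."""

    on_legal_hours: float = Field(ge=0.0, le=24.0)
    on_legal_7days: bool
    off_legal_hours: float = Field(ge=0.0, le=24.0)
    off_legal_7days: bool
    on_actual_hours: float = Field(ge=0.0, le=24.0)
    on_actual_7days: bool
    off_actual_hours: float = Field(ge=0.0, le=24.0)
    off_actual_7days: bool

    @model_validator(mode="after")
    def _warn_actual_exceeds_legal(self) -> "TradingHoursRecord":
        # observed opening can exceed the law (non-compliance); keep, but flag
        if self.on_actual_hours > self.on_legal_hours:
            warnings.warn(
                "on-premise actual trading hours exceed legal hours", stacklevel=2
            )
        if self.off_actual_hours > self.off_legal_hours:
            warnings.warn(
                "off-premise actual trading hours exceed legal hours", stacklevel=2
            )
        return self


class OutletDensityRecord(_Frozen):
    """Six binary outlet-density restrictions (on/off premise x three kinds)."""

    on_number: bool
    on_area: bool
    on_location: bool
    off_number: bool
    off_area: bool
    off_location: bool

    def n_restrictions(self) -> int:
        return sum(
            (
                self.on_number,
                self.on_area,
                self.on_location,
                self.off_number,
                self.off_area,
                self.off_location,
            )
        )


class PricingRecord(_Frozen):
    """Tax rates as % of price, mid-prices of 15 ml absolute alcohol, and GDP.

    Prices and GDP per capita must be expressed in the same (local)
    currency; the affordability ratio built from them is then unit-free
    and comparable across countries. That currency consistency is the
    caller's contract — no FX conversion happens here.
    """

    tax_pct: dict[str, float]
    midprice_15ml: dict[str, float]
    gdp_per_capita: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check_beverage_maps(self) -> "PricingRecord":
        for name, mapping in (("tax_pct", self.tax_pct), ("midprice_15ml", self.midprice_15ml)):
            if set(mapping) != set(BEVERAGES):
                raise ValueError(f"{name} keys must be exactly {set(BEVERAGES)}, got {set(mapping)}")
        for b, v in self.tax_pct.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"tax_pct[{b}] = {v} outside [0, 100]")
        for b, v in self.midprice_15ml.items():
            if v < 0.0:
                raise ValueError(f"midprice_15ml[{b}] = {v} must be >= 0")
        return self


class MarketingRecord(_Frozen):
    """Legislated restriction level per marketing mode plus observed modes."""

    regulation_level: dict[str, RegulationLevel]
    potency_differential: bool
    modes_present: tuple[bool, ...]

    @model_validator(mode="after")
    def _check_shapes(self) -> "MarketingRecord":
        if set(self.regulation_level) != set(MARKETING_MODES):
            raise ValueError(
                f"regulation_level keys must be exactly {set(MARKETING_MODES)}"
            )
        if len(self.modes_present) != N_MARKETING_MODES:
            raise ValueError(
                f"modes_present must have exactly {N_MARKETING_MODES} flags, "
                f"got {len(self.modes_present)}"
            )
        return self

    def n_modes_present(self) -> int:
        return sum(self.modes_present)


class DrinkDrivingRecord(_Frozen):
    """BAC limit and enforcement measures.

    ``bac_limit`` is the legal blood-alcohol concentration limit for
    drivers in percent; ``None`` means the jurisdiction has no legal
    limit at all (a distinct, least-strict category — 0.0 is itself the
    strictest possible limit, so it cannot stand in for "no limit").
    ``rbt_pct_vehicles_stopped`` is the % of vehicles stopped for random
    breath testing per year; ``None`` means not measured (imputable).
    """

    bac_limit: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    sobriety_checkpoints: bool
    random_breath_testing: bool
    zero_tolerance_professional: bool
    rbt_pct_vehicles_stopped: Optional[float] = Field(default=None, ge=0.0, le=100.0)


class CountryRecord(_Frozen):
    country_id: str = Field(min_length=1)
    hours: TradingHoursRecord
    density: OutletDensityRecord
    pricing: PricingRecord
    marketing: MarketingRecord
    drink_driving: DrinkDrivingRecord
    beverage_shares: dict[str, float]
    recorded_apc: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check_shares(self) -> "CountryRecord":
        if set(self.beverage_shares) != set(BEVERAGES):
            raise ValueError(f"beverage_shares keys must be exactly {set(BEVERAGES)}")
        total = sum(self.beverage_shares.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"beverage_shares must sum to 1, got {total!r}")
        if any(v < 0 for v in self.beverage_shares.values()):
            raise ValueError("beverage_shares must be non-negative")
        return self


class CohortSchemaError(ValueError):
    """Raised when an input file violates the cohort schema.

    Carries the offending row (0-based data row) and column where known.
    """

    def __init__(self, message: str, row: Optional[int] = None, column: Optional[str] = None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None:
            loc += f" [row {row}"
            loc += f", column {column}]" if column else "]"
        elif column:
            loc += f" [column {column}]"
        super().__init__(message + loc)


# ---------------------------------------------------------------------------
# flat (CSV) serialisation

_MODE_COLS = [f"mode_{i:02d}" for i in range(1, N_MARKETING_MODES + 1)]

CSV_COLUMNS = (
    ["country_id"]
    + [
        "on_legal_hours", "on_legal_7days", "off_legal_hours", "off_legal_7days",
        "on_actual_hours", "on_actual_7days", "off_actual_hours", "off_actual_7days",
        "density_on_number", "density_on_area", "density_on_location",
        "density_off_number", "density_off_area", "density_off_location",
        "tax_pct_beer", "tax_pct_wine", "tax_pct_spirits",
        "price15_beer", "price15_wine", "price15_spirits",
        "gdp_per_capita",
        "mkt_traditional", "mkt_digital", "mkt_sponsorship", "mkt_promotions",
        "mkt_placement", "mkt_potency_differential",
    ]
    + _MODE_COLS
    + [
        "bac_limit", "ddi_sobriety", "ddi_rbt", "ddi_zero_prof", "rbt_pct_stopped",
        "share_beer", "share_wine", "share_spirits", "recorded_apc",
    ]
)


def record_to_row(rec: CountryRecord) -> dict:
    """Flatten a record to the published CSV schema (booleans as 0/1)."""
    h, d, p, m, dd = rec.hours, rec.density, rec.pricing, rec.marketing, rec.drink_driving
    row: dict = {
        "country_id": rec.country_id,
        "on_legal_hours": h.on_legal_hours,
        "on_legal_7days": int(h.on_legal_7days),
        "off_legal_hours": h.off_legal_hours,
        "off_legal_7days": int(h.off_legal_7days),
        "on_actual_hours": h.on_actual_hours,
        "on_actual_7days": int(h.on_actual_7days),
        "off_actual_hours": h.off_actual_hours,
        "off_actual_7days": int(h.off_actual_7days),
        "density_on_number": int(d.on_number),
        "density_on_area": int(d.on_area),
        "density_on_location": int(d.on_location),
        "density_off_number": int(d.off_number),
        "density_off_area": int(d.off_area),
        "density_off_location": int(d.off_location),
        "tax_pct_beer": p.tax_pct["beer"],
        "tax_pct_wine": p.tax_pct["wine"],
        "tax_pct_spirits": p.tax_pct["spirits"],
        "price15_beer": p.midprice_15ml["beer"],
        "price15_wine": p.midprice_15ml["wine"],
        "price15_spirits": p.midprice_15ml["spirits"],
        "gdp_per_capita": p.gdp_per_capita,
        "mkt_traditional": _LEVEL_TO_SHORT[m.regulation_level["traditional"]],
        "mkt_digital": _LEVEL_TO_SHORT[m.regulation_level["digital"]],
        "mkt_sponsorship": _LEVEL_TO_SHORT[m.regulation_level["sponsorship"]],
        "mkt_promotions": _LEVEL_TO_SHORT[m.regulation_level["promotions"]],
        "mkt_placement": _LEVEL_TO_SHORT[m.regulation_level["placement"]],
        "mkt_potency_differential": int(m.potency_differential),
    }
    for col, flag in zip(_MODE_COLS, m.modes_present):
        row[col] = int(flag)
    row.update(
        {
            "bac_limit": "" if dd.bac_limit is None else dd.bac_limit,
            "ddi_sobriety": int(dd.sobriety_checkpoints),
            "ddi_rbt": int(dd.random_breath_testing),
            "ddi_zero_prof": int(dd.zero_tolerance_professional),
            "rbt_pct_stopped": (
                "" if dd.rbt_pct_vehicles_stopped is None else dd.rbt_pct_vehicles_stopped
            ),
            "share_beer": rec.beverage_shares["beer"],
            "share_wine": rec.beverage_shares["wine"],
            "share_spirits": rec.beverage_shares["spirits"],
            "recorded_apc": rec.recorded_apc,
        }
    )
    return row


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip()
    if s in ("0", "1"):
        return s == "1"
    if isinstance(value, bool):
        return value
    raise CohortSchemaError(f"expected 0/1 boolean, got {value!r}", row=row, column=column)


def _parse_float(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortSchemaError(f"expected number, got {value!r}", row=row, column=column) from None


def _parse_optional_float(value, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        return None
    return _parse_float(value, column, row)


def _parse_level(value, column: str, row: int) -> str:
    s = str(value).strip()
    if s in _SHORT_TO_LEVEL:
        return _SHORT_TO_LEVEL[s]
    if s in _LEVEL_TO_SHORT:
        return s
    raise CohortSchemaError(
        f"expected one of none|partial|total, got {value!r}", row=row, column=column
    )


def row_to_record(row: dict, row_index: int = 0) -> CountryRecord:
    """Build a validated CountryRecord from one flat CSV row."""
    missing = [c for c in CSV_COLUMNS if c not in row]
    if missing:
        raise CohortSchemaError(f"missing columns: {missing}", row=row_index)
    g = row  # shorthand
    try:
        rec = CountryRecord(
            country_id=str(g["country_id"]),
            hours=TradingHoursRecord(
                on_legal_hours=_parse_float(g["on_legal_hours"], "on_legal_hours", row_index),
                on_legal_7days=_parse_bool(g["on_legal_7days"], "on_legal_7days", row_index),
                off_legal_hours=_parse_float(g["off_legal_hours"], "off_legal_hours", row_index),
                off_legal_7days=_parse_bool(g["off_legal_7days"], "off_legal_7days", row_index),
                on_actual_hours=_parse_float(g["on_actual_hours"], "on_actual_hours", row_index),
                on_actual_7days=_parse_bool(g["on_actual_7days"], "on_actual_7days", row_index),
                off_actual_hours=_parse_float(g["off_actual_hours"], "off_actual_hours", row_index),
                off_actual_7days=_parse_bool(g["off_actual_7days"], "off_actual_7days", row_index),
            ),
            density=OutletDensityRecord(
                on_number=_parse_bool(g["density_on_number"], "density_on_number", row_index),
                on_area=_parse_bool(g["density_on_area"], "density_on_area", row_index),
                on_location=_parse_bool(g["density_on_location"], "density_on_location", row_index),
                off_number=_parse_bool(g["density_off_number"], "density_off_number", row_index),
                off_area=_parse_bool(g["density_off_area"], "density_off_area", row_index),
                off_location=_parse_bool(g["density_off_location"], "density_off_location", row_index),
            ),
            pricing=PricingRecord(
                tax_pct={
                    "beer": _parse_float(g["tax_pct_beer"], "tax_pct_beer", row_index),
                    "wine": _parse_float(g["tax_pct_wine"], "tax_pct_wine", row_index),
                    "spirits": _parse_float(g["tax_pct_spirits"], "tax_pct_spirits", row_index),
                },
                midprice_15ml={
                    "beer": _parse_float(g["price15_beer"], "price15_beer", row_index),
                    "wine": _parse_float(g["price15_wine"], "price15_wine", row_index),
                    "spirits": _parse_float(g["price15_spirits"], "price15_spirits", row_index),
                },
                gdp_per_capita=_parse_float(g["gdp_per_capita"], "gdp_per_capita", row_index),
            ),
            marketing=MarketingRecord(
                regulation_level={
                    mode: _parse_level(g[f"mkt_{mode}"], f"mkt_{mode}", row_index)
                    for mode in MARKETING_MODES
                },
                potency_differential=_parse_bool(
                    g["mkt_potency_differential"], "mkt_potency_differential", row_index
                ),
                modes_present=tuple(
                    _parse_bool(g[c], c, row_index) for c in _MODE_COLS
                ),
            ),
            drink_driving=DrinkDrivingRecord(
                bac_limit=_parse_optional_float(g["bac_limit"], "bac_limit", row_index),
                sobriety_checkpoints=_parse_bool(g["ddi_sobriety"], "ddi_sobriety", row_index),
                random_breath_testing=_parse_bool(g["ddi_rbt"], "ddi_rbt", row_index),
                zero_tolerance_professional=_parse_bool(
                    g["ddi_zero_prof"], "ddi_zero_prof", row_index
                ),
                rbt_pct_vehicles_stopped=_parse_optional_float(
                    g["rbt_pct_stopped"], "rbt_pct_stopped", row_index
                ),
            ),
            beverage_shares={
                "beer": _parse_float(g["share_beer"], "share_beer", row_index),
                "wine": _parse_float(g["share_wine"], "share_wine", row_index),
                "spirits": _parse_float(g["share_spirits"], "share_spirits", row_index),
            },
            recorded_apc=_parse_float(g["recorded_apc"], "recorded_apc", row_index),
        )
    except ValidationError as err:
        first = err.errors()[0]
        col = ".".join(str(p) for p in first["loc"])
        raise CohortSchemaError(first["msg"], row=row_index, column=col) from err
    except ValueError as err:
        if isinstance(err, CohortSchemaError):
            raise
        raise CohortSchemaError(str(err), row=row_index) from err
    return rec


def read_cohort(path, format: str | None = None) -> list[CountryRecord]:
    """Read a cohort file (CSV or nested JSON) into validated records.

    Row order is preserved; duplicated country ids are rejected.
    ``format`` defaults to the file extension.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
        unknown = [c for c in df.columns if c not in CSV_COLUMNS]
        if unknown:
            raise CohortSchemaError(f"unknown columns: {unknown}")
        cohort = [row_to_record(row, i) for i, row in enumerate(df.to_dict("records"))]
    elif fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise CohortSchemaError("JSON cohort must be a list of country objects")
        cohort = []
        for i, obj in enumerate(payload):
            try:
                cohort.append(CountryRecord.model_validate(obj))
            except ValidationError as err:
                first = err.errors()[0]
                col = ".".join(str(p) for p in first["loc"])
                raise CohortSchemaError(first["msg"], row=i, column=col) from err
    else:
        raise ValueError(f"unsupported cohort format: {fmt!r}")

    ids = [r.country_id for r in cohort]
    dupes = sorted({c for c in ids if ids.count(c) > 1})
    if dupes:
        raise CohortSchemaError(f"non-unique country_id: {dupes}")
    return cohort


def write_cohort(cohort: list[CountryRecord], path, format: str | None = None) -> None:
    """Write a cohort to CSV (flat published schema) or JSON (nested)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.DataFrame([record_to_row(r) for r in cohort], columns=CSV_COLUMNS)
        df.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump([r.model_dump(mode="json") for r in cohort], fh, indent=1)
    else:
        raise ValueError(f"unsupported cohort format: {fmt!r}")


def impute_missing_rbt(
    cohort: list[CountryRecord],
) -> tuple[list[CountryRecord], list[tuple[str, float]]]:
    """Fill missing RBT percentages with the cohort median of observed values.

    Returns a new cohort (inputs untouched) and an imputation log of
    ``(country_id, imputed_value)`` pairs. Idempotent. Raises if no
    country has an observed value.
    """
    observed = [
        r.drink_driving.rbt_pct_vehicles_stopped
        for r in cohort
        if r.drink_driving.rbt_pct_vehicles_stopped is not None
    ]
    missing = [r for r in cohort if r.drink_driving.rbt_pct_vehicles_stopped is None]
    if missing and not observed:
        raise ValueError("cannot impute RBT percentage: no observed values in cohort")
    if not missing:
        return list(cohort), []
    med = float(statistics.median(observed))
    log: list[tuple[str, float]] = []
    out: list[CountryRecord] = []
    for rec in cohort:
        if rec.drink_driving.rbt_pct_vehicles_stopped is None:
            dd = rec.drink_driving.model_copy(update={"rbt_pct_vehicles_stopped": med})
            out.append(rec.model_copy(update={"drink_driving": dd}))
            log.append((rec.country_id, med))
        else:
            out.append(rec)
    return out, log
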