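"""Normalised [0, 1] stringency and impact scores for the five policy domains.

Every score follows one direction convention: **higher = more
restrictive environment**. Measures whose raw direction runs the other
way (trading hours, marketing modes in use, affordability's raw price
side) are inverted inside their scorer so the convention holds
everywhere downstream.

Two impact measures — affordability and the RBT testing percentage —
are unbounded in raw form and are brought onto [0, 1] by min–max
scaling *across the cohort*; they therefore depend on which countries
are scored together, which is the standard composite-indicator
normalisation for open-ended measures. All other scores are
cohort-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .records import (
    BEVERAGES,
    MARKETING_MODES,
    N_MARKETING_MODES,
    CountryRecord,
    DrinkDrivingRecord,
    MarketingRecord,
    OutletDensityRecord,
    PricingRecord,
    TradingHoursRecord,
)

__all__ = [
    "DOMAINS",
    "DomainScore",
    "CohortContext",
    "score_hours_stringency",
    "score_hours_impact",
    "score_density_stringency",
    "score_pricing_stringency",
    "compute_affordability",
    "score_pricing_impact",
    "score_marketing_stringency",
    "score_marketing_impact",
    "bac_category",
    "score_drink_driving_stringency",
    "score_drink_driving_impact",
    "score_country",
    "score_cohort",
]

DOMAINS = ("hours", "density", "pricing", "marketing", "drink_driving")

_LEVEL_POINTS = {"none_or_self_regulation": 0, "partial_ban": 1, "total_ban": 2}


@dataclass(frozen=True)
class DomainScore:
    """A (stringency, impact) pair of normalised scores for one domain.

    ``impact`` is ``None`` only for the outlet-density domain, for which
    no on-the-ground measure is available.
    """

    domain: str
    stringency: float
    impact: Optional[float]

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not 0.0 <= self.stringency <= 1.0:
            raise ValueError(f"stringency {self.stringency} outside [0, 1]")
        if self.domain == "density":
            if self.impact is not None:
                raise ValueError("density has no impact score")
        else:
            if self.impact is None:
                raise ValueError(f"{self.domain} requires an impact score")
            if not 0.0 <= self.impact <= 1.0:
                raise ValueError(f"impact {self.impact} outside [0, 1]")


def _minmax(value: float, lo: float, hi: float, what: str) -> float:
    if hi <= lo:
        warnings.warn(
            f"degenerate cohort spread for {what}; scoring 0.5", stacklevel=3
        )
        return 0.5
    return (value - lo) / (hi - lo)


@dataclass(frozen=True)
class CohortContext:
    """Cohort-relative state for the two min–max scaled impact measures."""

    affordability: dict[str, float]
    rbt_pct: dict[str, float]

    @classmethod
    def from_cohort(cls, cohort: list[CountryRecord]) -> "CohortContext":
        """Build scaling context; RBT values must already be imputed."""
        afford = {
            r.country_id: compute_affordability(r.pricing, r.beverage_shares)
            for r in cohort
        }
        rbt: dict[str, float] = {}
        for r in cohort:
            v = r.drink_driving.rbt_pct_vehicles_stopped
            if v is None:
                raise ValueError(
                    f"{r.country_id}: missing RBT percentage; impute before scoring"
                )
            rbt[r.country_id] = v
        return cls(affordability=afford, rbt_pct=rbt)

    def scale_affordability(self, value: float) -> float:
        vals = list(self.affordability.values())
        return _minmax(value, min(vals), max(vals), "affordability")

    def scale_rbt(self, value: float) -> float:
        vals = list(self.rbt_pct.values())
        return _minmax(value, min(vals), max(vals), "RBT percentage")


# ---------------------------------------------------------------------------
# trading hours / days of sale

def _hours_subscores(hours_on: float, seven_on: bool, hours_off: float, seven_off: bool) -> float:
    # hours sub-score: linear, 24 h/day -> 0, 0 h/day -> 1
    # 7-days sub-score: allowed -> 0 (permissive), not allowed -> 1
    parts = (
        (24.0 - hours_on) / 24.0,
        0.0 if seven_on else 1.0,
        (24.0 - hours_off) / 24.0,
        0.0 if seven_off else 1.0,
    )
    return sum(parts) / 4.0


def score_hours_stringency(hours: TradingHoursRecord) -> float:
    """Mean of four sub-scores over legal on/off-premise hours and 7-day opening."""
    return _hours_subscores(
        hours.on_legal_hours, hours.on_legal_7days,
        hours.off_legal_hours, hours.off_legal_7days,
    )


def score_hours_impact(hours: TradingHoursRecord) -> float:
    """Same rule as the stringency score, applied to actual opening."""
    return _hours_subscores(
        hours.on_actual_hours, hours.on_actual_7days,
        hours.off_actual_hours, hours.off_actual_7days,
    )


# ---------------------------------------------------------------------------
# outlet density

def score_density_stringency(density: OutletDensityRecord) -> float:
    """Fraction of the six binary outlet-density restrictions in place."""
    return density.n_restrictions() / 6.0


# ---------------------------------------------------------------------------
# pricing

def score_pricing_stringency(pricing: PricingRecord, shares: dict[str, float]) -> float:
    """Market-share-weighted tax rate as a fraction of price."""
    return sum(shares[b] * pricing.tax_pct[b] / 100.0 for b in BEVERAGES)


def compute_affordability(pricing: PricingRecord, shares: dict[str, float]) -> float:
    """Share-weighted mid-price of 15 ml absolute alcohol over per-capita GDP.

    Unit-free because prices and GDP share a currency. Higher values
    mean alcohol is *less* affordable relative to income.
    """
    if pricing.gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be positive")
    weighted_price = sum(shares[b] * pricing.midprice_15ml[b] for b in BEVERAGES)
    return weighted_price / pricing.gdp_per_capita


def score_pricing_impact(affordability: float, context: CohortContext) -> float:
    """Min–max scaled affordability: cohort minimum -> 0, maximum -> 1."""
    return context.scale_affordability(affordability)


# ---------------------------------------------------------------------------
# marketing

def score_marketing_stringency(marketing: MarketingRecord) -> float:
    """Restriction points over five modes (0/1/2 each) plus potency rule, out of 11."""
    pts = sum(_LEVEL_POINTS[marketing.regulation_level[m]] for m in MARKETING_MODES)
    pts += 1 if marketing.potency_differential else 0
    return pts / 11.0


def score_marketing_impact(marketing: MarketingRecord) -> float:
    """Fraction of the 25 measured marketing modes *not* present."""
    return (N_MARKETING_MODES - marketing.n_modes_present()) / N_MARKETING_MODES


# ---------------------------------------------------------------------------
# drink driving

def bac_category(bac_limit: Optional[float]) -> int:
    """Ordinal BAC strictness: no limit 0; >=0.05% 1; [0.03, 0.05) 2; [0, 0.03) 3."""
    if bac_limit is None:
        return 0
    if bac_limit >= 0.05:
        return 1
    if bac_limit >= 0.03:
        return 2
    return 3


def score_drink_driving_stringency(dd: DrinkDrivingRecord) -> float:
    """BAC category plus three enforcement flags, out of 6."""
    pts = bac_category(dd.bac_limit)
    pts += dd.sobriety_checkpoints + dd.random_breath_testing
    pts += dd.zero_tolerance_professional
    return pts / 6.0


def score_drink_driving_impact(rbt_pct: float, context: CohortContext) -> float:
    """Min–max scaled percentage of vehicles stopped for random breath testing."""
    return context.scale_rbt(rbt_pct)


# ---------------------------------------------------------------------------
# whole-record scoring

def score_country(record: CountryRecord, context: CohortContext) -> dict[str, DomainScore]:
    """Score one country on all five domains (9 numeric components).

    Returns a mapping keyed by domain name in canonical order.
    """
    afford = compute_affordability(record.pricing, record.beverage_shares)
    rbt = record.drink_driving.rbt_pct_vehicles_stopped
    if rbt is None:
        raise ValueError(
            f"{record.country_id}: missing RBT percentage; impute before scoring"
        )
    return {
        "hours": DomainScore(
            "hours",
            score_hours_stringency(record.hours),
            score_hours_impact(record.hours),
        ),
        "density": DomainScore(
            "density", score_density_stringency(record.density), None
        ),
        "pricing": DomainScore(
            "pricing",
            score_pricing_stringency(record.pricing, record.beverage_shares),
            score_pricing_impact(afford, context),
        ),
        "marketing": DomainScore(
            "marketing",
            score_marketing_stringency(record.marketing),
            score_marketing_impact(record.marketing),
        ),
        "drink_driving": DomainScore(
            "drink_driving",
            score_drink_driving_stringency(record.drink_driving),
            score_drink_driving_impact(rbt, context),
        ),
    }


def score_cohort(cohort: list[CountryRecord]) -> dict[str, dict[str, DomainScore]]:
    """Score every country against a context built from the whole cohort."""
    context = CohortContext.from_cohort(cohort)
    return {r.country_id: score_country(r, context) for r in cohort}
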