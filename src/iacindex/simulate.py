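"""Synthetic country cohorts with a controllable policy–consumption link.

The generator implements a single-latent-factor design: each country
draws a latent policy restrictiveness ``u ~ Uniform(0, 1)``, every raw
policy measure in a signal-carrying domain moves monotonically with
``u`` (legal hours shrink, density restrictions accumulate, tax rates
rise, marketing bans tighten while observed modes disappear, the BAC
limit tightens and breath-testing intensity grows), and recorded
consumption is ``APC = max(0, a - b*u + e)`` with Gaussian noise ``e``.
This makes the core assumption behind the index — that one
restrictiveness dimension drives consumption — an explicit, adjustable
ground truth: with ``noise_sd = 0`` and full coupling, index totals and
APC are perfectly anti-monotone; with ``policy_effect = 0`` any
association is spurious.

Impact measures are a convex blend ``coupling * (stringency-implied
value) + (1 - coupling) * (independent draw)``, mirroring the observed
tight coupling between legislation and the on-the-ground environment.

The generator also bundles the published 12-country domain-score table
as a fixture for the score-passthrough pipeline (the raw underlying
protocol data are not public).
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .records import (
    MARKETING_MODES,
    N_MARKETING_MODES,
    CountryRecord,
    DrinkDrivingRecord,
    MarketingRecord,
    OutletDensityRecord,
    PricingRecord,
    TradingHoursRecord,
)
from .scoring import DOMAINS

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "make_table2_fixture",
    "fixture_domain_points",
    "FIXTURE_DOMAIN_COLUMNS",
]

#: fixture column -> canonical domain name
FIXTURE_DOMAIN_COLUMNS = {
    "score_hours": "hours",
    "score_density": "density",
    "score_drink_driving": "drink_driving",
    "score_pricing": "pricing",
    "score_marketing": "marketing",
}


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study setting: a dozen heterogeneous
    countries, a strong protective policy effect spanning most of the
    observed APC range (litres of pure alcohol per capita 15+), modest
    country-level noise, and tight stringency–impact coupling.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_countries: int = Field(default=12, ge=3)
    seed: int = 0
    #: APC decrease (litres) per unit of latent restrictiveness.
    policy_effect: float = Field(default=9.0, ge=0.0)
    noise_sd: float = Field(default=1.0, ge=0.0)
    #: APC (litres) of a country with no restrictions at all.
    baseline_apc: float = Field(default=12.0, gt=0.0)
    #: 1 = impact measures fully determined by stringency; 0 = independent.
    stringency_impact_coupling: float = Field(default=0.8, ge=0.0, le=1.0)
    #: Which of the five domains' measures track the latent factor.
    domain_signal_mask: tuple[bool, bool, bool, bool, bool] = (True,) * 5


_DENSITY_FLAG_ORDER = ("on_number", "off_number", "on_area", "off_area", "on_location", "off_location")

# staggered thresholds: higher latent restrictiveness upgrades one mode at a time
_MARKETING_PARTIAL_AT = {m: 0.1 + 0.1 * i for i, m in enumerate(MARKETING_MODES)}
_MARKETING_TOTAL_AT = {m: 0.55 + 0.08 * i for i, m in enumerate(MARKETING_MODES)}

# common price coefficient so affordability is exactly monotone in the latent
# factor regardless of the beverage-share draw
_PRICE_OVER_GDP = 1e-4


def _blend(coupling: float, implied: float, independent: float) -> float:
    return coupling * implied + (1.0 - coupling) * independent


def _marketing_levels(u: float) -> dict[str, str]:
    levels = {}
    for m in MARKETING_MODES:
        if u >= _MARKETING_TOTAL_AT[m]:
            levels[m] = "total_ban"
        elif u >= _MARKETING_PARTIAL_AT[m]:
            levels[m] = "partial_ban"
        else:
            levels[m] = "none_or_self_regulation"
    return levels


def _bac_limit(u: float) -> Optional[float]:
    if u < 0.25:
        return None
    if u < 0.5:
        return 0.08
    if u < 0.75:
        return 0.04
    return 0.02


def generate_cohort(config: GeneratorConfig) -> list[CountryRecord]:
    """Draw a fully validated synthetic cohort, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    mask = dict(zip(DOMAINS, config.domain_signal_mask))
    c = config.stringency_impact_coupling
    cohort: list[CountryRecord] = []
    floored = []
    for i in range(config.n_countries):
        u = float(rng.uniform())
        # per-domain latent: the global factor where the domain carries
        # signal, an independent draw where it does not
        ud = {d: (u if mask[d] else float(rng.uniform())) for d in DOMAINS}

        # hours: legal opening shrinks with restrictiveness
        uh = ud["hours"]
        on_legal = 24.0 - 14.0 * uh
        off_legal = 24.0 - 10.0 * uh
        legal_7 = uh < 0.5
        on_actual = min(24.0, _blend(c, on_legal, float(rng.uniform(6.0, 24.0))))
        off_actual = min(24.0, _blend(c, off_legal, float(rng.uniform(6.0, 24.0))))
        actual_7 = legal_7 if rng.uniform() < c else bool(rng.uniform() < 0.5)
        hours = TradingHoursRecord(
            on_legal_hours=on_legal, on_legal_7days=legal_7,
            off_legal_hours=off_legal, off_legal_7days=legal_7,
            on_actual_hours=on_actual, on_actual_7days=actual_7,
            off_actual_hours=off_actual, off_actual_7days=actual_7,
        )

        k = int(6 * ud["density"])  # 0..6 restrictions accumulate
        density = OutletDensityRecord(
            **{f: (j < k) for j, f in enumerate(_DENSITY_FLAG_ORDER)}
        )

        up = ud["pricing"]
        gdp = float(np.exp(rng.normal(9.5, 1.0)))
        up_imp = _blend(c, up, float(rng.uniform()))
        price = gdp * _PRICE_OVER_GDP * (0.2 + 0.8 * up_imp)
        pricing = PricingRecord(
            tax_pct={"beer": 60.0 * up, "wine": 50.0 * up, "spirits": 70.0 * up},
            midprice_15ml={b: price for b in ("beer", "wine", "spirits")},
            gdp_per_capita=gdp,
        )

        um = ud["marketing"]
        um_imp = _blend(c, um, float(rng.uniform()))
        n_present = int(round(N_MARKETING_MODES * (1.0 - um_imp)))
        marketing = MarketingRecord(
            regulation_level=_marketing_levels(um),
            potency_differential=um > 0.7,
            modes_present=tuple(j < n_present for j in range(N_MARKETING_MODES)),
        )

        udd = ud["drink_driving"]
        udd_imp = _blend(c, udd, float(rng.uniform()))
        drink_driving = DrinkDrivingRecord(
            bac_limit=_bac_limit(udd),
            sobriety_checkpoints=udd > 0.3,
            random_breath_testing=udd > 0.45,
            zero_tolerance_professional=udd > 0.6,
            rbt_pct_vehicles_stopped=60.0 * udd_imp,
        )

        shares = rng.dirichlet([4.0, 3.0, 3.0])
        beverage_shares = {
            "beer": float(shares[0]),
            "wine": float(shares[1]),
            "spirits": float(1.0 - shares[0] - shares[1]),
        }

        apc = config.baseline_apc - config.policy_effect * u
        if config.noise_sd > 0:
            apc += float(rng.normal(0.0, config.noise_sd))
        if apc < 0:
            floored.append(f"country_{i:03d}")
            apc = 0.0

        cohort.append(
            CountryRecord(
                country_id=f"country_{i:03d}",
                hours=hours,
                density=density,
                pricing=pricing,
                marketing=marketing,
                drink_driving=drink_driving,
                beverage_shares=beverage_shares,
                recorded_apc=apc,
            )
        )
    if floored:
        warnings.warn(f"APC floored at 0 for {floored}", stacklevel=2)
    return cohort


def make_table2_fixture() -> pd.DataFrame:
    """The published 12-country domain-score table, verbatim.

    Columns: country_id, rank, five ``score_*`` domain-point columns
    and the printed total. Points are as printed (one decimal, already
    effectiveness-weighted).
    """
    ref = importlib.resources.files("iacindex.data").joinpath("table2_scores.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def fixture_domain_points(df: Optional[pd.DataFrame] = None) -> dict[str, dict[str, float]]:
    """Fixture rows as a {country: {domain: points}} passthrough mapping."""
    if df is None:
        df = make_table2_fixture()
    return {
        row["country_id"]: {
            dom: float(row[col]) for col, dom in FIXTURE_DOMAIN_COLUMNS.items()
        }
        for _, row in df.iterrows()
    }
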