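import numpy as np
import pytest

from iacindex import (
    CountryRecord,
    DrinkDrivingRecord,
    MarketingRecord,
    OutletDensityRecord,
    PricingRecord,
    TradingHoursRecord,
)
from iacindex.records import MARKETING_MODES, N_MARKETING_MODES


def make_record(
    country_id="testland",
    legal_hours=12.0,
    legal_7days=True,
    actual_hours=None,
    actual_7days=None,
    density_flags=3,
    tax=(20.0, 30.0, 50.0),
    prices=(2.0, 4.0, 6.0),
    gdp=20000.0,
    levels=("partial_ban",) * 5,
    potency=False,
    n_modes_present=7,
    bac=0.05,
    sobriety=False,
    rbt=True,
    zero_prof=True,
    rbt_pct=10.0,
    shares=(0.5, 0.3, 0.2),
    apc=8.0,
) -> CountryRecord:
    """Hand-buildable record with sensible defaults for unit tests."""
    if actual_hours is None:
        actual_hours = legal_hours
    if actual_7days is None:
        actual_7days = legal_7days
    flag_names = ("on_number", "on_area", "on_location", "off_number", "off_area", "off_location")
    return CountryRecord(
        country_id=country_id,
        hours=TradingHoursRecord(
            on_legal_hours=legal_hours, on_legal_7days=legal_7days,
            off_legal_hours=legal_hours, off_legal_7days=legal_7days,
            on_actual_hours=actual_hours, on_actual_7days=actual_7days,
            off_actual_hours=actual_hours, off_actual_7days=actual_7days,
        ),
        density=OutletDensityRecord(**{f: i < density_flags for i, f in enumerate(flag_names)}),
        pricing=PricingRecord(
            tax_pct=dict(zip(("beer", "wine", "spirits"), tax)),
            midprice_15ml=dict(zip(("beer", "wine", "spirits"), prices)),
            gdp_per_capita=gdp,
        ),
        marketing=MarketingRecord(
            regulation_level=dict(zip(MARKETING_MODES, levels)),
            potency_differential=potency,
            modes_present=tuple(i < n_modes_present for i in range(N_MARKETING_MODES)),
        ),
        drink_driving=DrinkDrivingRecord(
            bac_limit=bac,
            sobriety_checkpoints=sobriety,
            random_breath_testing=rbt,
            zero_tolerance_professional=zero_prof,
            rbt_pct_vehicles_stopped=rbt_pct,
        ),
        beverage_shares=dict(zip(("beer", "wine", "spirits"), shares)),
        recorded_apc=apc,
    )


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_cohort():
    """Three hand-built countries with distinct measures."""
    return [
        make_record("alpha", legal_hours=24, legal_7days=True, density_flags=0,
                    tax=(5, 5, 5), prices=(1, 1, 1), gdp=40000, rbt_pct=2.0, apc=11.0),
        make_record("bravo", legal_hours=12, legal_7days=True, density_flags=3,
                    tax=(20, 30, 50), prices=(2, 4, 6), gdp=20000, rbt_pct=10.0, apc=8.0),
        make_record("charlie", legal_hours=6, legal_7days=False, density_flags=6,
                    tax=(60, 60, 60), prices=(5, 5, 5), gdp=10000, rbt_pct=40.0, apc=4.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
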