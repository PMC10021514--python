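"""Domain scorers: frozen worked examples, bounds and monotonicity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iacindex import CohortContext, bac_category, compute_affordability, score_cohort
from iacindex.records import MARKETING_MODES, N_MARKETING_MODES
from iacindex.scoring import (
    score_density_stringency,
    score_drink_driving_impact,
    score_drink_driving_stringency,
    score_hours_impact,
    score_hours_stringency,
    score_marketing_impact,
    score_marketing_stringency,
    score_pricing_impact,
    score_pricing_stringency,
)

from conftest import make_record


def ctx(afford, rbt):
    return CohortContext(
        affordability={f"c{i}": v for i, v in enumerate(afford)},
        rbt_pct={f"c{i}": v for i, v in enumerate(rbt)},
    )


class TestHours:
    def test_least_restrictive_scores_zero(self):
        rec = make_record(legal_hours=24.0, legal_7days=True)
        assert score_hours_stringency(rec.hours) == 0.0
        assert score_hours_impact(rec.hours) == 0.0

    def test_most_restrictive_scores_one(self):
        rec = make_record(legal_hours=0.0, legal_7days=False)
        assert score_hours_stringency(rec.hours) == 1.0

    def test_half_day_seven_days_allowed(self):
        # mean(0.5, 0, 0.5, 0) over on/off premise
        rec = make_record(legal_hours=12.0, legal_7days=True)
        assert score_hours_stringency(rec.hours) == pytest.approx(0.25)

    def test_actual_eight_hours_not_seven_days(self):
        # mean(16/24, 1, 16/24, 1) = 5/6
        rec = make_record(legal_hours=24.0, actual_hours=8.0, actual_7days=False)
        assert score_hours_impact(rec.hours) == pytest.approx(5 / 6)

    def test_impact_equals_stringency_when_actual_equals_legal(self):
        rec = make_record(legal_hours=9.5, legal_7days=False)
        assert score_hours_impact(rec.hours) == score_hours_stringency(rec.hours)


class TestDensity:
    @pytest.mark.parametrize("flags,expected", [(0, 0.0), (3, 0.5), (6, 1.0)])
    def test_fraction_of_restrictions(self, flags, expected):
        rec = make_record(density_flags=flags)
        assert score_density_stringency(rec.density) == expected


class TestPricing:
    def test_weighted_tax_share(self):
        rec = make_record(shares=(0.5, 0.3, 0.2), tax=(20, 30, 50))
        assert score_pricing_stringency(
            rec.pricing, rec.beverage_shares
        ) == pytest.approx(0.29)

    def test_zero_tax_scores_zero(self):
        rec = make_record(tax=(0, 0, 0))
        assert score_pricing_stringency(rec.pricing, rec.beverage_shares) == 0.0

    def test_full_tax_on_only_beverage_scores_one(self):
        rec = make_record(shares=(1.0, 0.0, 0.0), tax=(100, 0, 0))
        assert score_pricing_stringency(rec.pricing, rec.beverage_shares) == pytest.approx(1.0)

    def test_affordability_worked_example(self):
        rec = make_record(shares=(0.5, 0.3, 0.2), prices=(2, 4, 6), gdp=20000)
        # (1.0 + 1.2 + 1.2) / 20000
        assert compute_affordability(rec.pricing, rec.beverage_shares) == pytest.approx(1.7e-4)

    def test_affordability_scale_invariant(self):
        a = make_record(prices=(2, 4, 6), gdp=20000)
        b = make_record(prices=(4, 8, 12), gdp=40000)
        assert compute_affordability(a.pricing, a.beverage_shares) == pytest.approx(
            compute_affordability(b.pricing, b.beverage_shares)
        )

    def test_zero_prices_give_zero_ratio(self):
        rec = make_record(prices=(0, 0, 0))
        assert compute_affordability(rec.pricing, rec.beverage_shares) == 0.0

    def test_impact_minmax_endpoints_and_midpoint(self):
        c = ctx(afford=[1e-4, 2e-4, 3e-4], rbt=[0, 1, 2])
        assert score_pricing_impact(1e-4, c) == 0.0
        assert score_pricing_impact(3e-4, c) == 1.0
        assert score_pricing_impact(2e-4, c) == pytest.approx(0.5)

    def test_degenerate_spread_scores_half_with_warning(self):
        c = ctx(afford=[2e-4, 2e-4], rbt=[0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            assert score_pricing_impact(2e-4, c) == pytest.approx(0.5)


class TestMarketing:
    def test_total_bans_plus_potency_score_one(self):
        rec = make_record(levels=("total_ban",) * 5, potency=True)
        assert score_marketing_stringency(rec.marketing) == 1.0

    def test_no_regulation_scores_zero(self):
        rec = make_record(levels=("none_or_self_regulation",) * 5, potency=False)
        assert score_marketing_stringency(rec.marketing) == 0.0

    def test_partial_bans_score_five_elevenths(self):
        rec = make_record(levels=("partial_ban",) * 5, potency=False)
        assert score_marketing_stringency(rec.marketing) == pytest.approx(5 / 11)

    @pytest.mark.parametrize("present,expected", [(25, 0.0), (0, 1.0), (7, 0.72)])
    def test_impact_is_absent_modes_over_25(self, present, expected):
        rec = make_record(n_modes_present=present)
        assert score_marketing_impact(rec.marketing) == pytest.approx(expected)

    def test_impact_affine_in_presence_count(self):
        scores = [
            score_marketing_impact(make_record(n_modes_present=k).marketing)
            for k in range(N_MARKETING_MODES + 1)
        ]
        diffs = {round(b - a, 12) for a, b in zip(scores, scores[1:])}
        assert diffs == {round(-1 / 25, 12)}


class TestDrinkDriving:
    @pytest.mark.parametrize(
        "bac,expected",
        [
            (None, 0),
            (0.08, 1),
            (0.05, 1),  # boundary: "0.05% or above"
            (0.04, 2),
            (0.03, 2),  # boundary of the middle band
            (0.02, 3),
            (0.0, 3),
        ],
    )
    def test_bac_category(self, bac, expected):
        assert bac_category(bac) == expected

    def test_no_limit_no_enforcement_scores_zero(self):
        rec = make_record(bac=None, sobriety=False, rbt=False, zero_prof=False)
        assert score_drink_driving_stringency(rec.drink_driving) == 0.0

    def test_strictest_everything_scores_one(self):
        rec = make_record(bac=0.0, sobriety=True, rbt=True, zero_prof=True)
        assert score_drink_driving_stringency(rec.drink_driving) == 1.0

    def test_mid_example(self):
        # BAC 0.05 (1) + RBT (1) + zero tolerance (1) = 3/6
        rec = make_record(bac=0.05, sobriety=False, rbt=True, zero_prof=True)
        assert score_drink_driving_stringency(rec.drink_driving) == pytest.approx(0.5)

    def test_impact_minmax(self):
        c = ctx(afford=[1, 2], rbt=[2.0, 10.0, 40.0])
        assert score_drink_driving_impact(2.0, c) == 0.0
        assert score_drink_driving_impact(40.0, c) == 1.0
        assert score_drink_driving_impact(21.0, c) == 0.5


class TestWholeCohort:
    def test_score_cohort_structure(self, small_cohort):
        scored = score_cohort(small_cohort)
        assert set(scored) == {"alpha", "bravo", "charlie"}
        for per_domain in scored.values():
            assert set(per_domain) == {"hours", "density", "pricing", "marketing", "drink_driving"}
            n_components = sum(
                1 + (s.impact is not None) for s in per_domain.values()
            )
            assert n_components == 9

    def test_extremes_hit_bounds(self):
        top = make_record(
            "top", legal_hours=0.0, legal_7days=False, density_flags=6,
            tax=(100, 100, 100), prices=(9, 9, 9), gdp=1000,
            levels=("total_ban",) * 5, potency=True, n_modes_present=0,
            bac=0.0, sobriety=True, rbt=True, zero_prof=True, rbt_pct=90.0, apc=1.0,
        )
        bottom = make_record(
            "bottom", legal_hours=24.0, legal_7days=True, density_flags=0,
            tax=(0, 0, 0), prices=(0, 0, 0), gdp=1000,
            levels=("none_or_self_regulation",) * 5, potency=False, n_modes_present=25,
            bac=None, sobriety=False, rbt=False, zero_prof=False, rbt_pct=0.0, apc=12.0,
        )
        scored = score_cohort([top, bottom])
        for s in scored["top"].values():
            assert s.stringency == 1.0 and s.impact in (1.0, None)
        for s in scored["bottom"].values():
            assert s.stringency == 0.0 and s.impact in (0.0, None)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        legal_hours=st.floats(0, 24),
        legal_7days=st.booleans(),
        density_flags=st.integers(0, 6),
        tax=st.tuples(*[st.floats(0, 100)] * 3),
        n_modes=st.integers(0, 25),
        bac=st.one_of(st.none(), st.floats(0, 0.2)),
        rbt_pct=st.floats(0, 100),
    )
    def test_all_scores_within_unit_interval(
        self, legal_hours, legal_7days, density_flags, tax, n_modes, bac, rbt_pct
    ):
        rec = make_record(
            legal_hours=legal_hours, legal_7days=legal_7days,
            density_flags=density_flags, tax=tax, n_modes_present=n_modes,
            bac=bac, rbt_pct=rbt_pct,
        )
        other = make_record("other")
        scored = score_cohort([rec, other])  # DomainScore validates [0, 1]
        for s in scored["testland"].values():
            assert 0.0 <= s.stringency <= 1.0
            assert s.impact is None or 0.0 <= s.impact <= 1.0

    def test_adding_restrictions_never_decreases_scores(self):
        base = make_record(density_flags=2, tax=(10, 10, 10), n_modes_present=20, bac=0.08)
        stricter = make_record(density_flags=4, tax=(30, 30, 30), n_modes_present=15, bac=0.02)
        b, s = score_cohort([base]), score_cohort([stricter])
        for d in ("density", "pricing", "marketing", "drink_driving"):
            assert s["testland"][d].stringency >= b["testland"][d].stringency
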