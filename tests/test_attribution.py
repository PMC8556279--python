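import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roadpm import (
    AttributionResult,
    ContributionSurface,
    ConversionConstants,
    CountyPanel,
    MortalityPanel,
    attributable_deaths,
    clamp_contribution,
    co2_to_mileage,
    contribution,
    mileage_per_unit_pm25,
    propagate_mortality,
)


class StubGTWRFit:
    """Minimal stand-in exposing local CO2 coefficients per county-year."""

    def __init__(self, frame: pd.DataFrame):
        self._s = frame.set_index(["county_id", "year"])["beta"]

    def coefficients(self, regressor):
        assert regressor == "co2_per_km2"
        return self._s


def make_panel(rows):
    df = pd.DataFrame(rows)
    df["x"] = 0.0
    df["y"] = 0.0
    return CountyPanel(df)


class TestMileageConversion:
    def test_one_mile_by_definition(self):
        assert co2_to_mileage(404e-6) == pytest.approx(1.61)

    def test_million_tons_equals_about_3_99_billion_km(self):
        gkm = co2_to_mileage(1e6) / 1e9
        assert round(gkm, 2) == 3.99

    def test_zero_and_negative(self):
        assert co2_to_mileage(0.0) == 0.0
        with pytest.raises(ValueError):
            co2_to_mileage(-1.0)

    def test_headline_slope_and_interval(self):
        assert round(mileage_per_unit_pm25(0.646), 2) == 6.17
        assert round(mileage_per_unit_pm25(0.699), 2) == 5.70
        assert round(mileage_per_unit_pm25(0.593), 2) == pytest.approx(6.72, abs=0.011)

    def test_strictly_decreasing_in_beta(self):
        grid = np.linspace(0.05, 5.0, 60)
        vals = [mileage_per_unit_pm25(b) for b in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert mileage_per_unit_pm25(1e9) < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mileage_per_unit_pm25(0.0)
        with pytest.raises(ValueError):
            ConversionConstants(grams_co2_per_mile=0.0)


class TestContribution:
    def _surface(self, beta, co2, pm25):
        panel = make_panel(
            {"county_id": ["a"], "year": [2010], "pm25": [pm25], "co2_per_km2": [co2]}
        )
        fit = StubGTWRFit(
            pd.DataFrame({"county_id": ["a"], "year": [2010], "beta": [beta]})
        )
        return contribution(fit, panel)

    def test_share_arithmetic(self):
        assert self._surface(0.5, 2.0, 10.0).df["con_raw"][0] == pytest.approx(10.0)
        assert self._surface(0.0, 5.0, 10.0).df["con_raw"][0] == 0.0

    def test_negative_coefficient_clamped_to_zero(self):
        s = self._surface(-0.2, 1.0, 10.0)
        assert s.df["con_raw"][0] == pytest.approx(-2.0)
        assert s.df["con_clamped"][0] == 0.0

    def test_nonpositive_concentration_names_offender(self):
        with pytest.raises(ValueError, match="a/2010"):
            self._surface(0.5, 1.0, 0.0)

    def test_period_mean_averaging(self):
        panel = make_panel(
            {
                "county_id": ["a", "a"],
                "year": [2010, 2011],
                "pm25": [10.0, 10.0],
                "co2_per_km2": [1.0, 3.0],
            }
        )
        fit = StubGTWRFit(
            pd.DataFrame(
                {"county_id": ["a", "a"], "year": [2010, 2011], "beta": [1.0, 1.0]}
            )
        )
        s = contribution(fit, panel, co2_averaging="period-mean")
        assert s.df["con_raw"].to_numpy() == pytest.approx([20.0, 20.0])


class TestClamp:
    @pytest.mark.parametrize("raw,expected", [(-5.0, 0.0), (37.765, 37.765), (150.0, 100.0)])
    def test_branches(self, raw, expected):
        s = ContributionSurface(
            pd.DataFrame({"county_id": ["a"], "year": [2010], "con_raw": [raw]})
        )
        assert clamp_contribution(s).df["con_clamped"][0] == pytest.approx(expected)

    @given(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_clamped_in_range_and_idempotent(self, raw):
        s = ContributionSurface(
            pd.DataFrame({"county_id": ["a"], "year": [2010], "con_raw": [raw]})
        )
        once = clamp_contribution(s)
        assert 0.0 <= once.df["con_clamped"][0] <= 100.0
        twice = clamp_contribution(once)
        assert twice.df["con_clamped"][0] == once.df["con_clamped"][0]


def two_county_panel():
    years = list(range(2004, 2011))
    rows = []
    pm = {"a": [10, 11, 12, 11.5, 10, 9, 9.5], "b": [8, 8.5, 9, 9, 8, 7.5, 8]}
    for cid in ("a", "b"):
        for yr, v in zip(years, pm[cid]):
            rows.append(
                {"county_id": cid, "year": yr, "pm25": v, "co2_per_km2": 0.01}
            )
    return make_panel(rows)


class TestPropagation:
    def test_forward_step_arithmetic(self):
        panel = make_panel(
            {
                "county_id": ["a", "a"],
                "year": [2010, 2011],
                "pm25": [10.0, 11.0],
                "co2_per_km2": [0.0, 0.0],
            }
        )
        base = MortalityPanel(
            pd.DataFrame({"county_id": ["a"], "year": [2010], "map_deaths": [1000.0]})
        )
        out = propagate_mortality(base, panel, cpd=0.012)
        got = out.df.set_index("year")["map_deaths"]
        assert got.loc[2011] == pytest.approx(1012.0)

    def test_constant_concentration_constant_series(self):
        panel = make_panel(
            {
                "county_id": ["a"] * 4,
                "year": [2008, 2009, 2010, 2011],
                "pm25": [9.0] * 4,
                "co2_per_km2": [0.0] * 4,
            }
        )
        base = MortalityPanel(
            pd.DataFrame({"county_id": ["a"], "year": [2009], "map_deaths": [500.0]})
        )
        out = propagate_mortality(base, panel)
        assert out.df["map_deaths"].to_numpy() == pytest.approx([500.0] * 4)

    def test_forward_backward_round_trip(self):
        panel = two_county_panel()
        base = MortalityPanel(
            pd.DataFrame(
                {"county_id": ["a", "b"], "year": [2007, 2007], "map_deaths": [800.0, 300.0]}
            )
        )
        full = propagate_mortality(base, panel, cpd=0.012, anchor_year=2007)
        # re-anchor at the last year and propagate back
        tail = MortalityPanel(full.df[full.df["year"] == 2010])
        back = propagate_mortality(tail, panel, cpd=0.012, anchor_year=2010)
        a = full.df.set_index(["county_id", "year"])["map_deaths"]
        b = back.df.set_index(["county_id", "year"])["map_deaths"]
        assert np.max(np.abs(a - b) / a) < 1e-9

    def test_degenerate_jump_raises(self):
        panel = make_panel(
            {
                "county_id": ["a", "a"],
                "year": [2010, 2011],
                "pm25": [10.0, 500.0],
                "co2_per_km2": [0.0, 0.0],
            }
        )
        base = MortalityPanel(
            pd.DataFrame({"county_id": ["a"], "year": [2011], "map_deaths": [100.0]})
        )
        with pytest.raises(ValueError, match="degenerate"):
            propagate_mortality(base, panel, cpd=-0.012, anchor_year=2011)

    def test_national_level_matches_totals_shape(self):
        panel = two_county_panel()
        base = MortalityPanel(
            pd.DataFrame(
                {"county_id": ["a", "b"], "year": [2007, 2007], "map_deaths": [800.0, 200.0]}
            )
        )
        out = propagate_mortality(base, panel, anchor_year=2007, level="national")
        anchor = out.df[out.df["year"] == 2007].set_index("county_id")["map_deaths"]
        assert anchor["a"] == pytest.approx(800.0)
        assert anchor["b"] == pytest.approx(200.0)


class TestAttributableDeaths:
    def _result(self, maps, cons):
        years = list(range(2010, 2010 + len(maps)))
        m = MortalityPanel(
            pd.DataFrame(
                {"county_id": ["a"] * len(maps), "year": years, "map_deaths": maps}
            )
        )
        s = ContributionSurface(
            pd.DataFrame(
                {
                    "county_id": ["a"] * len(cons),
                    "year": years,
                    "con_raw": cons,
                    "con_clamped": cons,
                }
            )
        )
        return attributable_deaths(m, s)

    def test_printed_share_arithmetic(self):
        res = self._result([54730.0], [3605.0 / 54730.0 * 100])
        assert round(res.yearly["pta_pct"][0], 2) == 6.59

    def test_zero_and_full_contribution(self):
        res0 = self._result([100.0, 200.0], [0.0, 0.0])
        assert res0.pta_pooled_pct == 0.0
        res1 = self._result([100.0, 200.0], [100.0, 100.0])
        assert res1.yearly["mapor_total"].to_numpy() == pytest.approx([100.0, 200.0])
        assert res1.pta_pooled_pct == pytest.approx(100.0)

    def test_pooled_is_ratio_of_sums_not_mean_of_ratios(self):
        # year 1: 10% of 1000; year 2: 50% of 100 -> pooled (100+50)/1100
        res = self._result([1000.0, 100.0], [10.0, 50.0])
        pooled = res.pta_pooled_pct
        mean_of_years = res.yearly["pta_pct"].mean()
        assert pooled == pytest.approx(150.0 / 1100.0 * 100)
        assert abs(pooled - mean_of_years) > 5.0

    def test_mapor_never_exceeds_map(self):
        rng = np.random.default_rng(3)
        maps = rng.uniform(10, 1000, 12)
        cons = rng.uniform(0, 100, 12)
        res = self._result(list(maps), list(cons))
        assert (res.county_year["mapor_deaths"] <= res.county_year["map_deaths"] + 1e-12).all()

    def test_misalignment_errors(self):
        m = MortalityPanel(
            pd.DataFrame({"county_id": ["a"], "year": [2010], "map_deaths": [10.0]})
        )
        s = ContributionSurface(
            pd.DataFrame(
                {"county_id": ["b"], "year": [2010], "con_raw": [5.0], "con_clamped": [5.0]}
            )
        )
        with pytest.raises(ValueError, match="misaligned"):
            attributable_deaths(m, s)

    def test_invariant_to_county_reordering(self):
        m_df = pd.DataFrame(
            {
                "county_id": ["a", "b", "a", "b"],
                "year": [2010, 2010, 2011, 2011],
                "map_deaths": [100.0, 50.0, 90.0, 60.0],
            }
        )
        s_df = pd.DataFrame(
            {
                "county_id": ["a", "b", "a", "b"],
                "year": [2010, 2010, 2011, 2011],
                "con_raw": [10.0, 20.0, 30.0, 40.0],
                "con_clamped": [10.0, 20.0, 30.0, 40.0],
            }
        )
        r1 = attributable_deaths(MortalityPanel(m_df), ContributionSurface(s_df))
        perm = [3, 0, 2, 1]
        r2 = attributable_deaths(
            MortalityPanel(m_df.iloc[perm]), ContributionSurface(s_df.iloc[perm])
        )
        assert r1.pta_pooled_pct == pytest.approx(r2.pta_pooled_pct)
        assert r1.yearly["mapor_total"].to_numpy() == pytest.approx(
            r2.yearly["mapor_total"].to_numpy()
        )

    def test_summary_prints_pooled_share(self):
        res = self._result([100.0], [25.0])
        assert "25.00%" in res.summary()
        assert isinstance(res, AttributionResult)
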