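"""Composition shares, ratio series, peak detection, piecewise fits."""

import numpy as np
import pandas as pd
import pytest

from pmforge import (
    carbon_shares,
    component_ratio_series,
    fine_coarse_ratio,
    kuznets_peak,
    piecewise_dependence,
    size_shares,
)


def emission_table(rows):
    """rows: (year, species, value) in an arbitrary single sector/source."""
    return pd.DataFrame(
        [(y, "sec", "src", sp, v) for y, sp, v in rows],
        columns=["year", "sector", "source", "species", "emission_g"],
    )


class TestSizeShares:
    def test_iron_steel_style_profile(self):
        # 21 : 12 : 67 masses normalize to exactly those percentage shares
        t = emission_table([(1960, "PM2.5", 21.0), (1960, "PM2.5-10", 12.0), (1960, "PM>10", 67.0)])
        p = size_shares(t, 1960)
        assert p.shares == pytest.approx((0.21, 0.12, 0.67))
        assert sum(p.shares) == pytest.approx(1.0, abs=1e-12)

    def test_equal_masses_give_thirds(self):
        t = emission_table([(2000, sp, 5.0) for sp in ("PM2.5", "PM2.5-10", "PM>10")])
        assert size_shares(t, 2000).shares == pytest.approx((1 / 3,) * 3)

    def test_total_2019_style_profile(self):
        t = emission_table([(2019, "PM2.5", 41.0), (2019, "PM2.5-10", 17.0), (2019, "PM>10", 42.0)])
        assert size_shares(t, 2019).shares == pytest.approx((0.41, 0.17, 0.42))

    def test_zero_total_flagged_undefined(self):
        t = emission_table([(2000, sp, 0.0) for sp in ("PM2.5", "PM2.5-10", "PM>10")])
        assert not size_shares(t, 2000).defined

    def test_scale_invariance(self, default_emissions):
        a = size_shares(default_emissions, 1995)
        scaled = default_emissions.assign(emission_g=default_emissions["emission_g"] * 17.0)
        b = size_shares(scaled, 1995)
        assert b.shares == pytest.approx(a.shares, rel=1e-12)


class TestCarbonShares:
    def test_no_carbon_is_all_noncarbonaceous(self):
        t = emission_table([(2000, "PM2.5", 3.0), (2000, "BC", 0.0), (2000, "OC", 0.0)])
        assert carbon_shares(t, 2000).shares == pytest.approx((0.0, 0.0, 1.0))

    def test_oc_share_complement(self):
        # OC share 38.8% with BC 15% leaves 46.2% non-carbonaceous; the
        # combined BC + non-carbonaceous share is 61.2%
        t = emission_table([(1960, "PM2.5", 1.0), (1960, "BC", 0.15), (1960, "OC", 0.388)])
        p = carbon_shares(t, 1960)
        assert p.shares[2] == pytest.approx(0.462)
        assert p.shares[0] + p.shares[2] == pytest.approx(0.612)

    def test_carbon_saturated_boundary(self):
        t = emission_table([(2000, "PM2.5", 2.0), (2000, "BC", 1.0), (2000, "OC", 1.0)])
        assert carbon_shares(t, 2000).shares == pytest.approx((0.5, 0.5, 0.0))

    def test_carbon_exceeding_pm25_is_error(self):
        t = emission_table([(2000, "PM2.5", 1.0), (2000, "BC", 0.8), (2000, "OC", 0.8)])
        with pytest.raises(ValueError, match="exceeds PM2.5"):
            carbon_shares(t, 2000)


class TestRatioSeries:
    def test_fine_coarse_consistent_with_shares(self, default_emissions):
        ratio = fine_coarse_ratio(default_emissions)
        for year in (1960, 1995, 2019):
            p = size_shares(default_emissions, year)
            a, b, c = p.shares
            assert ratio.loc[year] == pytest.approx(a / (b + c), rel=1e-12)

    def test_2019_style_shares_give_point_seven(self):
        t = emission_table([(2019, "PM2.5", 41.0), (2019, "PM2.5-10", 17.0), (2019, "PM>10", 42.0)])
        # 0.41/0.59 = 0.6949, i.e. ~0.70 once input rounding is allowed for
        assert fine_coarse_ratio(t).loc[2019] == pytest.approx(0.41 / 0.59, rel=1e-9)
        assert fine_coarse_ratio(t).loc[2019] == pytest.approx(0.70, abs=0.01)

    def test_gt10_convention_option(self):
        t = emission_table([(2019, "PM2.5", 41.0), (2019, "PM2.5-10", 17.0), (2019, "PM>10", 42.0)])
        assert fine_coarse_ratio(t, convention="gt10").loc[2019] == pytest.approx(41 / 42)

    def test_zero_coarse_is_undefined(self):
        t = emission_table([(2000, "PM2.5", 1.0), (2000, "PM2.5-10", 0.0), (2000, "PM>10", 0.0)])
        assert np.isnan(fine_coarse_ratio(t).loc[2000])

    def test_equal_sizes_give_half(self):
        t = emission_table([(2000, sp, 2.0) for sp in ("PM2.5", "PM2.5-10", "PM>10")])
        assert fine_coarse_ratio(t).loc[2000] == pytest.approx(0.5)

    def test_constant_oc_fraction_recovered(self):
        rows = []
        for y in range(2000, 2005):
            pm = 10.0 + y - 2000
            rows += [(y, "PM2.5", pm), (y, "OC", 0.38 * pm), (y, "BC", 0.1 * pm)]
        t = emission_table(rows)
        s = component_ratio_series(t, "OC")
        assert np.allclose(s.to_numpy(), 0.38)

    def test_component_ratio_bounded_on_scenario(self, default_emissions):
        for comp in ("BC", "OC"):
            s = component_ratio_series(default_emissions, comp)
            assert ((s >= 0) & (s <= 1)).all()


class TestKuznetsPeak:
    def gdp(self, years):
        return pd.Series(1000.0 * 1.05 ** (np.arange(len(years))), index=years)

    def test_monotone_series_flags_boundary(self):
        years = pd.Index(range(1990, 2001))
        em = pd.Series(np.arange(11, dtype=float), index=years)
        res = kuznets_peak(em, self.gdp(years))
        assert res.peak_year == 2000
        assert res.boundary

    def test_triangle_apex_recovered(self):
        years = pd.Index(range(1990, 2001))
        em = pd.Series([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], index=years, dtype=float)
        res = kuznets_peak(em, self.gdp(years))
        assert res.peak_year == 1995
        assert res.peak_value == 5.0
        assert res.gdp_at_peak == pytest.approx(self.gdp(years).loc[1995])
        assert not res.boundary

    def test_tie_breaks_to_earliest_year(self):
        years = pd.Index(range(1990, 1995))
        em = pd.Series([1.0, 4.0, 4.0, 2.0, 1.0], index=years)
        assert kuznets_peak(em, self.gdp(years)).peak_year == 1991

    def test_empty_series_rejected(self):
        empty = pd.Series(dtype=float)
        with pytest.raises(ValueError, match="empty"):
            kuznets_peak(empty, empty)


class TestPiecewiseDependence:
    def years(self):
        return pd.Index(range(1988, 2003))

    def test_globally_linear_relation(self):
        x = pd.Series(np.linspace(1, 10, 15), index=self.years())
        y = 2.0 * x
        fit = piecewise_dependence(x, y, breakpoint_year=1995)
        assert fit["pre"].slope == pytest.approx(2.0)
        assert fit["post"].slope == pytest.approx(2.0)
        assert fit["pre"].r == pytest.approx(1.0)
        assert fit["pooled_r"] == pytest.approx(1.0)

    def test_noiseless_broken_slopes_recovered(self):
        years = self.years()
        x = pd.Series(np.linspace(1, 10, 15), index=years)
        y = x.copy()
        pre = years <= 1995
        y[pre] = 3.0 * x[pre]
        y[~pre] = 1.0 * x[~pre] + 5.0
        fit = piecewise_dependence(x, y, breakpoint_year=1995)
        assert fit["pre"].slope == pytest.approx(3.0)
        assert fit["post"].slope == pytest.approx(1.0)

    def test_single_regime_pools_tighter_than_broken(self):
        rng = np.random.default_rng(0)
        years = self.years()
        x = pd.Series(np.linspace(1, 10, 15), index=years)
        noise = rng.normal(0, 0.05, 15)
        linear = 2 * x + noise
        broken = linear.copy()
        broken[years <= 1995] = 5 * x[years <= 1995] + noise[: (years <= 1995).sum()]
        r_linear = piecewise_dependence(x, linear)["pooled_r"]
        r_broken = piecewise_dependence(x, broken)["pooled_r"]
        assert r_linear > r_broken

    def test_short_segment_rejected_by_name(self):
        years = pd.Index([1994, 1995, 1996, 1997, 1998])
        x = pd.Series(np.arange(5.0), index=years)
        with pytest.raises(ValueError, match="pre"):
            piecewise_dependence(x, x, breakpoint_year=1995)
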