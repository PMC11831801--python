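"""Trend and composition metrics for size- and carbon-resolved PM emissions.

Ternary composition shares (size triple PM2.5 : PM2.5-10 : PM>10 and
carbon triple BC : OC : non-carbonaceous PM2.5), fine/coarse ratio
series, BC/OC-to-PM2.5 ratio series, environmental-Kuznets-curve peak
detection against a GDP-per-capita series, and piecewise linear
dependence diagnostics around a breakpoint year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pmforge.core_inventory import species_series

_SIZE_SPECIES = ("PM2.5", "PM2.5-10", "PM>10")


@dataclass(frozen=True)
class TernaryPoint:
    """One year's three-part composition (shares sum to 1 when defined)."""

    year: int
    labels: tuple[str, str, str]
    shares: tuple[float, float, float]
    total: float  # annual mass of the triple's denominator, grams
    defined: bool = True


@dataclass(frozen=True)
class PeakResult:
    """Kuznets-curve apex of an emission series."""

    peak_year: int
    peak_value: float
    gdp_at_peak: float
    boundary: bool  # True when the argmax sits on the first/last year


@dataclass(frozen=True)
class SegmentFit:
    slope: float
    intercept: float
    r: float


def _scope_total(table: pd.DataFrame, species: str, scope: str | None, year: int) -> float:
    sub = table[(table["species"] == species) & (table["year"] == year)]
    if scope is not None:
        sub = sub[sub["sector"] == scope]
    return float(sub["emission_g"].sum())


def size_shares(table: pd.DataFrame, year: int, scope: str | None = None) -> TernaryPoint:
    """Mass shares of the size triple PM2.5 : PM2.5-10 : PM>10.

    ``scope`` is a sector label, or ``None`` for the all-sector total.
    Shares are the three species totals normalized by their sum, so they
    close to exactly 1; a zero total yields an undefined point.
    """
    vals = [_scope_total(table, sp, scope, year) for sp in _SIZE_SPECIES]
    total = sum(vals)
    if total <= 0:
        return TernaryPoint(year, _SIZE_SPECIES, (np.nan,) * 3, total, defined=False)
    return TernaryPoint(year, _SIZE_SPECIES, tuple(v / total for v in vals), total)


def carbon_shares(table: pd.DataFrame, year: int, scope: str | None = None) -> TernaryPoint:
    """Shares of BC : OC : non-carbonaceous PM2.5 within the PM2.5 mass."""
    labels = ("BC", "OC", "non-carbonaceous-PM2.5")
    pm25 = _scope_total(table, "PM2.5", scope, year)
    bc = _scope_total(table, "BC", scope, year)
    oc = _scope_total(table, "OC", scope, year)
    if pm25 <= 0:
        return TernaryPoint(year, labels, (np.nan,) * 3, pm25, defined=False)
    if bc + oc > pm25 * (1 + 1e-9):
        raise ValueError(
            f"BC + OC ({bc + oc:.6g} g) exceeds PM2.5 ({pm25:.6g} g) in {year}; "
            "upstream carbon-bound invariant is broken"
        )
    return TernaryPoint(year, labels, (bc / pm25, oc / pm25, (pm25 - bc - oc) / pm25), pm25)


def fine_coarse_ratio(
    table: pd.DataFrame,
    scope: str | None = None,
    convention: str = "coarse_sum",
) -> pd.Series:
    """Yearly fine/coarse emission ratio series.

    ``convention='coarse_sum'`` (default) divides PM2.5 by PM>2.5, the
    sum of PM2.5-10 and PM>10 — the definition under which the 2019
    size fractions 41:17:42 give a ratio of about 0.70.
    ``convention='gt10'`` divides by PM>10 alone. Years with a zero
    denominator are flagged undefined as NaN.
    """
    fine = species_series(table, "PM2.5", scope)
    mid = species_series(table, "PM2.5-10", scope)
    coarse = species_series(table, "PM>10", scope)
    if convention == "coarse_sum":
        denom = mid.add(coarse, fill_value=0.0)
    elif convention == "gt10":
        denom = coarse
    else:
        raise ValueError(f"unknown convention {convention!r}")
    denom = denom.reindex(fine.index)
    return fine / denom.where(denom > 0)


def component_ratio_series(
    table: pd.DataFrame, numerator: str = "OC", scope: str | None = None
) -> pd.Series:
    """Yearly BC/PM2.5 or OC/PM2.5 ratio (NaN where PM2.5 is zero)."""
    if numerator not in ("BC", "OC"):
        raise ValueError("numerator must be 'BC' or 'OC'")
    num = species_series(table, numerator, scope)
    pm25 = species_series(table, "PM2.5", scope).reindex(num.index)
    return num / pm25.where(pm25 > 0)


def kuznets_peak(
    emissions: pd.Series,
    gdp_per_capita: pd.Series,
    smooth: bool = False,
) -> PeakResult:
    """Locate the emission apex along the development axis.

    ``emissions`` and ``gdp_per_capita`` are year-indexed series over
    the same span. The peak year is the argmax of the (optionally
    3-year centered moving-average smoothed) emission series, earliest
    year on ties; ``boundary`` marks an argmax on the span edge, i.e. no
    interior inverted-U apex. The reported peak value is always from the
    raw series.
    """
    if len(emissions) == 0:
        raise ValueError("empty emission series")
    if not emissions.index.equals(gdp_per_capita.index):
        raise ValueError("emission and GDP series must share the same year index")
    series = emissions.astype(float)
    scan = series.rolling(3, center=True, min_periods=1).mean() if smooth else series
    peak_year = int(scan.idxmax())  # idxmax returns the first maximal year
    years = list(series.index)
    boundary = peak_year in (years[0], years[-1])
    return PeakResult(
        peak_year=peak_year,
        peak_value=float(series.loc[peak_year]),
        gdp_at_peak=float(gdp_per_capita.loc[peak_year]),
        boundary=boundary,
    )


def piecewise_dependence(
    x: pd.Series,
    y: pd.Series,
    breakpoint_year: int = 1995,
) -> dict:
    """Two-segment OLS dependence of ``y`` on ``x`` around a breakpoint year.

    Segments are years <= breakpoint and years > breakpoint, each fitted
    by independent ordinary least squares (no continuity constraint at
    the break) with its Pearson correlation, plus the pooled correlation
    over all years. Each segment needs at least 3 points.
    """
    if not x.index.equals(y.index):
        raise ValueError("x and y series must share the same year index")
    years = x.index.to_numpy()
    result: dict[str, object] = {}
    for name, mask in (
        ("pre", years <= breakpoint_year),
        ("post", years > breakpoint_year),
    ):
        if mask.sum() < 3:
            raise ValueError(
                f"segment {name!r} ({'<=' if name == 'pre' else '>'} {breakpoint_year}) "
                f"has {int(mask.sum())} points; need >= 3"
            )
        fit = stats.linregress(x.to_numpy()[mask], y.to_numpy()[mask])
        result[name] = SegmentFit(float(fit.slope), float(fit.intercept), float(fit.rvalue))
    pooled = stats.pearsonr(x.to_numpy(), y.to_numpy())
    result["pooled_r"] = float(pooled.statistic)
    return result
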