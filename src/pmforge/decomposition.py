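"""Exact-additive structural decomposition of emission changes into drivers.

Emissions are expressed per cell (source, technology) as a product of
named factors, e.g. ``E = activity * technology_mix * emission_factor *
control``, and the change in the aggregate E between two snapshots is
attributed to the factors with the Shapley (Sun) decomposition: each
factor's effect is its marginal contribution to the change averaged over
all orders in which the factors could be switched from their start to
their end values. The effects are exactly additive (they sum to the
total change), symmetric in the factor labels, and remain finite when a
factor is zero in one snapshot — the situation whenever a technology
phases in or out — which is why this variant is used rather than a
log-mean Divisia index.

Annual steps are decomposed one by one and summed, so the cumulative
effect of each driver since the baseline year is available for every
year of the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pmforge.core_inventory import G_PER_TG

_MAX_FACTORS = 8  # K! / 2^K growth guard

DEFAULT_FACTORS = ("activity", "technology_mix", "emission_factor", "control")


@dataclass
class FactorPanel:
    """Multiplicative factor series on a common cell grid.

    ``data`` maps each factor name to a DataFrame whose index is the cell
    key (e.g. a (source, technology) MultiIndex) and whose columns are
    the years. Cell emissions in year *y* are the row-wise product of all
    factors at column *y*; the aggregate is their sum over cells.
    """

    data: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.data)
        if not names:
            raise ValueError("FactorPanel needs at least one factor")
        ref = self.data[names[0]]
        for name in names[1:]:
            df = self.data[name]
            if not df.index.equals(ref.index) or not df.columns.equals(ref.columns):
                raise ValueError(f"factor {name!r} is not aligned with {names[0]!r}")
        for name, df in self.data.items():
            if (df.to_numpy() < 0).any():
                raise ValueError(f"factor {name!r} has negative values")

    @property
    def factor_names(self) -> list[str]:
        return list(self.data)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in next(iter(self.data.values())).columns]

    def snapshot(self, year: int) -> dict[str, np.ndarray]:
        """Per-factor cell-value vectors at one year."""
        return {name: df[year].to_numpy(float) for name, df in self.data.items()}

    def emissions(self, year: int) -> float:
        """Aggregate emission at one year: sum over cells of the factor product."""
        snap = self.snapshot(year)
        prod = np.ones_like(next(iter(snap.values())))
        for v in snap.values():
            prod = prod * v
        return float(prod.sum())

    def emission_series(self) -> pd.Series:
        return pd.Series({y: self.emissions(y) for y in self.years})


def _aggregate(snapshot: Mapping[str, np.ndarray]) -> float:
    prod = None
    for v in snapshot.values():
        prod = v if prod is None else prod * v
    return float(np.asarray(prod).sum())


def shapley_step(
    factors_at_t0: Mapping[str, np.ndarray],
    factors_at_t1: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Shapley-attributed additive effect of each factor for one step.

    Each mapping gives, per factor name, the vector of cell values at the
    start (t0) and end (t1) of the step. The effect of factor *k* is the
    average over all factor orderings of the change in the aggregate when
    *k* flips from its t0 to its t1 values; equivalently the weighted sum
    over subsets S (not containing k) of |S|!(K-1-|S|)!/K! times the
    marginal E(S + k) - E(S), which is what is computed (2^K aggregate
    evaluations instead of K!). Effects sum exactly to E(t1) - E(t0).
    """
    names = list(factors_at_t0)
    if set(names) != set(factors_at_t1):
        raise ValueError("factor names differ between the two snapshots")
    K = len(names)
    if K > _MAX_FACTORS:
        raise ValueError(f"{K} factors exceeds the combinatorial guard of {_MAX_FACTORS}")
    f0 = {n: np.atleast_1d(np.asarray(factors_at_t0[n], dtype=float)) for n in names}
    f1 = {n: np.atleast_1d(np.asarray(factors_at_t1[n], dtype=float)) for n in names}
    shape = f0[names[0]].shape
    for n in names:
        if f0[n].shape != shape or f1[n].shape != shape:
            raise ValueError(f"cell vectors for factor {n!r} are not aligned")

    # E(S) for every subset S of factors taken at their t1 values
    agg: dict[frozenset, float] = {}
    for r in range(K + 1):
        for subset in combinations(names, r):
            s = frozenset(subset)
            agg[s] = _aggregate({n: (f1[n] if n in s else f0[n]) for n in names})

    effects: dict[str, float] = {}
    denom = factorial(K)
    for k in names:
        others = [n for n in names if n != k]
        total = 0.0
        for r in range(K):
            w = factorial(r) * factorial(K - 1 - r) / denom
            for subset in combinations(others, r):
                s = frozenset(subset)
                total += w * (agg[s | {k}] - agg[s])
        effects[k] = total
    return effects


def decompose(panel: FactorPanel, baseline_year: int | None = None) -> pd.DataFrame:
    """Per-factor effects of every annual step from the baseline year.

    Returns a DataFrame indexed by factor name with one column per step
    end-year (baseline+1 .. last). Use :func:`accumulate_effects` to turn
    the steps into cumulative driver contributions.
    """
    years = panel.years
    if baseline_year is None:
        baseline_year = years[0]
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} not in panel span")
    span = [y for y in years if y >= baseline_year]
    steps = {}
    for y0, y1 in zip(span[:-1], span[1:]):
        steps[y1] = shapley_step(panel.snapshot(y0), panel.snapshot(y1))
    return pd.DataFrame(steps).reindex(panel.factor_names)


def accumulate_effects(step_effects: pd.DataFrame, baseline_year: int) -> pd.DataFrame:
    """Cumulative driver effects since the baseline year.

    ``step_effects`` is the frame returned by :func:`decompose` (factors x
    step end-years, contiguous annual steps starting at baseline+1). The
    result has a leading all-zero baseline column; at every year the
    factor effects sum to E(year) - E(baseline) by construction.
    """
    years = [int(y) for y in step_effects.columns]
    expected = list(range(baseline_year + 1, baseline_year + 1 + len(years)))
    if years != expected:
        raise ValueError(
            f"step years {years} are not contiguous annual steps from baseline {baseline_year}"
        )
    cum = step_effects.cumsum(axis=1)
    cum.insert(0, baseline_year, 0.0)
    return cum


def counterfactual_series(
    panel: FactorPanel,
    frozen_factors: Iterable[str],
    baseline_year: int | None = None,
) -> pd.Series:
    """Emission series with the named factors held at their baseline values.

    Every frozen factor keeps its baseline-year cell values for all years
    while the others follow their actual series. With no frozen factors
    this reproduces the actual series; with all factors frozen it is flat
    at the baseline emission.
    """
    frozen = set(frozen_factors)
    unknown = frozen - set(panel.factor_names)
    if unknown:
        raise ValueError(f"unknown factor name(s): {sorted(unknown)}")
    years = panel.years
    if baseline_year is None:
        baseline_year = years[0]
    base = panel.snapshot(baseline_year)
    out = {}
    for y in years:
        snap = panel.snapshot(y)
        for name in frozen:
            snap[name] = base[name]
        out[y] = _aggregate(snap)
    return pd.Series(out)


def abatement_bookkeeping(counterfactual_total: float, actual_total: float) -> float:
    """Emission reduction attributable to the frozen (negative) drivers.

    The difference between the counterfactual total (negative drivers
    held at baseline) and the actual total in the same year.
    """
    return counterfactual_total - actual_total


def driver_size_ratio(
    effects_fine: pd.DataFrame,
    effects_coarse: pd.DataFrame,
    eps: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-driver, per-year ratio of fine to coarse effects.

    ``eps`` is the magnitude (in the effect unit, Tg by convention) below
    which the coarse effect is treated as zero and the ratio flagged
    undefined. Returns ``(ratio, undefined)``: the ratio frame (NaN where
    undefined) and a boolean frame marking undefined entries.
    """
    if list(effects_fine.index) != list(effects_coarse.index) or list(
        effects_fine.columns
    ) != list(effects_coarse.columns):
        raise ValueError("fine and coarse effect frames are not aligned")
    undefined = effects_coarse.abs() < eps
    ratio = effects_fine / effects_coarse.mask(undefined)
    return ratio, undefined


def _species_columns(species: str) -> tuple[list[str], list[str]]:
    """(size-fraction columns, removal columns) composing one species."""
    table = {
        "PM2.5": (["f_fine"], ["rem_fine"]),
        "PM2.5-10": (["f_mid"], ["rem_mid"]),
        "PM>10": (["f_coarse"], ["rem_coarse"]),
        "PM>2.5": (["f_mid", "f_coarse"], ["rem_mid", "rem_coarse"]),
        "TSP": (["f_fine", "f_mid", "f_coarse"], ["rem_fine", "rem_mid", "rem_coarse"]),
        "BC": (["f_fine"], ["rem_fine"]),
        "OC": (["f_fine"], ["rem_fine"]),
    }
    if species not in table:
        raise ValueError(f"unknown species {species!r}")
    return table[species]


def inventory_factor_panel(
    activities: pd.DataFrame,
    splits: pd.DataFrame,
    efs: pd.DataFrame,
    controls: pd.DataFrame,
    species: str = "PM2.5",
    population: pd.Series | None = None,
    unit: str = "Tg",
) -> FactorPanel:
    """Build the default driver panel for one species from the four tables.

    Cells are (source, technology) pairs; the factors are

    - ``activity`` — annual source activity (kg), summed over fuels;
    - ``technology_mix`` — technology share of the source activity;
    - ``emission_factor`` — species-resolved uncontrolled EF (g/kg),
      i.e. ``ef_tsp`` times the species' size (and BC/OC) fractions;
    - ``control`` — the surviving fraction ``1 - min(1, sum phi*eta)``
      for the species' size class (size-weighted for multi-class
      species such as TSP or PM>2.5).

    The row product summed over cells reproduces the inventory's annual
    species total. With ``population`` given (year-indexed series) the
    activity factor is split into ``population`` and
    ``activity_per_capita``, demonstrating the configurable driver
    grouping. ``unit`` scales the panel so effects come out in Tg
    (default) or g.
    """
    from pmforge.core_inventory import _combined_removal  # shared cap/warn semantics

    fcols, rcols = _species_columns(species)

    act = activities.groupby(["year", "source"])["amount"].sum()
    years = sorted(activities["year"].unique().tolist())
    cells = splits[["source", "technology"]].drop_duplicates().sort_values(
        ["source", "technology"]
    )
    idx = pd.MultiIndex.from_frame(cells)

    def grid(series: pd.Series, level_cols: list[str]) -> pd.DataFrame:
        """Pivot a keyed series to the (cell x year) grid, zero-filled."""
        df = series.rename("v").reset_index()
        wide = df.pivot_table(index=level_cols, columns="year", values="v", fill_value=0.0)
        if len(level_cols) == 1:
            wide = wide.reindex(idx.get_level_values(level_cols[0])).set_axis(idx)
        else:
            wide = wide.reindex(idx)
        return wide.reindex(columns=years, fill_value=0.0).fillna(0.0)

    activity = grid(act, ["source"])
    mix = grid(splits.set_index(["year", "source", "technology"])["share"], ["source", "technology"])

    ef = efs.set_index(["source", "technology"])
    ef = ef.reindex(idx)
    ef_species = ef["ef_tsp"].to_numpy() * ef[fcols].sum(axis=1).to_numpy()
    if species == "BC":
        ef_species = ef_species * ef["bc_frac"].to_numpy()
    elif species == "OC":
        ef_species = ef_species * ef["oc_frac"].to_numpy()
    ef_grid = pd.DataFrame(
        np.repeat(ef_species[:, None], len(years), axis=1), index=idx, columns=years
    )

    rem = _combined_removal(controls).set_index(["year", "source", "technology"])
    f = ef[fcols].to_numpy()  # (cells, n_classes) size weights
    fsum = f.sum(axis=1)
    surv = np.ones((len(idx), len(years)))
    for j, y in enumerate(years):
        try:
            r = rem.xs(y, level="year")
        except KeyError:
            continue
        r = r.reindex(idx)[rcols].fillna(0.0).to_numpy()  # (cells, n_classes)
        with np.errstate(invalid="ignore"):
            weighted = (f * (1.0 - r)).sum(axis=1) / fsum
        surv[:, j] = np.where(fsum > 0, weighted, 1.0)
    control = pd.DataFrame(surv, index=idx, columns=years)

    if unit == "Tg":
        ef_grid = ef_grid / G_PER_TG
    elif unit != "g":
        raise ValueError(f"unknown unit {unit!r}")

    data: dict[str, pd.DataFrame] = {}
    if population is not None:
        pop = pd.Series(population).reindex(years)
        if pop.isna().any():
            raise ValueError("population series does not cover the activity years")
        pop_grid = pd.DataFrame(
            np.repeat(pop.to_numpy(float)[None, :], len(idx), axis=0), index=idx, columns=years
        )
        data["population"] = pop_grid
        data["activity_per_capita"] = activity / pop_grid
    else:
        data["activity"] = activity
    data["technology_mix"] = mix
    data["emission_factor"] = ef_grid
    data["control"] = control
    return FactorPanel(data)
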