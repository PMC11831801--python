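"""Bottom-up size- and species-resolved primary PM emission inventory.

The inventory follows the standard multiplicative form

    E[y, src, k] = sum_tech  A[y, src] * s[y, src, tech]
                             * ef_tsp[src, tech] * f_k[src, tech]
                             * (1 - sum_m phi_m[y, src, tech] * eta_mk)

where ``A`` is annual activity (kg of fuel burned or product made), ``s``
the share of the activity processed by a technology, ``ef_tsp`` the
uncontrolled total-suspended-particulate emission factor (g per kg),
``f_k`` the mass fraction of TSP in size class ``k`` (PM2.5, PM2.5-10,
PM>10), ``phi_m`` the penetration of end-of-pipe control ``m`` and
``eta_mk`` its size-resolved removal efficiency. Penetrations of
co-existing controls denote disjoint shares of equipped capacity, so
their removals combine additively; the combined removal is capped at 1.

BC and OC are carried as fixed fractions of the fine (PM2.5) portion and
are removed with the fine-size efficiency, reflecting that essentially
all primary combustion BC/OC resides in fine PM.

Internal mass unit is grams; reporting unit is Tg (1 Tg = 1e12 g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: species reported in an emission table
SPECIES = ("PM2.5", "PM2.5-10", "PM>10", "BC", "OC", "TSP")

#: grams per teragram
G_PER_TG = 1e12

ACTIVITY_COLUMNS = ("year", "sector", "source", "fuel_or_process", "amount")
SPLIT_COLUMNS = ("year", "source", "technology", "share")
EF_COLUMNS = (
    "source",
    "technology",
    "ef_tsp",
    "f_fine",
    "f_mid",
    "f_coarse",
    "bc_frac",
    "oc_frac",
    "cv",
)
CONTROL_COLUMNS = (
    "year",
    "source",
    "technology",
    "control_type",
    "penetration",
    "eta_fine",
    "eta_mid",
    "eta_coarse",
)

_SHARE_TOL = 1e-9
_FRACTION_TOL = 1e-9


class Tables(NamedTuple):
    """The four input tables of the inventory."""

    activities: pd.DataFrame
    splits: pd.DataFrame
    efs: pd.DataFrame
    controls: pd.DataFrame


class MissingEFError(KeyError):
    """A (source, technology) present in the activity/split data has no EF record."""


class MissingSplitError(KeyError):
    """A (year, source) with activity has no technology-split records."""


@dataclass(frozen=True)
class Violation:
    """One validation failure: the table, the offending key, and the broken rule."""

    table: str
    key: tuple
    rule: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.table}] {self.key}: {self.rule}"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> list[Violation]:
    missing = [c for c in cols if c not in df.columns]
    return [Violation(table, (c,), "missing column") for c in missing]


def validate_tables(
    activities: pd.DataFrame,
    splits: pd.DataFrame,
    efs: pd.DataFrame,
    controls: pd.DataFrame,
    year_span: tuple[int, int] | None = None,
) -> list[Violation]:
    """Check every table invariant and cross-table consistency.

    Returns a list of :class:`Violation`; an empty list means all
    invariants hold and every (source, technology) appearing in the
    technology splits has an emission-factor record. This is a reporting
    operation — callers decide whether to abort.
    """
    out: list[Violation] = []
    out += _require_columns(activities, ACTIVITY_COLUMNS, "activities")
    out += _require_columns(splits, SPLIT_COLUMNS, "splits")
    out += _require_columns(efs, EF_COLUMNS, "efs")
    out += _require_columns(controls, CONTROL_COLUMNS, "controls")
    if out:
        return out

    for _, r in activities[activities["amount"] < 0].iterrows():
        out.append(
            Violation(
                "activities",
                (r["year"], r["sector"], r["source"], r["fuel_or_process"]),
                "amount negative",
            )
        )
    if year_span is not None:
        lo, hi = year_span
        bad = activities[(activities["year"] < lo) | (activities["year"] > hi)]
        for _, r in bad.iterrows():
            out.append(
                Violation(
                    "activities",
                    (r["year"], r["sector"], r["source"], r["fuel_or_process"]),
                    f"year outside configured span [{lo}, {hi}]",
                )
            )
    akey = ["year", "sector", "source", "fuel_or_process"]
    dup = activities[activities.duplicated(akey, keep=False)]
    for key, _ in dup.groupby(akey):
        out.append(Violation("activities", tuple(key), "duplicate record key"))

    bad_share = splits[(splits["share"] < 0) | (splits["share"] > 1)]
    for _, r in bad_share.iterrows():
        out.append(
            Violation("splits", (r["year"], r["source"], r["technology"]), "share out of [0,1]")
        )
    sums = splits.groupby(["year", "source"])["share"].sum()
    for key, s in sums.items():
        if abs(s - 1.0) > _SHARE_TOL:
            out.append(Violation("splits", tuple(key), f"shares sum to {s!r}, not 1"))

    ekey = ["source", "technology"]
    for key, _ in efs[efs.duplicated(ekey, keep=False)].groupby(ekey):
        out.append(Violation("efs", tuple(key), "duplicate record key"))
    for _, r in efs.iterrows():
        key = (r["source"], r["technology"])
        if r["ef_tsp"] < 0:
            out.append(Violation("efs", key, "ef_tsp negative"))
        fsum = r["f_fine"] + r["f_mid"] + r["f_coarse"]
        if abs(fsum - 1.0) > _FRACTION_TOL:
            out.append(Violation("efs", key, "size fractions sum != 1"))
        if min(r["f_fine"], r["f_mid"], r["f_coarse"]) < 0:
            out.append(Violation("efs", key, "negative size fraction"))
        if r["bc_frac"] < 0 or r["oc_frac"] < 0:
            out.append(Violation("efs", key, "negative BC/OC fraction"))
        if r["bc_frac"] + r["oc_frac"] > 1 + _FRACTION_TOL:
            out.append(Violation("efs", key, "bc_frac + oc_frac > 1"))
        if r["cv"] < 0:
            out.append(Violation("efs", key, "cv negative"))

    ckey = ["year", "source", "technology", "control_type"]
    for key, _ in controls[controls.duplicated(ckey, keep=False)].groupby(ckey):
        out.append(Violation("controls", tuple(key), "duplicate record key"))
    for _, r in controls.iterrows():
        key = (r["year"], r["source"], r["technology"], r["control_type"])
        if not 0 <= r["penetration"] <= 1:
            out.append(Violation("controls", key, "penetration out of [0,1]"))
        for c in ("eta_fine", "eta_mid", "eta_coarse"):
            if not 0 <= r[c] <= 1:
                out.append(Violation("controls", key, f"{c} out of [0,1]"))

    have_ef = set(map(tuple, efs[["source", "technology"]].itertuples(index=False)))
    want_ef = set(map(tuple, splits[["source", "technology"]].drop_duplicates().itertuples(index=False)))
    for key in sorted(want_ef - have_ef):
        out.append(Violation("efs", key, "no EF record for (source, technology) in splits"))

    return out


def _combined_removal(controls: pd.DataFrame) -> pd.DataFrame:
    """Sum phi*eta over control types per (year, source, technology), capped at 1."""
    c = controls.copy()
    for size in ("fine", "mid", "coarse"):
        c[f"rem_{size}"] = c["penetration"] * c[f"eta_{size}"]
    rem = c.groupby(["year", "source", "technology"], as_index=False)[
        ["rem_fine", "rem_mid", "rem_coarse"]
    ].sum()
    over = rem[["rem_fine", "rem_mid", "rem_coarse"]].to_numpy() > 1 + 1e-12
    if over.any():
        n = int(over.any(axis=1).sum())
        logger.warning(
            "combined control removal (sum of phi*eta) exceeds 1 for %d "
            "(year, source, technology) cells; capped at 1",
            n,
        )
    for col in ("rem_fine", "rem_mid", "rem_coarse"):
        rem[col] = rem[col].clip(upper=1.0)
    return rem


def build_cells(
    activities: pd.DataFrame,
    splits: pd.DataFrame,
    efs: pd.DataFrame,
    controls: pd.DataFrame,
) -> pd.DataFrame:
    """Merge the four tables into one flat cell frame.

    One row per (year, sector, source, technology) with the activity
    summed over fuels/processes, the technology share, the EF record and
    the combined (capped) size-resolved removal. This is the common
    front-end of :func:`compute_emissions` and the Monte Carlo engine.
    """
    act = activities.groupby(["year", "sector", "source"], as_index=False)["amount"].sum()
    cells = act.merge(splits, on=["year", "source"], how="left", indicator=True)
    orphans = cells[(cells["_merge"] == "left_only") & (cells["amount"] > 0)]
    if len(orphans):
        key = orphans.iloc[0]
        raise MissingSplitError(
            f"no technology split for (year={key['year']!r}, source={key['source']!r})"
        )
    cells = cells[cells["_merge"] == "both"].drop(columns="_merge")
    cells = cells.merge(efs, on=["source", "technology"], how="left", indicator=True)
    no_ef = cells[cells["_merge"] == "left_only"]
    if len(no_ef):
        key = no_ef.iloc[0]
        raise MissingEFError(
            f"no emission factor for (source={key['source']!r}, "
            f"technology={key['technology']!r})"
        )
    cells = cells.drop(columns="_merge")
    rem = _combined_removal(controls)
    cells = cells.merge(rem, on=["year", "source", "technology"], how="left")
    for col in ("rem_fine", "rem_mid", "rem_coarse"):
        cells[col] = cells[col].astype(float).fillna(0.0)
    return cells


def _emissions_from_cells(cells: pd.DataFrame) -> pd.DataFrame:
    tsp_cell = cells["amount"].to_numpy() * cells["share"].to_numpy() * cells["ef_tsp"].to_numpy()
    fine = tsp_cell * cells["f_fine"].to_numpy() * (1.0 - cells["rem_fine"].to_numpy())
    mid = tsp_cell * cells["f_mid"].to_numpy() * (1.0 - cells["rem_mid"].to_numpy())
    coarse = tsp_cell * cells["f_coarse"].to_numpy() * (1.0 - cells["rem_coarse"].to_numpy())
    out = cells[["year", "sector", "source"]].copy()
    out["PM2.5"] = fine
    out["PM2.5-10"] = mid
    out["PM>10"] = coarse
    out["BC"] = fine * cells["bc_frac"].to_numpy()
    out["OC"] = fine * cells["oc_frac"].to_numpy()
    out["TSP"] = fine + mid + coarse
    wide = out.groupby(["year", "sector", "source"], as_index=False)[list(SPECIES)].sum()
    long = wide.melt(
        id_vars=["year", "sector", "source"], var_name="species", value_name="emission_g"
    )
    return long.sort_values(["year", "sector", "source", "species"], ignore_index=True)


def compute_emissions(
    activities: pd.DataFrame,
    splits: pd.DataFrame,
    efs: pd.DataFrame,
    controls: pd.DataFrame,
) -> pd.DataFrame:
    """Compute the emission table from the four input tables.

    Returns a long-format frame with columns
    ``year, sector, source, species, emission_g`` covering all six
    species. Raises :class:`MissingEFError` (or
    :class:`MissingSplitError`) when a cell with activity has no EF
    (split) record; a combined removal above 1 is capped and logged.
    """
    cells = build_cells(activities, splits, efs, controls)
    return _emissions_from_cells(cells)


def aggregate_emissions(table: pd.DataFrame, by: Iterable[str]) -> pd.DataFrame:
    """Sum the emission table over the key columns not listed in ``by``.

    ``by`` must be a subset of {year, sector, source, species}; the grand
    total is invariant under any grouping.
    """
    by = list(by)
    allowed = {"year", "sector", "source", "species"}
    unknown = set(by) - allowed
    if unknown:
        raise ValueError(f"unknown grouping key(s): {sorted(unknown)}")
    if not by:
        return pd.DataFrame({"emission_g": [table["emission_g"].sum()]})
    return table.groupby(by, as_index=False)["emission_g"].sum()


def emissions_to_tg(table: pd.DataFrame) -> pd.DataFrame:
    """Convert an emission table from grams to Tg for reporting."""
    out = table.drop(columns="emission_g").copy()
    out["emission_Tg"] = table["emission_g"] / G_PER_TG
    return out


def species_series(table: pd.DataFrame, species: str, sector: str | None = None) -> pd.Series:
    """Annual total of one species (grams), optionally restricted to a sector."""
    sub = table[table["species"] == species]
    if sector is not None:
        sub = sub[sub["sector"] == sector]
    return sub.groupby("year")["emission_g"].sum()
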