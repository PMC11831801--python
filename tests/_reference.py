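"""Independent reference implementations used as oracles in the tests.

These deliberately avoid the package's vectorized code paths: the
inventory oracle is a plain quadruple loop with dict lookups, and the
Shapley oracle averages marginal contributions over explicitly
enumerated factor orderings.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd

SIZES = ("fine", "mid", "coarse")
SIZE_SPECIES = {"fine": "PM2.5", "mid": "PM2.5-10", "coarse": "PM>10"}


def naive_emissions(activities, splits, efs, controls) -> pd.DataFrame:
    """Loop-based bottom-up inventory: one cell at a time, no vectorization."""
    ef_map = {(r.source, r.technology): r for r in efs.itertuples(index=False)}
    share_map = defaultdict(list)
    for r in splits.itertuples(index=False):
        share_map[(r.year, r.source)].append((r.technology, r.share))
    ctrl_map = defaultdict(list)
    for r in controls.itertuples(index=False):
        ctrl_map[(r.year, r.source, r.technology)].append(r)

    out: dict[tuple, float] = defaultdict(float)
    for a in activities.itertuples(index=False):
        for tech, share in share_map[(a.year, a.source)]:
            ef = ef_map[(a.source, tech)]
            tsp = a.amount * share * ef.ef_tsp
            rows = ctrl_map[(a.year, a.source, tech)]
            rem = {}
            for size in SIZES:
                total = sum(c.penetration * getattr(c, f"eta_{size}") for c in rows)
                rem[size] = min(1.0, total)
            by_size = {}
            for size, frac in zip(SIZES, (ef.f_fine, ef.f_mid, ef.f_coarse)):
                by_size[size] = tsp * frac * (1.0 - rem[size])
                out[(a.year, a.sector, a.source, SIZE_SPECIES[size])] += by_size[size]
            out[(a.year, a.sector, a.source, "BC")] += by_size["fine"] * ef.bc_frac
            out[(a.year, a.sector, a.source, "OC")] += by_size["fine"] * ef.oc_frac
            out[(a.year, a.sector, a.source, "TSP")] += sum(by_size.values())

    rows = [
        {"year": k[0], "sector": k[1], "source": k[2], "species": k[3], "emission_g": v}
        for k, v in out.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["year", "sector", "source", "species"], ignore_index=True)
    )


def shapley_by_orderings(f0: dict, f1: dict) -> dict[str, float]:
    """Shapley effects via explicit enumeration of all K! factor orderings."""

    def agg(state):
        prod = None
        for v in state.values():
            v = np.atleast_1d(np.asarray(v, dtype=float))
            prod = v if prod is None else prod * v
        return float(prod.sum())

    names = list(f0)
    effects = {n: 0.0 for n in names}
    for perm in permutations(names):
        state = dict(f0)
        for n in perm:
            before = agg(state)
            state[n] = f1[n]
            effects[n] += agg(state) - before
    k_fact = factorial(len(names))
    return {n: e / k_fact for n, e in effects.items()}


def random_tables(rng: np.random.Generator, n_years=3, n_sources=2, max_techs=2,
                  max_fuels=2, max_controls=2):
    """A random small-but-valid table set for property tests."""
    years = list(range(2000, 2000 + n_years))
    sectors = ["alpha", "beta"]
    act_rows, split_rows, ef_rows, ctrl_rows = [], [], [], []
    for si in range(n_sources):
        source = f"src{si}"
        sector = sectors[si % len(sectors)]
        n_fuels = rng.integers(1, max_fuels + 1)
        for y in years:
            for fi in range(n_fuels):
                act_rows.append((y, sector, source, f"fuel{fi}", float(rng.uniform(0, 100))))
        n_techs = int(rng.integers(1, max_techs + 1))
        techs = [f"tech{ti}" for ti in range(n_techs)]
        for y in years:
            w = rng.uniform(0.05, 1.0, n_techs)
            w = w / w.sum()
            for t, share in zip(techs, w):
                split_rows.append((y, source, t, float(share)))
        for t in techs:
            f = rng.uniform(0.05, 1.0, 3)
            f = f / f.sum()
            bc, oc = rng.uniform(0, 0.5), rng.uniform(0, 0.5)
            ef_rows.append(
                (source, t, float(rng.uniform(0, 50)), *map(float, f), float(bc), float(oc),
                 float(rng.uniform(0, 1)))
            )
            n_ctrl = int(rng.integers(0, max_controls + 1))
            for ci in range(n_ctrl):
                pen_curve = rng.uniform(0, 1.0 / max(1, n_ctrl))
                for y in years:
                    ctrl_rows.append(
                        (y, source, t, f"ctl{ci}", float(pen_curve),
                         float(rng.uniform(0, 1)), float(rng.uniform(0, 1)),
                         float(rng.uniform(0, 1)))
                    )
    activities = pd.DataFrame(
        act_rows, columns=["year", "sector", "source", "fuel_or_process", "amount"]
    )
    splits = pd.DataFrame(split_rows, columns=["year", "source", "technology", "share"])
    efs = pd.DataFrame(
        ef_rows,
        columns=["source", "technology", "ef_tsp", "f_fine", "f_mid", "f_coarse",
                 "bc_frac", "oc_frac", "cv"],
    )
    controls = pd.DataFrame(
        ctrl_rows,
        columns=["year", "source", "technology", "control_type", "penetration",
                 "eta_fine", "eta_mid", "eta_coarse"],
    )
    return activities, splits, efs, controls
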