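"""End-to-end orchestration: simulate -> compute -> decompose -> mc -> metrics.

Each stage writes its outputs under the run directory and the run emits
one manifest with input hashes, the config snapshot and the seed. A
single global seed drives every stage through deterministically derived
substreams, so rerunning with the same config and seed reproduces every
numeric output byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from pmforge import io
from pmforge.core_inventory import Tables, compute_emissions, species_series
from pmforge.decomposition import (
    accumulate_effects,
    counterfactual_series,
    decompose,
    driver_size_ratio,
    inventory_factor_panel,
)
from pmforge.metrics import (
    carbon_shares,
    component_ratio_series,
    fine_coarse_ratio,
    kuznets_peak,
    piecewise_dependence,
    size_shares,
)
from pmforge.synthetic_data import (
    ScenarioConfig,
    config_from_dict,
    config_to_dict,
    default_config,
    gdp_per_capita_series,
    generate_scenario,
)
from pmforge.uncertainty import default_specs, run_mc

logger = logging.getLogger(__name__)

STAGES = ("simulate", "compute", "decompose", "mc", "metrics")

#: drivers held at baseline in the negative-driver counterfactual
NEGATIVE_DRIVERS = ("technology_mix", "control")


def stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage substream seeds derived from the single global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s % 2**31) for stage, s in zip(STAGES, state)}


def _tg(series: pd.Series) -> pd.Series:
    return series / 1e12


def decomposition_outputs(
    tables: Tables, baseline_year: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cumulative driver effects, counterfactuals and fine/coarse driver ratios.

    Returns ``(effects, counterfactual, ratios)``: a long frame
    (factor, species, year, cumulative_effect_Tg) for PM2.5 and PM>2.5,
    the actual-vs-negative-driver-frozen PM2.5 series, and the
    per-driver fine/coarse effect ratios.
    """
    effects_frames = {}
    long_rows = []
    for species in ("PM2.5", "PM>2.5"):
        panel = inventory_factor_panel(*tables, species=species, unit="Tg")
        steps = decompose(panel, baseline_year)
        cum = accumulate_effects(steps, baseline_year)
        effects_frames[species] = cum
        long = cum.reset_index(names="factor").melt(
            id_vars="factor", var_name="year", value_name="cumulative_effect_Tg"
        )
        long.insert(1, "species", species)
        long_rows.append(long)
    effects = pd.concat(long_rows, ignore_index=True)

    panel_fine = inventory_factor_panel(*tables, species="PM2.5", unit="Tg")
    actual = panel_fine.emission_series()
    frozen = counterfactual_series(panel_fine, NEGATIVE_DRIVERS, baseline_year)
    counterfactual = pd.DataFrame(
        {
            "year": actual.index,
            "actual_Tg": actual.to_numpy(),
            "counterfactual_Tg": frozen.to_numpy(),
            "reduction_Tg": (frozen - actual).to_numpy(),
        }
    )

    ratio, undefined = driver_size_ratio(effects_frames["PM2.5"], effects_frames["PM>2.5"])
    ratios = ratio.reset_index(names="factor").melt(
        id_vars="factor", var_name="year", value_name="fine_coarse_ratio"
    )
    ratios["undefined"] = (
        undefined.reset_index(names="factor")
        .melt(id_vars="factor", var_name="year", value_name="u")["u"]
        .to_numpy()
    )
    return effects, counterfactual, ratios


def metrics_report(
    emissions: pd.DataFrame, gdp_pc: pd.Series, breakpoint_year: int = 1995
) -> dict:
    """Bundle of trend/composition metrics for one emission table."""
    years = sorted(emissions["year"].unique().tolist())
    first, last = years[0], years[-1]
    pm25 = _tg(species_series(emissions, "PM2.5"))
    peak = kuznets_peak(pm25, gdp_pc.reindex(pm25.index))
    fits = {}
    for comp in ("BC", "OC"):
        series = _tg(species_series(emissions, comp)).reindex(pm25.index)
        fit = piecewise_dependence(pm25, series, breakpoint_year)
        fits[comp] = {
            "pre": vars(fit["pre"]),
            "post": vars(fit["post"]),
            "pooled_r": fit["pooled_r"],
        }
    fc = fine_coarse_ratio(emissions)

    def tern(point):
        return {
            "labels": list(point.labels),
            "shares": [None if not point.defined else s for s in point.shares],
            "defined": point.defined,
        }

    return {
        "peak": {
            "peak_year": peak.peak_year,
            "peak_value_Tg": peak.peak_value,
            "gdp_per_capita_at_peak": peak.gdp_at_peak,
            "boundary": peak.boundary,
        },
        "piecewise_dependence": fits,
        "fine_coarse_ratio": {str(first): float(fc.loc[first]), str(last): float(fc.loc[last])},
        "size_shares": {
            str(y): tern(size_shares(emissions, y)) for y in (first, last)
        },
        "carbon_shares": {
            str(y): tern(carbon_shares(emissions, y)) for y in (first, last)
        },
        "component_ratios": {
            comp: {
                str(first): float(component_ratio_series(emissions, comp).loc[first]),
                str(last): float(component_ratio_series(emissions, comp).loc[last]),
            }
            for comp in ("BC", "OC")
        },
    }


def run_pipeline(
    config: ScenarioConfig | dict | str | Path | None = None,
    out: str | Path = "pmforge_run",
    seed: int = 0,
    skip: Iterable[str] = (),
    mc_draws: int = 500,
    breakpoint_year: int = 1995,
) -> dict[str, Path]:
    """Run the full pipeline on a synthetic scenario and write all outputs.

    ``config`` may be a :class:`ScenarioConfig`, a dict, a YAML/JSON path
    or ``None`` for the default scenario. Stages in ``skip`` are left
    out; later stages re-derive what they need from the written tables.
    Returns the mapping of stage outputs to paths.
    """
    skip = set(skip)
    unknown = skip - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) to skip: {sorted(unknown)}")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    started = io.utc_now()
    seeds = stage_seeds(seed)

    if config is None:
        cfg = default_config()
    elif isinstance(cfg_in := config, ScenarioConfig):
        cfg = cfg_in
    elif isinstance(config, dict):
        cfg = config_from_dict(config)
    else:
        cfg = config_from_dict(io.read_config(config))

    outputs: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn):
            if name in skip:
                logger.info("stage %s skipped", name)
                return None
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    tables = None

    @_stage("simulate")
    def _simulate():
        nonlocal tables
        tables = generate_scenario(cfg, seed=seeds["simulate"])
        paths = io.write_tables(tables, out / "tables")
        outputs.update({f"tables/{k}": v for k, v in paths.items()})
        return tables

    if tables is None:  # simulate skipped: ingest previously written tables
        tables = io.read_tables(out / "tables")

    emissions = None

    @_stage("compute")
    def _compute():
        nonlocal emissions
        emissions = compute_emissions(*tables)
        outputs["emissions"] = io.write_emissions(emissions, out / "emissions.csv")
        totals = {
            sp: float(species_series(emissions, sp).sum() / 1e12)
            for sp in ("PM2.5", "PM2.5-10", "PM>10", "BC", "OC", "TSP")
        }
        outputs["totals"] = io.write_json(
            {"cumulative_emissions_Tg": totals}, out / "totals.json"
        )
        return emissions

    @_stage("decompose")
    def _decompose():
        baseline = cfg.year_start
        effects, counterfactual, ratios = decomposition_outputs(tables, baseline)
        effects.to_csv(out / "decomposition.csv", index=False)
        counterfactual.to_csv(out / "counterfactual.csv", index=False)
        ratios.to_csv(out / "driver_size_ratios.csv", index=False)
        outputs["decomposition"] = out / "decomposition.csv"
        outputs["counterfactual"] = out / "counterfactual.csv"
        outputs["driver_size_ratios"] = out / "driver_size_ratios.csv"

    @_stage("mc")
    def _mc():
        summary = run_mc(tables, default_specs(), n_draws=mc_draws, seed=seeds["mc"])
        summary.to_tg().to_csv(out / "mc_summary.csv", index=False)
        outputs["mc_summary"] = out / "mc_summary.csv"

    @_stage("metrics")
    def _metrics():
        if emissions is None:
            raise RuntimeError("metrics needs the compute stage (or its emissions.csv)")
        gdp = gdp_per_capita_series(cfg)
        report = metrics_report(emissions, gdp, breakpoint_year)
        outputs["metrics"] = io.write_json(report, out / "metrics.json")

    manifest = io.RunManifest(
        command="run",
        inputs=io.hash_inputs([p for p in outputs.values() if p.suffix == ".csv"]),
        config=config_to_dict(cfg),
        seed=seed,
        version=_version(),
        started=started,
        finished=io.utc_now(),
    )
    outputs["manifest"] = io.write_manifest(manifest, out / "manifest.json")
    return outputs


def _version() -> str:
    from pmforge import __version__

    return __version__
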