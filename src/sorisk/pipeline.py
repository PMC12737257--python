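"""End-to-end pipeline orchestration.

Runs indices -> ecological risk -> 1D-MCS -> sensitivity -> 2D-MCS ->
PMF -> source-oriented risk over one concentration table, writing one
JSON summary plus per-stage CSVs. A single master seed expands into
named per-stage substreams so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import apportion, defaults, indices, montecarlo, pmf
from .data import (ConcentrationTable, ElementReference, SchemaError,
                   load_concentration_table)
from .health import ExposureScenario

log = logging.getLogger("sorisk")

# fixed per-stage substream labels under the master seed
_STAGE_STREAMS = {"simulate": 0, "mcs1d": 1, "mcs2d": 2, "threshold": 3,
                  "pmf": 4, "source_risk": 5}


def stage_seed(master: int, stage: str) -> list[int]:
    return [int(master), _STAGE_STREAMS[stage]]


@dataclasses.dataclass
class PipelineConfig:
    table_path: str | None = None
    reference_path: str | None = None
    scenario_path: str | None = None
    out_dir: str = "sorisk_out"
    seed: int = 0
    n_iter_1d: int = 10_000
    n_inner: int = 10_000
    n_outer: int = 200
    n_factors: int = 4
    n_starts: int = 20
    receptors: tuple = ("child", "adult")
    run_pmf: bool = True
    run_2d: bool = True
    metric_2d: str = "HI"
    land_use_2d: str | None = "farmland"
    receptor_2d: str = "child"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise SchemaError(f"unknown pipeline config keys: {sorted(unknown)}")
        obj = cls(**cfg)
        if obj.table_path and not Path(obj.table_path).exists():
            raise SchemaError(f"table file not found: {obj.table_path}")
        return obj


def _load_inputs(config: PipelineConfig):
    if config.table_path is None:
        from .synthetic import default_study_spec, generate_mixture
        dataset = generate_mixture(
            default_study_spec(stage_seed(config.seed, "simulate")[0]))
        table = dataset.table
    else:
        table = load_concentration_table(config.table_path)
    ref = (ElementReference.from_yaml(config.reference_path)
           if config.reference_path else ElementReference.default(table.elements))
    if config.scenario_path:
        with open(config.scenario_path) as fh:
            catalogue = yaml.safe_load(fh)
        scenarios = {r: ExposureScenario.from_config(r, catalogue[r])
                     for r in config.receptors}
    else:
        scenarios = {r: ExposureScenario.default(r) for r in config.receptors}
    return table, ref, scenarios


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the summary dict (also written
    to ``<out_dir>/summary.json``)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    failed_stage = None
    try:
        table, ref, scenarios = _load_inputs(config)
        table.to_csv(out_dir / "table.csv")

        stage = "indices"
        pol = indices.pollution_index(table, ref)
        pol.summary().to_csv(out_dir / "pollution.csv")
        summary["stages"]["indices"] = {
            "nipi_mean": float(pol.nipi.mean()),
            "nipi_max": float(pol.nipi.max()),
        }
        log.info("stage=indices n=%d", table.n_samples)

        stage = "ecorisk"
        eco = indices.ecological_risk(table, ref)
        eco.summary().to_csv(out_dir / "ecorisk.csv")
        summary["stages"]["ecorisk"] = {
            "ri_mean": float(eco.ri.mean()),
            "niri_mean": float(eco.niri.mean()),
        }

        stage = "mcs1d"
        runs = montecarlo.run_1d_study(
            table, scenarios, ref, n_iter=config.n_iter_1d,
            seed=stage_seed(config.seed, "mcs1d")[0])
        block = {}
        for (land_use, receptor), run in runs.items():
            block[f"{land_use}/{receptor}"] = {
                "HI": run.hi.summary, "TCR": run.tcr.summary}
        summary["stages"]["mcs1d"] = {
            "n_iter": config.n_iter_1d,
            "seed": stage_seed(config.seed, "mcs1d"), "results": block}

        stage = "sensitivity"
        key = (config.land_use_2d or sorted(set(table.land_use))[0],
               config.receptor_2d)
        sens = montecarlo.sensitivity_contribution(
            runs[key].parameter_draws,
            runs[key].distribution(config.metric_2d).realizations)
        summary["stages"]["sensitivity"] = {
            "stratum": list(key), "metric": config.metric_2d,
            "contributions": sens.contributions.round(3).to_dict(),
            "top_parameter": sens.top_parameter}

        stage = "mcs2d"
        if config.run_2d:
            two_d = montecarlo.run_2d_mcs(
                table, scenarios[config.receptor_2d], ref,
                uncertain_param=sens.top_parameter,
                n_inner=config.n_inner, n_outer=config.n_outer,
                seed=stage_seed(config.seed, "mcs2d")[0],
                land_use=config.land_use_2d, metric=config.metric_2d)
            summary["stages"]["mcs2d"] = {
                "uncertain_parameter": two_d.uncertain_parameter,
                "n_inner": two_d.n_inner, "n_outer": two_d.n_outer,
                "n_pooled": int(two_d.pooled.realizations.size),
                "seed": stage_seed(config.seed, "mcs2d"),
                "pooled": two_d.pooled.summary}
        else:
            summary["stages"]["mcs2d"] = {"skipped": "disabled"}

        stage = "pmf"
        solution = None
        if config.run_pmf:
            u = pmf.compute_uncertainty(table, ref)
            solution = pmf.PMF(table.data, u, config.n_factors).fit(
                n_starts=config.n_starts,
                seed=stage_seed(config.seed, "pmf")[0])
            solution.profiles.to_csv(out_dir / "pmf_profiles.csv")
            solution.contributions.to_csv(out_dir / "pmf_contributions.csv")
            diag = solution.diagnostics()
            summary["stages"]["pmf"] = {
                "n_factors": config.n_factors,
                "seed": stage_seed(config.seed, "pmf"),
                "q_true": diag["q_true"], "q_robust": diag["q_robust"],
                "q_ratio": diag["q_ratio"],
                "residuals_within_3": diag["residuals_within_3"],
                "contribution_pct":
                    solution.factor_contribution_pct().round(3).to_dict()}
        else:
            summary["stages"]["pmf"] = {"skipped": "disabled"}

        stage = "source_risk"
        if solution is not None:
            shares = apportion.apportion_risk(solution, table, ref, scenarios)
            shares.summary().to_csv(out_dir / "source_shares.csv")
            summary["stages"]["source_risk"] = {
                "shares": {col: shares.summary()[col].round(3).to_dict()
                           for col in shares.summary().columns},
                "priority": apportion.priority_ranking(shares)}
        else:
            summary["stages"]["source_risk"] = {"skipped": "missing dependency"}
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        _write_summary(summary, out_dir / "summary.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_summary(summary, out_dir / "summary.json")
    return summary


def _write_summary(summary: dict, path: Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_default, sort_keys=True)
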