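"""Global weighted trend, prior-sensitivity scan, and pipeline orchestration.

The global figure is a convex combination of regional posterior modes with
weights proportional to each region's record-average chlorophyll times its
areal extent — regions that hold more of the ocean's chlorophyll count
more.  The sensitivity scan refits one region over a grid of normal trend
priors at reduced MCMC length to map how strongly the prior can pull the
posterior.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ChlTrendError, InvalidConfigurationError
from .fields import ChlField
from .priors import (
    PERCENT_PER_YEAR,
    TrendPrior,
    build_region_priors,
    convert_prior_units,
    prior_table,
    vague_prior,
)
from .regions import (
    RegionMask,
    climatology_peak_month,
    regional_mean_chl,
    regional_mean_series,
)
from .st_model import STModelConfig, build_design, fit_st_model
from .summarize import TrendEstimate, estimate_from_draws, results_table, scenarios_differ
from .synthetic import (
    SimulationTruth,
    generate_region_layout,
    random_truth,
    simulate_chl_field,
    simulate_climate_ensemble,
    write_runs_csv,
)


@dataclass
class GlobalSummary:
    """Chl-and-area weighted average of regional trend modes."""

    weighted_trend_pct_yr: float
    weights: dict[int, float]
    n_regions: int
    scenario: str

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12 or min(self.weights.values()) < 0:
            raise ValueError("weights must be non-negative and sum to 1")


def global_weighted_trend(
    estimates: Mapping[int, TrendEstimate],
    mean_chl: Mapping[int, float],
    area: Mapping[int, float],
    scenario: str = "vague",
    weight_mode: str = "chl_area",
) -> GlobalSummary:
    """Weight regional modes by mean chl x area (or area alone)."""
    ids = set(estimates)
    if ids != set(mean_chl) or ids != set(area):
        raise InvalidConfigurationError("estimates, mean_chl and area must share region ids")
    if any(mean_chl[r] <= 0 or area[r] <= 0 for r in ids):
        raise InvalidConfigurationError("mean chl and areas must be positive")
    if weight_mode == "chl_area":
        raw = {r: mean_chl[r] * area[r] for r in ids}
    elif weight_mode == "area":
        raw = {r: float(area[r]) for r in ids}
    else:
        raise InvalidConfigurationError(f"unknown weight mode {weight_mode!r}")
    total = sum(raw.values())
    weights = {r: raw[r] / total for r in sorted(ids)}
    trend = sum(weights[r] * estimates[r].mode_pct_yr for r in ids)
    return GlobalSummary(
        weighted_trend_pct_yr=float(trend), weights=weights, n_regions=len(ids), scenario=scenario
    )


@dataclass
class SensitivityResult:
    """Modes and HDI widths over a (prior mean, prior variance) grid."""

    region_id: int
    table: pd.DataFrame  # prior_mean_pct_yr, prior_var_pct_yr, mode, width, seed
    n_iterations: int


def _cell_seed(base_seed: int, i: int, j: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), i, j]).generate_state(1)[0] % 2**31)


def sensitivity_scan(
    field: ChlField,
    mask: RegionMask,
    region_id: int,
    mean_grid: Sequence[float],
    variance_grid: Sequence[float],
    reduced_config: STModelConfig,
    peak_month: int | None = None,
) -> SensitivityResult:
    """Refit one region for every (prior mean, prior variance) pair.

    Priors are on the % year^-1 scale.  Each grid cell gets its own
    deterministic seed derived from the reduced config's seed.
    """
    if len(mean_grid) == 0 or len(variance_grid) == 0:
        raise InvalidConfigurationError("sensitivity grids must be non-empty")
    if peak_month is None:
        peak_month = climatology_peak_month(regional_mean_series(field, mask, region_id), field.start_month)
    design = build_design(field, mask, region_id, peak_month)
    rows = []
    for i, m in enumerate(mean_grid):
        for j, v in enumerate(variance_grid):
            provenance = "vague" if (m == 0.0 and v == 100.0) else "ensemble"
            prior = TrendPrior(mean=float(m), variance=float(v), unit_scale=PERCENT_PER_YEAR, provenance=provenance)
            cfg = replace(reduced_config, trend_prior=prior, seed=_cell_seed(reduced_config.seed, i, j))
            try:
                samples = fit_st_model(field, mask, region_id, design, cfg)
            except ChlTrendError as exc:
                raise type(exc)(f"sensitivity cell (mean={m}, var={v}): {exc}") from exc
            est = estimate_from_draws(samples.trend_draws, region_id, provenance)
            rows.append(
                {
                    "prior_mean_pct_yr": float(m),
                    "prior_var_pct_yr": float(v),
                    "mode_pct_yr": est.mode_pct_yr,
                    "hdi_width_pct_yr": est.hdi_width_pct_yr,
                    "seed": cfg.seed,
                }
            )
    return SensitivityResult(
        region_id=region_id, table=pd.DataFrame(rows), n_iterations=reduced_config.n_iterations
    )


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "chltrend_run",
    "simulation": {
        "n_regions": 4,
        "grid_shape": [16, 16],
        "n_months": 120,
        "trend_range": [-2.0, 2.0],
        "truth_overrides": {},
        "trends": None,
    },
    "climate_ensemble": {
        "n_models": 8,
        "ensembles_per_model": None,
        "n_months": 240,
        "model_trend_sd": 0.5,
    },
    "mcmc": {
        "n_iterations": 3000,
        "n_burnin": 600,
        "spatial_decay_km": 500.0,
        "knots": None,
    },
    "prior": {"scenarios": ["vague", "ensemble"]},
    "area_weighted_means": True,
    "sensitivity": {
        "enabled": False,
        "region": 0,
        "mean_grid": [0.0],
        "variance_grid": [100.0, 10.0, 1.0, 0.1, 0.01, 0.001],
        "n_iterations": 1000,
        "n_burnin": 500,
    },
    "data": None,  # {"field": path.nc, "mask": path.nc} to skip simulation
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


@dataclass
class RunResult:
    """Everything a pipeline run produced, plus where it was written."""

    results: pd.DataFrame
    priors: pd.DataFrame
    globals_: dict[str, GlobalSummary]
    comparison: pd.DataFrame
    truth: SimulationTruth | None
    sensitivity: SensitivityResult | None
    manifest: dict
    output_dir: Path
    failed_regions: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed_regions


def run_pipeline(config: dict | str | Path) -> RunResult:
    """Execute the full analysis: data -> priors -> fits -> summaries.

    ``config`` is a YAML path or an already-merged dict.  Writes results,
    prior and comparison tables, global summaries, ground truth (when
    simulated) and a manifest sufficient to reproduce the run.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    truth: SimulationTruth | None = None
    if cfg.get("data"):
        field_obj = ChlField.from_netcdf(cfg["data"]["field"])
        mask = RegionMask.from_netcdf(cfg["data"]["mask"])
    else:
        sim = cfg["simulation"]
        mask = generate_region_layout(int(sim["n_regions"]), tuple(sim["grid_shape"]), seed=seed)
        lo, hi = sim["trend_range"]
        truth = random_truth(mask.region_ids, seed=seed, trend_low=float(lo), trend_high=float(hi), **sim["truth_overrides"])
        if sim.get("trends"):
            truth.region_trends = {int(k): float(v) for k, v in sim["trends"].items()}
        field_obj = simulate_chl_field(truth, mask, int(sim["n_months"]))
        field_obj.to_netcdf(out_dir / "field.nc")
        mask.to_netcdf(out_dir / "mask.nc")
        (out_dir / "truth.json").write_text(truth.to_json())

    scenarios = list(cfg["prior"]["scenarios"])
    region_priors: dict[int, TrendPrior] = {}
    if "ensemble" in scenarios:
        if truth is None:
            raise InvalidConfigurationError(
                "the ensemble scenario needs simulated climate runs; supply simulation config"
            )
        ce = cfg["climate_ensemble"]
        counts = ce["ensembles_per_model"] or [1] * int(ce["n_models"])
        runs = simulate_climate_ensemble(
            truth,
            n_models=int(ce["n_models"]),
            ensembles_per_model=counts,
            n_months=int(ce["n_months"]),
            model_trend_sd=float(ce["model_trend_sd"]),
            seed=_cell_seed(seed, 9999, 0),
        )
        write_runs_csv(runs, out_dir / "climate_runs.csv")
        region_priors = build_region_priors(runs)
    priors_df = prior_table(region_priors) if region_priors else pd.DataFrame()
    if not priors_df.empty:
        priors_df.to_csv(out_dir / "priors.csv", index=False)

    mcmc = cfg["mcmc"]
    area_weighted = bool(cfg["area_weighted_means"])
    estimates: dict[str, dict[int, TrendEstimate]] = {s: {} for s in scenarios}
    failed: list[int] = []
    mean_chl: dict[int, float] = {}
    area: dict[int, float] = {}
    for ridx, region_id in enumerate(mask.region_ids):
        try:
            series = regional_mean_series(field_obj, mask, region_id, area_weighted=area_weighted)
            peak = climatology_peak_month(series, field_obj.start_month)
            design = build_design(field_obj, mask, region_id, peak)
            mean_chl[region_id] = regional_mean_chl(field_obj, mask, region_id)
            area[region_id] = mask.region_area_km2(region_id)
            for sidx, scenario in enumerate(scenarios):
                prior = vague_prior() if scenario == "vague" else region_priors[region_id]
                config_r = STModelConfig(
                    trend_prior=prior,
                    spatial_decay_km=float(mcmc["spatial_decay_km"]),
                    n_iterations=int(mcmc["n_iterations"]),
                    n_burnin=int(mcmc["n_burnin"]),
                    knots=mcmc["knots"],
                    seed=_cell_seed(seed, ridx, sidx),
                )
                samples = fit_st_model(field_obj, mask, region_id, design, config_r)
                estimates[scenario][region_id] = estimate_from_draws(samples.trend_draws, region_id, scenario)
        except ChlTrendError:
            failed.append(region_id)

    all_estimates = [estimates[s][r] for s in scenarios for r in sorted(estimates[s])]
    results = results_table(all_estimates)
    results.to_csv(out_dir / "results.csv", index=False)

    globals_: dict[str, GlobalSummary] = {}
    for scenario in scenarios:
        ids = sorted(estimates[scenario])
        if ids:
            globals_[scenario] = global_weighted_trend(
                {r: estimates[scenario][r] for r in ids},
                {r: mean_chl[r] for r in ids},
                {r: area[r] for r in ids},
                scenario=scenario,
            )
    (out_dir / "global.json").write_text(
        json.dumps(
            {
                s: {
                    "weighted_trend_pct_yr": g.weighted_trend_pct_yr,
                    "weights": {str(k): v for k, v in g.weights.items()},
                    "n_regions": g.n_regions,
                }
                for s, g in globals_.items()
            },
            indent=2,
        )
    )

    comparison = pd.DataFrame()
    if len(scenarios) == 2:
        a, b = scenarios
        shared = sorted(set(estimates[a]) & set(estimates[b]))
        comparison = pd.DataFrame(
            [
                {"region_id": r, "scenarios_differ": scenarios_differ(estimates[a][r], estimates[b][r])}
                for r in shared
            ]
        )
        comparison.to_csv(out_dir / "scenario_comparison.csv", index=False)

    sens = None
    if cfg["sensitivity"]["enabled"]:
        sc = cfg["sensitivity"]
        reduced = STModelConfig(
            n_iterations=int(sc["n_iterations"]),
            n_burnin=int(sc["n_burnin"]),
            spatial_decay_km=float(mcmc["spatial_decay_km"]),
            knots=mcmc["knots"],
            seed=_cell_seed(seed, 777, 0),
        )
        sens = sensitivity_scan(
            field_obj, mask, int(sc["region"]), sc["mean_grid"], sc["variance_grid"], reduced
        )
        sens.table.to_csv(out_dir / "sensitivity.csv", index=False)

    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": cfg_hash,
        "n_regions": len(mask.region_ids),
        "scenarios": scenarios,
        "failed_regions": failed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        results=results,
        priors=priors_df,
        globals_=globals_,
        comparison=comparison,
        truth=truth,
        sensitivity=sens,
        manifest=manifest,
        output_dir=out_dir,
        failed_regions=failed,
    )
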