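"""Seeded synthetic observations and climate-ensemble series.

The generator mirrors the statistical structure the trend model assumes:
per-region log-chl fields built from an intercept, a linear trend, an
annual cosine, a spatially correlated AR(1) process (exponential
covariance in great-circle distance) and white measurement noise, with
completely-at-random missingness.  Climate-ensemble series emulate a
CMIP5-style archive: each model draws its own trend around the regional
truth, each ensemble member adds AR(1) noise around its model's trend
line.  Ground truth travels alongside for recovery tests.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidConfigurationError
from .fields import ChlField, calendar_months
from .regions import NO_REGION, RegionMask, cell_area_km2, pairwise_distances_km
from .summarize import from_percent_per_year

#: ensemble-member counts of the 14 CMIP5 models with monthly chl output
#: under historical + RCP8.5 (24 runs in total)
CMIP5_ENSEMBLE_COUNTS: dict[str, int] = {
    "CMCC-CESM": 1,
    "CNRM-CM5": 1,
    "GFDL-ESM2G": 1,
    "GFDL-ESM2M": 1,
    "GISS-E2-H-CC": 1,
    "GISS-E2-R-CC": 1,
    "HadGEM2-CC": 3,
    "HadGEM2-ES": 4,
    "IPSL-CM5A-LR": 4,
    "IPSL-CM5A-MR": 1,
    "IPSL-CM5B-LR": 1,
    "MPI-ESM-LR": 3,
    "MPI-ESM-MR": 1,
    "MRI-ESM1": 1,
}

#: first month of the satellite record emulated by default
DEFAULT_START_MONTH = (1997, 9)


@dataclass
class SimulationTruth:
    """Ground-truth parameters for one synthetic world.

    Trends are on the reporting scale (% year^-1); intercepts, amplitudes
    and noise s.d.s are in log units (ln mg m^-3).
    """

    region_trends: dict[int, float]
    intercepts: dict[int, float]
    seasonal_amplitudes: dict[int, float]
    seasonal_peak_months: dict[int, int]
    spatial_decay_km: float = 500.0
    ar1_rho: float = 0.6
    process_sd: float = 0.05
    nugget_sd: float = 0.10
    missing_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_rho < 1.0:
            raise InvalidConfigurationError("ar1_rho must lie strictly inside (-1, 1)")
        if min(self.process_sd, self.nugget_sd) < 0:
            raise InvalidConfigurationError("noise standard deviations must be >= 0")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise InvalidConfigurationError("missing_fraction must be in [0, 1)")
        if self.spatial_decay_km <= 0:
            raise InvalidConfigurationError("spatial_decay_km must be positive")
        for r, m in self.seasonal_peak_months.items():
            if not 1 <= int(m) <= 12:
                raise InvalidConfigurationError(f"seasonal peak month {m} for region {r} not in 1..12")

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("region_trends", "intercepts", "seasonal_amplitudes", "seasonal_peak_months"):
            d[key] = {str(k): v for k, v in d[key].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        for key in ("region_trends", "intercepts", "seasonal_amplitudes"):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
        d["seasonal_peak_months"] = {int(k): int(v) for k, v in d["seasonal_peak_months"].items()}
        return cls(**d)


@dataclass
class ClimateRunSeries:
    """Monthly regional-mean log-chl from one model run (one ensemble member)."""

    model_id: str
    ensemble_id: str
    region_id: int
    series: np.ndarray
    start_month: tuple[int, int] = DEFAULT_START_MONTH

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float).ravel()
        if self.series.size < 24:
            raise InvalidConfigurationError("a climate run series needs at least 24 months")
        if not np.all(np.isfinite(self.series)):
            raise InvalidConfigurationError("climate run series must be finite")


def random_truth(
    region_ids,
    seed: int,
    trend_low: float = -2.0,
    trend_high: float = 2.0,
    **overrides,
) -> SimulationTruth:
    """Draw a SimulationTruth with per-region trends uniform on [low, high] % year^-1.

    Intercepts sit around ln(0.25 mg m^-3) with mild regional spread;
    seasonal amplitude defaults to 0.15 log units with a random peak month.
    """
    rng = np.random.default_rng(seed)
    region_ids = [int(r) for r in region_ids]
    return SimulationTruth(
        region_trends={r: float(rng.uniform(trend_low, trend_high)) for r in region_ids},
        intercepts={r: float(np.log(0.25) + rng.normal(0.0, 0.3)) for r in region_ids},
        seasonal_amplitudes={r: 0.15 for r in region_ids},
        seasonal_peak_months={r: int(rng.integers(1, 13)) for r in region_ids},
        seed=seed,
        **overrides,
    )


def generate_region_layout(
    n_regions: int,
    grid_shape: tuple[int, int],
    seed: int,
    cell_size_deg: float = 1.0,
) -> RegionMask:
    """Partition a grid into ``n_regions`` contiguous regions by seeded growth.

    Cells are ``cell_size_deg`` boxes; latitudes straddle the equator and
    longitudes start at 0, so areas vary realistically with latitude.
    Region seeds are drawn at random and grown breadth-first with random
    frontier priorities, which yields irregular but contiguous provinces.
    """
    rows, cols = grid_shape
    if n_regions < 1 or n_regions > rows * cols:
        raise InvalidConfigurationError(f"cannot place {n_regions} regions on a {rows}x{cols} grid")
    rng = np.random.default_rng(seed)
    assignment = np.full((rows, cols), NO_REGION, dtype=int)
    seeds = rng.choice(rows * cols, size=n_regions, replace=False)
    # one frontier heap per region, grown round-robin so sizes stay balanced
    frontiers: list[list[tuple[float, int, int]]] = [[] for _ in range(n_regions)]

    def _claim(i: int, j: int, region: int) -> None:
        assignment[i, j] = region
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < rows and 0 <= nj < cols and assignment[ni, nj] == NO_REGION:
                heapq.heappush(frontiers[region], (float(rng.random()), ni, nj))

    for region, flat in enumerate(seeds):
        _claim(int(flat) // cols, int(flat) % cols, region)
    remaining = rows * cols - n_regions
    while remaining:
        progressed = False
        for region in range(n_regions):
            while frontiers[region]:
                _, i, j = heapq.heappop(frontiers[region])
                if assignment[i, j] == NO_REGION:
                    _claim(i, j, region)
                    remaining -= 1
                    progressed = True
                    break
        if not progressed:  # pragma: no cover - frontiers jointly cover the grid
            break

    lat_centers = (np.arange(rows) - rows / 2.0 + 0.5) * cell_size_deg
    lon_centers = (np.arange(cols) + 0.5) * cell_size_deg
    areas = np.broadcast_to(
        np.array([cell_area_km2(lat, cell_size_deg) for lat in lat_centers])[:, None], (rows, cols)
    ).copy()
    return RegionMask(
        region_of_cell=assignment,
        cell_area_km2=areas,
        region_ids=list(range(n_regions)),
        lat_centers=lat_centers,
        lon_centers=lon_centers,
    )


def spatial_cholesky(lats: np.ndarray, lons: np.ndarray, decay_km: float) -> np.ndarray:
    """Cholesky factor of exp(-d/decay) over cell centers; rejects duplicates."""
    d = pairwise_distances_km(lats, lons)
    off_diag = d[~np.eye(d.shape[0], dtype=bool)]
    if off_diag.size and off_diag.min() <= 0:
        raise DegenerateGeometryError("duplicate cell coordinates make the spatial covariance singular")
    corr = np.exp(-d / decay_km)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateGeometryError("spatial correlation matrix is not positive definite") from exc


def simulate_chl_field(
    truth: SimulationTruth,
    mask: RegionMask,
    n_months: int,
    start_month: tuple[int, int] = DEFAULT_START_MONTH,
) -> ChlField:
    """Simulate the monthly log-chl field implied by ``truth`` on ``mask``'s grid.

    Mean surface: per-region intercept + linear trend (converted to log
    month^-1) + annual cosine peaking at the region's peak month.  On top,
    a spatio-temporal process w with AR(1) dynamics and exponential spatial
    innovation covariance (started from its stationary distribution), plus
    iid nugget noise; ``missing_fraction`` of cell-months masked at random.
    """
    if n_months < 24:
        raise InvalidConfigurationError("need at least 24 months for a meaningful record")
    rng = np.random.default_rng(truth.seed)
    rows_all, cols_all = np.nonzero(mask.region_of_cell != NO_REGION)
    n_cells = rows_all.size
    lats = mask.lat_centers[rows_all]
    lons = mask.lon_centers[cols_all]
    regions = mask.region_of_cell[rows_all, cols_all]

    t = np.arange(n_months, dtype=float)
    months = calendar_months(start_month, n_months)
    values = np.full(mask.shape + (n_months,), np.nan)

    mean_surface = np.empty((n_cells, n_months))
    for r in np.unique(regions):
        beta_trend = float(from_percent_per_year(truth.region_trends[int(r)]))
        seas = truth.seasonal_amplitudes[int(r)] * np.cos(
            2.0 * np.pi * (months - truth.seasonal_peak_months[int(r)]) / 12.0
        )
        mean_surface[regions == r] = truth.intercepts[int(r)] + beta_trend * t + seas

    field_vals = mean_surface
    if truth.process_sd > 0:
        L = truth.process_sd * spatial_cholesky(lats, lons, truth.spatial_decay_km)
        w = np.empty((n_cells, n_months))
        w[:, 0] = (L @ rng.standard_normal(n_cells)) / np.sqrt(1.0 - truth.ar1_rho**2)
        for k in range(1, n_months):
            w[:, k] = truth.ar1_rho * w[:, k - 1] + L @ rng.standard_normal(n_cells)
        field_vals = field_vals + w
    if truth.nugget_sd > 0:
        field_vals = field_vals + truth.nugget_sd * rng.standard_normal((n_cells, n_months))
    if truth.missing_fraction > 0:
        gaps = rng.random((n_cells, n_months)) < truth.missing_fraction
        field_vals = np.where(gaps, np.nan, field_vals)

    values[rows_all, cols_all, :] = field_vals
    return ChlField(values=values, lat_centers=mask.lat_centers, lon_centers=mask.lon_centers, start_month=start_month)


def simulate_climate_ensemble(
    truth: SimulationTruth,
    n_models: int,
    ensembles_per_model,
    n_months: int,
    model_trend_sd: float,
    seed: int,
    start_month: tuple[int, int] = DEFAULT_START_MONTH,
) -> list[ClimateRunSeries]:
    """Emulate a multi-model archive of regional-mean log-chl series.

    Model m's trend is drawn N(true regional trend, model_trend_sd^2) on
    the % year^-1 scale; each of its ensemble members follows that trend
    line (with the region's intercept and seasonality) plus AR(1) noise
    using the truth's process s.d. and rho.  The prior record is typically
    about twice the observational one.
    """
    if n_models < 2:
        raise InvalidConfigurationError("need at least two models for a multi-model prior")
    ensembles_per_model = list(ensembles_per_model)
    if len(ensembles_per_model) != n_models:
        raise InvalidConfigurationError("ensembles_per_model length must equal n_models")
    if any(int(c) < 1 for c in ensembles_per_model):
        raise InvalidConfigurationError("every model needs at least one ensemble member")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months, dtype=float)
    months = calendar_months(start_month, n_months)
    runs: list[ClimateRunSeries] = []
    for region_id in sorted(truth.region_trends):
        seas = truth.seasonal_amplitudes[region_id] * np.cos(
            2.0 * np.pi * (months - truth.seasonal_peak_months[region_id]) / 12.0
        )
        for m, n_ens in enumerate(ensembles_per_model):
            trend_pct = truth.region_trends[region_id] + model_trend_sd * rng.standard_normal()
            beta = float(from_percent_per_year(trend_pct))
            line = truth.intercepts[region_id] + beta * t + seas
            for e in range(int(n_ens)):
                noise = np.zeros(n_months)
                if truth.process_sd > 0:
                    noise[0] = rng.normal(0.0, truth.process_sd / np.sqrt(1.0 - truth.ar1_rho**2))
                    eps = rng.normal(0.0, truth.process_sd, size=n_months)
                    for k in range(1, n_months):
                        noise[k] = truth.ar1_rho * noise[k - 1] + eps[k]
                runs.append(
                    ClimateRunSeries(
                        model_id=f"model-{m:02d}",
                        ensemble_id=f"ens-{e}",
                        region_id=int(region_id),
                        series=line + noise,
                        start_month=start_month,
                    )
                )
    return runs


def write_runs_csv(runs, path) -> None:
    """Persist climate run series as long-form CSV."""
    frames = []
    for run in runs:
        years = []
        months = []
        y, m = run.start_month
        for _ in range(run.series.size):
            years.append(y)
            months.append(m)
            m += 1
            if m > 12:
                m = 1
                y += 1
        frames.append(
            pd.DataFrame(
                {
                    "model_id": run.model_id,
                    "ensemble_id": run.ensemble_id,
                    "region_id": run.region_id,
                    "year": years,
                    "month": months,
                    "log_chl": run.series,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_runs_csv(path) -> list[ClimateRunSeries]:
    df = pd.read_csv(path)
    runs = []
    for (model_id, ensemble_id, region_id), g in df.groupby(
        ["model_id", "ensemble_id", "region_id"], sort=True
    ):
        g = g.sort_values(["year", "month"])
        runs.append(
            ClimateRunSeries(
                model_id=str(model_id),
                ensemble_id=str(ensemble_id),
                region_id=int(region_id),
                series=g["log_chl"].to_numpy(),
                start_month=(int(g["year"].iloc[0]), int(g["month"].iloc[0])),
            )
        )
    return runs
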