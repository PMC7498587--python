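"""Grid and region bookkeeping: areas, downscaling, regional averaging.

Regions play the role of Longhurst-style biogeochemical provinces: every
included grid cell belongs to exactly one region, and the trend model is
fitted independently within each.  Cell areas come from the spherical-zone
formula so that regional averages and the global weighting can be
area-aware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .errors import InsufficientDataError, InvalidConfigurationError
from .fields import ChlField, calendar_months

EARTH_RADIUS_KM = 6371.0

#: marker for cells excluded from every region
NO_REGION = -1


def cell_area_km2(lat_center: float, cell_size: float) -> float:
    """Area of a ``cell_size`` x ``cell_size`` degree cell centered at ``lat_center``.

    Spherical zone formula: ``R^2 * dlon * (sin(lat+h) - sin(lat-h))`` with
    ``h`` the half cell size.  Exact on the sphere, so summing over a global
    grid recovers ``4 pi R^2``.
    """
    lat_center = float(lat_center)
    half = cell_size / 2.0
    if abs(lat_center) + half > 90.0 + 1e-12:
        raise ValueError(f"cell at lat {lat_center} with size {cell_size} exceeds the pole")
    h = np.deg2rad(half)
    lat = np.deg2rad(lat_center)
    dlon = np.deg2rad(cell_size)
    return float(EARTH_RADIUS_KM**2 * dlon * (np.sin(lat + h) - np.sin(lat - h)))


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in degrees (broadcasting)."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances_km(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Dense great-circle distance matrix for a list of cell centers."""
    return haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


@dataclass
class RegionMask:
    """Cell-to-region assignment with per-cell areas.

    ``region_of_cell`` holds integer region ids (``NO_REGION`` for excluded
    cells); ``cell_area_km2`` the spherical cell areas; coordinates are cell
    centers aligned with the fields the mask will be applied to.
    """

    region_of_cell: np.ndarray
    cell_area_km2: np.ndarray
    region_ids: list[int]
    lat_centers: np.ndarray
    lon_centers: np.ndarray

    def __post_init__(self) -> None:
        self.region_of_cell = np.asarray(self.region_of_cell, dtype=int)
        self.cell_area_km2 = np.asarray(self.cell_area_km2, dtype=float)
        if self.region_of_cell.shape != self.cell_area_km2.shape:
            raise ValueError("region grid and area grid shapes differ")
        present = set(np.unique(self.region_of_cell).tolist()) - {NO_REGION}
        if not present <= set(self.region_ids):
            raise ValueError("region grid contains ids missing from region_ids")
        included = self.region_of_cell != NO_REGION
        if np.any(self.cell_area_km2[included] <= 0):
            raise ValueError("included cells must have positive area")

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_of_cell.shape

    def cells_of(self, region_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells belonging to ``region_id``."""
        if region_id not in self.region_ids:
            raise KeyError(f"unknown region id {region_id!r}")
        return np.nonzero(self.region_of_cell == region_id)

    def region_area_km2(self, region_id: int) -> float:
        rows, cols = self.cells_of(region_id)
        return float(self.cell_area_km2[rows, cols].sum())

    def to_xarray(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "region": (("lat", "lon"), self.region_of_cell),
                "area_km2": (("lat", "lon"), self.cell_area_km2),
            },
            coords={"lat": self.lat_centers, "lon": self.lon_centers},
            attrs={"no_region": NO_REGION, "region_ids": json.dumps(list(self.region_ids))},
        )

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path)

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "RegionMask":
        return cls(
            region_of_cell=np.asarray(ds["region"].values, dtype=int),
            cell_area_km2=np.asarray(ds["area_km2"].values, dtype=float),
            region_ids=list(json.loads(ds.attrs["region_ids"])),
            lat_centers=np.asarray(ds["lat"].values, dtype=float),
            lon_centers=np.asarray(ds["lon"].values, dtype=float),
        )

    @classmethod
    def from_netcdf(cls, path) -> "RegionMask":
        with xr.open_dataset(path) as ds:
            return cls.from_xarray(ds.load())

    def registry_json(self) -> str:
        """JSON region registry: id, cell count, areal extent."""
        recs = [
            {
                "region_id": int(r),
                "n_cells": int((self.region_of_cell == r).sum()),
                "area_km2": self.region_area_km2(int(r)),
            }
            for r in self.region_ids
        ]
        return json.dumps(recs, indent=2)


def downscale_to_one_degree(field: ChlField, target_resolution: float = 1.0) -> ChlField:
    """Box-average a finer-resolution field onto a coarser grid.

    Each coarse cell is the arithmetic mean of its non-missing fine cells;
    a coarse cell is missing only when every fine cell in its box is.
    """
    nlat, nlon, _ = field.shape
    fine_res_lat = abs(float(field.lat_centers[1] - field.lat_centers[0])) if nlat > 1 else target_resolution
    fine_res_lon = abs(float(field.lon_centers[1] - field.lon_centers[0])) if nlon > 1 else target_resolution
    ratio_lat = target_resolution / fine_res_lat
    ratio_lon = target_resolution / fine_res_lon
    for name, r in (("latitude", ratio_lat), ("longitude", ratio_lon)):
        if abs(r - round(r)) > 1e-9 or round(r) < 1:
            raise InvalidConfigurationError(
                f"{name} resolution does not nest an integer number of fine cells per box (ratio {r})"
            )
    klat, klon = int(round(ratio_lat)), int(round(ratio_lon))
    if nlat % klat or nlon % klon:
        raise InvalidConfigurationError("fine grid extent is not a whole number of target boxes")

    v = field.values.reshape(nlat // klat, klat, nlon // klon, klon, field.n_months)
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(v, axis=(1, 3))
    lat = field.lat_centers.reshape(-1, klat).mean(axis=1)
    lon = field.lon_centers.reshape(-1, klon).mean(axis=1)
    return ChlField(values=coarse, lat_centers=lat, lon_centers=lon, start_month=field.start_month)


def regional_mean_series(
    field: ChlField, mask: RegionMask, region_id: int, area_weighted: bool = True
) -> np.ndarray:
    """Monthly regional-mean series (area-weighted by default).

    Months with no data in the region come back NaN.
    """
    rows, cols = mask.cells_of(region_id)
    vals = field.values[rows, cols, :]  # (n_cells, T)
    w = mask.cell_area_km2[rows, cols] if area_weighted else np.ones(rows.size)
    ok = np.isfinite(vals)
    wsum = (w[:, None] * ok).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, np.nansum(w[:, None] * np.where(ok, vals, 0.0), axis=0) / wsum, np.nan)
    return out


def regional_mean_chl(field: ChlField, mask: RegionMask, region_id: int) -> float:
    """Record-average chlorophyll in natural units (mg m^-3) for a region.

    Un-logs the field first so the value reflects actual concentration; used
    for the chl-and-area global weighting.
    """
    rows, cols = mask.cells_of(region_id)
    vals = np.exp(field.values[rows, cols, :])
    w = np.broadcast_to(mask.cell_area_km2[rows, cols][:, None], vals.shape)
    ok = np.isfinite(vals)
    if not ok.any():
        raise InsufficientDataError(f"region {region_id} has no data")
    return float(np.nansum(np.where(ok, vals * w, 0.0)) / (w * ok).sum())


def climatology_peak_month(series: np.ndarray, start_month: tuple[int, int]) -> int:
    """Calendar month (1..12) at which the across-years mean of the series peaks.

    Fixes the phase of the seasonal harmonic so its crest lands on the
    climatological chlorophyll maximum.  Ties break to the earliest month.
    """
    series = np.asarray(series, dtype=float)
    if np.isfinite(series).sum() < 12:
        raise InsufficientDataError("need at least 12 months with data for a climatology")
    months = calendar_months(start_month, series.size)
    clim = np.full(12, np.nan)
    for m in range(1, 13):
        sel = series[months == m]
        sel = sel[np.isfinite(sel)]
        if sel.size == 0:
            raise InsufficientDataError(f"calendar month {m} has no data in any year")
        clim[m - 1] = sel.mean()
    return int(np.argmax(clim)) + 1  # argmax returns the first (earliest) maximum
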