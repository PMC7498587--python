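"""Gridded monthly log-chlorophyll fields.

The satellite record is modelled on the natural-log scale, so a field holds
``ln(chl / (mg m^-3))`` on a regular latitude-longitude grid of cell centers
with one layer per month.  Missing cells (clouds, no retrieval) are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr


def month_range(start_month: tuple[int, int], n_months: int) -> pd.DatetimeIndex:
    """Contiguous monthly timestamps starting at ``(year, month)``."""
    y, m = start_month
    return pd.date_range(f"{y:04d}-{m:02d}-01", periods=n_months, freq="MS")


def calendar_months(start_month: tuple[int, int], n_months: int) -> np.ndarray:
    """Calendar month-of-year (1..12) for each of ``n_months`` time steps."""
    _, m0 = start_month
    return (m0 - 1 + np.arange(n_months)) % 12 + 1


@dataclass
class ChlField:
    """Monthly log-chl observations Z on a lat x lon grid.

    values has shape (n_lat, n_lon, n_months); NaN marks missing cells.
    """

    values: np.ndarray
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    start_month: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (lat, lon, month)")
        if self.values.shape[0] != self.lat_centers.size:
            raise ValueError("lat_centers length does not match values")
        if self.values.shape[1] != self.lon_centers.size:
            raise ValueError("lon_centers length does not match values")

    @property
    def n_months(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def calendar_months(self) -> np.ndarray:
        return calendar_months(self.start_month, self.n_months)

    def to_xarray(self) -> xr.Dataset:
        times = month_range(self.start_month, self.n_months)
        da = xr.DataArray(
            self.values,
            dims=("lat", "lon", "time"),
            coords={"lat": self.lat_centers, "lon": self.lon_centers, "time": times},
            name="log_chl",
            attrs={
                "units": "ln(mg m-3)",
                "long_name": "natural log of chlorophyll-a concentration",
                "missing_value": "NaN",
            },
        )
        ds = da.to_dataset()
        ds.attrs["start_year"] = self.start_month[0]
        ds.attrs["start_month"] = self.start_month[1]
        return ds

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path)

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "ChlField":
        da = ds["log_chl"].transpose("lat", "lon", "time")
        t0 = pd.Timestamp(da["time"].values[0])
        return cls(
            values=np.asarray(da.values, dtype=float),
            lat_centers=np.asarray(da["lat"].values, dtype=float),
            lon_centers=np.asarray(da["lon"].values, dtype=float),
            start_month=(int(t0.year), int(t0.month)),
        )

    @classmethod
    def from_netcdf(cls, path) -> "ChlField":
        with xr.open_dataset(path) as ds:
            return cls.from_xarray(ds.load())
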