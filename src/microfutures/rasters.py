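"""Georeferenced raster grids and the file formats shared by all stages.

Rasters are square-celled, north-up, in a projected metric CRS (the study
landscape convention is British National Grid, EPSG:27700).  Row 0 is the
northernmost row and a cell value refers to the cell centre.  Geographic
lat/lon grids are rejected: every terrain operator downstream assumes metric
cell sizes.

On disk a 2-D layer is an ESRI ASCII grid (``.asc``) with a ``.prj`` sidecar
holding the CRS identifier; (time, y, x) stacks are NetCDF with a CF time
axis; station and logger series are CSV with ISO-8601 timestamps.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "LandSeaMask",
    "LoggerSeries",
    "read_ascii_grid",
    "write_ascii_grid",
    "align_to",
    "read_stack",
    "write_stack",
    "read_logger_csv",
    "write_logger_csv",
    "DAILY_COLUMNS",
    "HOURLY_COLUMNS",
    "validate_daily",
    "validate_hourly",
]

_GEOGRAPHIC_CRS = {"EPSG:4326", "EPSG:4258", "WGS84", "CRS84"}


@dataclasses.dataclass
class RasterGrid:
    """A single georeferenced 2-D field.

    Parameters
    ----------
    values
        2-D float array, row-major with row 0 northernmost.  Missing cells
        are NaN in memory; ``nodata`` is only the on-disk sentinel.
    origin_x, origin_y
        Map coordinates (m) of the *top-left corner* of the grid.
    cell_size
        Cell edge length in metres (cells are square).
    crs_id
        Projected CRS identifier, e.g. ``"EPSG:27700"``.
    nodata
        Sentinel written to file for NaN cells.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_id: str = "EPSG:27700"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.crs_id.upper() in _GEOGRAPHIC_CRS:
            raise ValueError(
                f"geographic CRS {self.crs_id!r} not supported: rasters must "
                "use a projected metric CRS (e.g. EPSG:27700)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell centre (each shape ny, nx)."""
        j = np.arange(self.nx)
        i = np.arange(self.ny)
        x = self.origin_x + (j + 0.5) * self.cell_size
        y = self.origin_y - (i + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y)."""
        j = int((x - self.origin_x) // self.cell_size)
        i = int((self.origin_y - y) // self.cell_size)
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return i, j

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=np.float32),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            crs_id=self.crs_id,
            nodata=self.nodata,
        )

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size == other.cell_size
            and self.crs_id == other.crs_id
        )


class LandSeaMask(RasterGrid):
    """RasterGrid whose finite values are exactly 0 (sea) or 1 (land)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("land/sea mask may only contain 0, 1 or NaN")

    @property
    def land(self) -> np.ndarray:
        return self.values == 1.0

    @property
    def sea(self) -> np.ndarray:
        return self.values == 0.0


@dataclasses.dataclass
class LoggerSeries:
    """A near-surface temperature logger: a point series at a known height."""

    x: float
    y: float
    height_m: float
    records: pd.Series  # DatetimeIndex (UTC) -> temperature degC
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError("sensor height must be positive")
        if not self.records.index.is_monotonic_increasing or self.records.index.has_duplicates:
            raise ValueError("logger timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write ``grid`` as an ESRI ASCII grid plus a ``.prj`` CRS sidecar.

    Values are written with 9 significant digits, enough to round-trip
    float32 bit-exactly.
    """
    path = Path(path)
    vals = np.where(np.isfinite(grid.values), grid.values, np.float32(grid.nodata))
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.ny * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.9g")
    path.with_suffix(".prj").write_text(grid.crs_id + "\n")
    return path


def read_ascii_grid(path: str | Path, mask: bool = False) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`.

    The CRS sidecar is required: a grid without a CRS is refused rather than
    silently defaulted.
    """
    path = Path(path)
    prj = path.with_suffix(".prj")
    if not prj.exists():
        raise FileNotFoundError(
            f"no CRS sidecar {prj}: refusing to guess a coordinate system"
        )
    crs_id = prj.read_text().strip()
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=np.float64)
    values = np.atleast_2d(values).astype(np.float32)
    nodata = np.float32(header["nodata_value"])
    values = np.where(values == nodata, np.nan, values).astype(np.float32)
    cls = LandSeaMask if mask else RasterGrid
    return cls(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + header["nrows"] * header["cellsize"],
        cell_size=header["cellsize"],
        crs_id=crs_id,
        nodata=header["nodata_value"],
    )


# ---------------------------------------------------------------------------
# Resampling


def align_to(grid: RasterGrid, template: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Resample ``grid`` onto ``template``'s geometry.

    ``method`` is ``"nearest"`` (categorical layers) or ``"bilinear"``
    (continuous fields; exact for fields affine in x, y).  Both grids must
    share a CRS.  Template cells whose centres fall outside ``grid`` are
    filled by edge extension.
    """
    if grid.crs_id != template.crs_id:
        raise ValueError(f"CRS mismatch: {grid.crs_id} vs {template.crs_id}")
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    tx, ty = template.cell_centers()
    # fractional (row, col) indices into the source grid, cell-centre registered
    col = (tx - grid.origin_x) / grid.cell_size - 0.5
    row = (grid.origin_y - ty) / grid.cell_size - 0.5
    order = 0 if method == "nearest" else 1
    out = ndimage.map_coordinates(
        grid.values.astype(np.float64),
        [row.ravel(), col.ravel()],
        order=order,
        mode="nearest",
    ).reshape(template.shape)
    new = template.copy_with(out)
    new.nodata = grid.nodata
    if isinstance(grid, LandSeaMask):
        return LandSeaMask(new.values, new.origin_x, new.origin_y, new.cell_size, new.crs_id, new.nodata)
    return new


# ---------------------------------------------------------------------------
# NetCDF (time, y, x) stacks


def write_stack(da: xr.DataArray, path: str | Path, crs_id: str = "EPSG:27700") -> Path:
    """Write a (time, y, x) DataArray as NetCDF3 with a CF time axis."""
    path = Path(path)
    da = da.astype(np.float32)
    da.attrs.setdefault("crs_id", crs_id)
    enc = {da.name or "data": {"dtype": "f4"}}
    ds = da.to_dataset(name=da.name or "data")
    ds.to_netcdf(path, engine="scipy", encoding=enc)
    return path


def read_stack(path: str | Path, name: str | None = None) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    if name is None:
        name = next(iter(ds.data_vars))
    da = ds[name].load()
    ds.close()
    return da


# ---------------------------------------------------------------------------
# Weather table schemas

DAILY_COLUMNS = ("tmax", "tmin", "swdown", "shum", "pres", "wind", "precip")
HOURLY_COLUMNS = ("temp", "swrad", "shum", "pres", "wind", "winddir")


def validate_daily(df: pd.DataFrame) -> pd.DataFrame:
    """Check a daily weather table: tmax/tmin degC, swdown MJ m-2 day-1,
    shum kg kg-1, pres kPa, wind m s-1 at 2 m, precip mm day-1."""
    missing = set(DAILY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"daily weather missing columns {sorted(missing)}")
    if (df["tmax"] < df["tmin"]).any():
        raise ValueError("tmax < tmin")
    if (df["precip"] < 0).any() or (df["swdown"] < 0).any():
        raise ValueError("negative precip or shortwave")
    if ((df["shum"] <= 0) | (df["shum"] >= 0.1)).any():
        raise ValueError("specific humidity outside (0, 0.1)")
    return df


def validate_hourly(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(HOURLY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hourly weather missing columns {sorted(missing)}")
    if (df["swrad"] < 0).any():
        raise ValueError("negative shortwave")
    return df


# ---------------------------------------------------------------------------
# Logger CSV


def write_logger_csv(logger: LoggerSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"timestamp": logger.records.index.strftime("%Y-%m-%dT%H:%M:%SZ"),
                       "temp": logger.records.to_numpy()})
    with open(path, "w") as fh:
        fh.write(f"# x={logger.x!r} y={logger.y!r} height_m={logger.height_m!r} site={logger.site_id}\n")
        df.to_csv(fh, index=False)
    return path


def read_logger_csv(path: str | Path) -> LoggerSeries:
    path = Path(path)
    with open(path) as fh:
        meta = dict(
            item.split("=", 1) if "=" in item else (item, "")
            for item in fh.readline().lstrip("# ").split()
        )
        df = pd.read_csv(fh, parse_dates=["timestamp"])
    rec = pd.Series(df["temp"].to_numpy(), index=pd.DatetimeIndex(df["timestamp"], tz="UTC"))
    return LoggerSeries(
        x=float(meta["x"]), y=float(meta["y"]), height_m=float(meta["height_m"]),
        records=rec, site_id=meta.get("site", ""),
    )
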