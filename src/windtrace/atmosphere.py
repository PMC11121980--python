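"""Gridded wind/temperature fields and synthetic atmosphere generation.

The meteorological data model is a regular 4-D grid (time x height-AGL x
lat x lon) carrying the horizontal wind components ``u`` (eastward, m/s),
``v`` (northward, m/s) and air temperature (degC).  Real fields come from a
mesoscale model (e.g. hourly 10-km WRF output, externally preprocessed to
height-above-ground levels); the generators here build synthetic fields with
the same structure for testing and demonstration.

Interpolation between nodes is multilinear (trilinear in space, linear in
time), the simplest scheme consistent with hourly, ~10-km data; it is exact
at the nodes and a convex combination of the 16 enclosing corner values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "Domain",
    "WindGrid",
    "OutOfDomainError",
    "make_uniform_field",
    "make_monsoon_field",
    "sample",
    "read_netcdf",
    "write_netcdf",
]

_EPOCH = np.datetime64("1970-01-01T00:00:00", "s")


class OutOfDomainError(ValueError):
    """A sample query fell outside the grid hull.

    The trajectory engine consumes this as a boundary exit; other callers
    should treat it as a plain error.
    """


def _to_seconds(t) -> float:
    """Coerce datetime / np.datetime64 / ISO string to POSIX seconds."""
    return float((np.datetime64(t, "s") - _EPOCH) / np.timedelta64(1, "s"))


@dataclass(frozen=True)
class Domain:
    """Axis-aligned simulation domain (the trajectory 'simulation boundary')."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    height_min: float = 0.0
    height_max: float = 2000.0
    time_start: datetime | str | np.datetime64 = "2019-01-01T00:00:00"
    time_end: datetime | str | np.datetime64 = "2019-01-02T00:00:00"

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max):
            raise ValueError("degenerate domain: lat_min must be < lat_max")
        if not (self.lon_min < self.lon_max):
            raise ValueError("degenerate domain: lon_min must be < lon_max")
        if not (self.height_min < self.height_max):
            raise ValueError("degenerate domain: height_min must be < height_max")
        if not (_to_seconds(self.time_start) < _to_seconds(self.time_end)):
            raise ValueError("degenerate domain: time_start must be < time_end")


@dataclass
class WindGrid:
    """Regular 4-D field of wind components and temperature.

    Heights are metres above ground level (AGL), matching the fixed-layer
    flight-altitude design; longitudes live in [-180, 180) with no
    antimeridian wraparound.
    """

    times: np.ndarray          # datetime64[s], strictly increasing
    heights_agl: np.ndarray    # m AGL, strictly increasing
    lats: np.ndarray           # deg N, strictly increasing
    lons: np.ndarray           # deg E, strictly increasing
    u: np.ndarray              # m/s eastward, (time, height, lat, lon)
    v: np.ndarray              # m/s northward
    temperature: np.ndarray    # degC
    grid_spacing_km: float = 10.0
    _interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.heights_agl = np.asarray(self.heights_agl, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        shape = (
            self.times.size,
            self.heights_agl.size,
            self.lats.size,
            self.lons.size,
        )
        for name in ("u", "v", "temperature"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape} "
                    "(time, height, lat, lon)"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        for name, coord in (
            ("times", self.times.astype(float)),
            ("heights_agl", self.heights_agl),
            ("lats", self.lats),
            ("lons", self.lons),
        ):
            if coord.size < 2:
                raise ValueError(f"{name} needs at least 2 nodes")
            if not np.all(np.diff(coord) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.heights_agl[0] < 0 or self.heights_agl[-1] > 5000:
            raise ValueError("heights_agl must lie within [0, 5000] m")
        if self.lons[0] < -180 or self.lons[-1] >= 180:
            raise ValueError("longitudes must lie in [-180, 180)")

    # -- sampling ----------------------------------------------------------

    @property
    def _times_s(self) -> np.ndarray:
        return self.times.astype("datetime64[s]").astype(float)

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            values = np.stack([self.u, self.v, self.temperature], axis=-1)
            self._interp = RegularGridInterpolator(
                (self._times_s, self.heights_agl, self.lats, self.lons),
                values,
                method="linear",
                bounds_error=True,
            )
        return self._interp

    def contains(self, t, lat: float, lon: float, h_agl: float) -> bool:
        ts = _to_seconds(t)
        times_s = self._times_s
        return bool(
            times_s[0] <= ts <= times_s[-1]
            and self.heights_agl[0] <= h_agl <= self.heights_agl[-1]
            and self.lats[0] <= lat <= self.lats[-1]
            and self.lons[0] <= lon <= self.lons[-1]
        )

    def sample(self, t, lat: float, lon: float, h_agl: float):
        """Quadrilinear interpolation of (u, v, temperature) at a point.

        Raises :class:`OutOfDomainError` when the query leaves the grid hull.
        """
        if not self.contains(t, lat, lon, h_agl):
            raise OutOfDomainError(
                f"query (t={t}, lat={lat}, lon={lon}, h={h_agl}) outside grid hull"
            )
        out = self._interpolator()([[_to_seconds(t), h_agl, lat, lon]])[0]
        return float(out[0]), float(out[1]), float(out[2])


def sample(grid: WindGrid, t, lat: float, lon: float, h_agl: float):
    """Functional alias for :meth:`WindGrid.sample`."""
    return grid.sample(t, lat, lon, h_agl)


# -- synthetic field generators -------------------------------------------


def _axes(domain: Domain, resolution: Sequence[int]):
    nt, nh, nlat, nlon = resolution
    if min(nt, nh, nlat, nlon) < 2:
        raise ValueError("resolution must give at least 2 nodes per dimension")
    t0 = np.datetime64(domain.time_start, "s")
    t1 = np.datetime64(domain.time_end, "s")
    span = (t1 - t0) / np.timedelta64(1, "s")
    times = t0 + (np.linspace(0.0, span, nt)).astype("timedelta64[s]")
    heights = np.linspace(domain.height_min, domain.height_max, nh)
    lats = np.linspace(domain.lat_min, domain.lat_max, nlat)
    lons = np.linspace(domain.lon_min, domain.lon_max, nlon)
    spacing_km = float(np.mean(np.diff(lats)) * 111.0)
    return times, heights, lats, lons, spacing_km


def make_uniform_field(
    u0: float,
    v0: float,
    t0: float,
    domain: Domain,
    resolution: Sequence[int] = (25, 6, 11, 11),
) -> WindGrid:
    """Constant wind/temperature everywhere — the basic trajectory fixture."""
    times, heights, lats, lons, spacing = _axes(domain, resolution)
    shape = (times.size, heights.size, lats.size, lons.size)
    return WindGrid(
        times=times,
        heights_agl=heights,
        lats=lats,
        lons=lons,
        u=np.full(shape, float(u0)),
        v=np.full(shape, float(v0)),
        temperature=np.full(shape, float(t0)),
        grid_spacing_km=spacing,
    )


def make_monsoon_field(
    season: str,
    speed: float,
    t_surface: float,
    lapse: float,
    domain: Domain,
    resolution: Sequence[int] = (25, 6, 11, 11),
    seed: int | None = None,
) -> WindGrid:
    """Idealised monsoon flow over the study region.

    ``spring`` gives a southwesterly (u > 0, v > 0, transport toward the
    north-east, the flow that carries spring immigrants into Yunnan);
    ``autumn`` gives the reversed northeasterly (u < 0, v < 0).  Temperature
    falls linearly with height at ``lapse`` degC per 100 m.  A seeded smooth
    sinusoidal perturbation (amplitude 30% of the mean component) adds
    spatial structure without ever flipping the component signs.
    """
    if season not in ("spring", "autumn"):
        raise ValueError(f"unknown season {season!r}: expected 'spring' or 'autumn'")
    if speed < 0:
        raise ValueError("speed must be >= 0")
    times, heights, lats, lons, spacing = _axes(domain, resolution)
    sign = 1.0 if season == "spring" else -1.0
    comp = speed / np.sqrt(2.0)

    tt = np.arange(times.size)[:, None, None, None]
    hh = heights[None, :, None, None]
    la = lats[None, None, :, None]
    lo = lons[None, None, None, :]

    if seed is not None:
        rng = np.random.default_rng(seed)
        ph = rng.uniform(0, 2 * np.pi, size=4)
        wob_u = 0.3 * np.sin(
            2 * np.pi * (la - lats[0]) / max(lats[-1] - lats[0], 1e-9) + ph[0]
        ) * np.cos(2 * np.pi * (lo - lons[0]) / max(lons[-1] - lons[0], 1e-9) + ph[1])
        wob_v = 0.3 * np.sin(
            2 * np.pi * (lo - lons[0]) / max(lons[-1] - lons[0], 1e-9) + ph[2]
        ) * np.cos(0.1 * tt + ph[3])
    else:
        wob_u = wob_v = 0.0

    shape = (times.size, heights.size, lats.size, lons.size)
    u = np.broadcast_to(sign * comp * (1.0 + wob_u), shape).copy()
    v = np.broadcast_to(sign * comp * (1.0 + wob_v), shape).copy()
    temp = np.broadcast_to(t_surface - lapse * hh / 100.0, shape).copy()
    return WindGrid(
        times=times,
        heights_agl=heights,
        lats=lats,
        lons=lons,
        u=u,
        v=v,
        temperature=temp,
        grid_spacing_km=spacing,
    )


# -- NetCDF I/O ------------------------------------------------------------

# accepted variable spellings, first match wins
_VAR_ALIASES = {
    "u": ("u", "U", "ua", "u_wind", "eastward_wind"),
    "v": ("v", "V", "va", "v_wind", "northward_wind"),
    "temperature": ("temperature", "T", "t", "ta", "air_temperature", "temp"),
}
_DIM_ALIASES = {
    "time": ("time",),
    "height": ("height", "height_agl", "level", "z"),
    "lat": ("lat", "latitude"),
    "lon": ("lon", "longitude"),
}


def write_netcdf(grid: WindGrid, path) -> None:
    """Write a WindGrid as CF-style NetCDF (classic format)."""
    ds = xr.Dataset(
        {
            "u": (("time", "height", "lat", "lon"), grid.u,
                  {"units": "m s-1", "standard_name": "eastward_wind"}),
            "v": (("time", "height", "lat", "lon"), grid.v,
                  {"units": "m s-1", "standard_name": "northward_wind"}),
            "temperature": (("time", "height", "lat", "lon"), grid.temperature,
                            {"units": "degC", "standard_name": "air_temperature"}),
        },
        coords={
            "time": grid.times,
            "height": ("height", grid.heights_agl,
                       {"units": "m", "positive": "up",
                        "long_name": "height above ground level"}),
            "lat": ("lat", grid.lats, {"units": "degrees_north"}),
            "lon": ("lon", grid.lons, {"units": "degrees_east"}),
        },
        attrs={
            "Conventions": "CF-1.8",
            "grid_metadata": json.dumps({"grid_spacing_km": grid.grid_spacing_km}),
        },
    )
    encoding = {"time": {"dtype": "float64",
                         "units": "seconds since 1970-01-01T00:00:00"}}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def _find(ds_names, aliases, kind, path):
    for a in aliases:
        if a in ds_names:
            return a
    raise ValueError(
        f"{path}: missing required {kind} (looked for any of {list(aliases)})"
    )


def read_netcdf(path, var_aliases: dict | None = None) -> WindGrid:
    """Read a WindGrid from a CF-style NetCDF file.

    Variable names may deviate from u/v/temperature via ``var_aliases``
    (mapping canonical name -> actual name).  Kelvin temperatures are
    converted to degC when the units attribute says so; descending latitude
    or longitude axes are normalised to ascending with fields re-ordered.
    """
    with xr.open_dataset(path, engine="scipy", decode_times=True) as ds:
        ds = ds.load()
    aliases = dict(_VAR_ALIASES)
    if var_aliases:
        for k, name in var_aliases.items():
            aliases[k] = (name,) + tuple(aliases.get(k, ()))
    names = {k: _find(set(ds.data_vars), v, f"variable '{k}'", path)
             for k, v in aliases.items()}
    dims = {k: _find(set(ds.dims), v, f"dimension '{k}'", path)
            for k, v in _DIM_ALIASES.items()}

    # normalise descending spatial axes
    for d in ("lat", "lon", "height"):
        coord = ds[dims[d]].values
        if coord.size >= 2 and coord[0] > coord[-1]:
            ds = ds.isel({dims[d]: slice(None, None, -1)})

    order = (dims["time"], dims["height"], dims["lat"], dims["lon"])
    u = ds[names["u"]].transpose(*order).values.astype(float)
    v = ds[names["v"]].transpose(*order).values.astype(float)
    temp = ds[names["temperature"]].transpose(*order).values.astype(float)
    t_units = str(ds[names["temperature"]].attrs.get("units", "degC"))
    if t_units.strip() in ("K", "kelvin", "Kelvin"):
        temp = temp - 273.15

    meta = {}
    if "grid_metadata" in ds.attrs:
        try:
            meta = json.loads(ds.attrs["grid_metadata"])
        except (TypeError, json.JSONDecodeError):
            meta = {}
    times = ds[dims["time"]].values
    if not np.issubdtype(times.dtype, np.datetime64):
        raise ValueError(f"{path}: time coordinate did not decode to datetimes")
    return WindGrid(
        times=times,
        heights_agl=ds[dims["height"]].values.astype(float),
        lats=ds[dims["lat"]].values.astype(float),
        lons=ds[dims["lon"]].values.astype(float),
        u=u,
        v=v,
        temperature=temp,
        grid_spacing_km=float(meta.get("grid_spacing_km", 10.0)),
    )
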