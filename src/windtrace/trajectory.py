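"""Lagrangian trajectory integration for wind-borne moth migration.

Virtual moths are advected passively by the horizontal wind at fixed
altitudes above ground (their movement direction is assumed to align with
the wind; self-powered airspeed and heading are deliberately excluded).
Forward runs start at the take-off instant and predict landing areas;
backward runs start at the landing deadline and integrate against the wind
back toward take-off, inferring source areas.

Rules per run:

* one trajectory per release altitude (default 100..1000 m AGL by 100 m);
* positions are recorded every ``step`` (default 10 min);
* a run is gated by ambient temperature at the release point: below the
  flight threshold (default 13.1 degC, the published Spodoptera frugiperda
  value adopted for S. litura) the moth never takes off and the trajectory
  is a single point (``temperature_stop``);
* integration ends when the flight window is exhausted (``window_end``) or
  when the next proposed position would leave the grid domain
  (``boundary_exit``; the last inside point is kept, which is what produces
  the characteristic pile-up of endpoints along the domain edge).

Meters are converted to degrees with 110,574 m per degree latitude and
111,320 * cos(lat) m per degree longitude; at the few-hundred-km scale of
single-night flights a great-circle treatment changes nothing material.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta
from typing import Iterable, Literal, Sequence

from .atmosphere import OutOfDomainError, WindGrid
from .solar import FlightWindow, Site, flight_window

__all__ = [
    "TrajectoryParams",
    "ReleaseSpec",
    "TrajectoryPoint",
    "Trajectory",
    "simulate",
    "endpoints",
    "batch_simulate",
    "trajectories_to_csv",
    "endpoints_to_geojson",
    "M_PER_DEG_LAT",
    "M_PER_DEG_LON_EQ",
]

M_PER_DEG_LAT = 110_574.0
M_PER_DEG_LON_EQ = 111_320.0

DEFAULT_ALTITUDES = (100.0, 200.0, 300.0, 400.0, 500.0,
                     600.0, 700.0, 800.0, 900.0, 1000.0)

Termination = Literal["window_end", "boundary_exit", "temperature_stop"]


@dataclass(frozen=True)
class TrajectoryParams:
    step: timedelta = timedelta(minutes=10)
    altitudes_agl: Sequence[float] = DEFAULT_ALTITUDES
    temp_threshold: float = 13.1
    temp_gate_mode: Literal["takeoff_only", "continuous"] = "takeoff_only"
    integrator: Literal["euler", "midpoint"] = "euler"

    def __post_init__(self) -> None:
        if self.step <= timedelta(0):
            raise ValueError("step must be positive")
        if any(a <= 0 for a in self.altitudes_agl):
            raise ValueError("altitudes must be positive (m AGL)")
        if not math.isfinite(self.temp_threshold):
            # +-inf is allowed for gate-disabling sensitivity runs
            pass
        if self.temp_gate_mode not in ("takeoff_only", "continuous"):
            raise ValueError(f"unknown temp_gate_mode {self.temp_gate_mode!r}")
        if self.integrator not in ("euler", "midpoint"):
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass(frozen=True)
class ReleaseSpec:
    """One release: a point, a night, and a direction of integration."""

    lat: float
    lon: float
    date: _date
    direction: Literal["forward", "backward"]
    window: FlightWindow
    site_name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward/backward, got {self.direction!r}")


@dataclass(frozen=True)
class TrajectoryPoint:
    time: datetime
    lat: float
    lon: float
    altitude_agl: float
    u: float
    v: float
    temperature: float


@dataclass
class Trajectory:
    release: ReleaseSpec
    altitude_agl: float
    points: list[TrajectoryPoint]
    termination: Termination

    @property
    def endpoint(self) -> TrajectoryPoint:
        return self.points[-1]


def _advance(lat: float, lon: float, u: float, v: float, dt_s: float,
             sign: float) -> tuple[float, float]:
    dlat = sign * v * dt_s / M_PER_DEG_LAT
    dlon = sign * u * dt_s / (M_PER_DEG_LON_EQ * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def simulate(release: ReleaseSpec, grid: WindGrid,
             params: TrajectoryParams = TrajectoryParams()) -> list[Trajectory]:
    """Integrate one release at every configured altitude.

    Forward runs step from the window's take-off time toward the landing
    deadline; backward runs step from the landing deadline back toward
    take-off with the velocity sign flipped (time reversal through the
    stored fields).
    """
    win = release.window
    forward = release.direction == "forward"
    t_start = win.takeoff if forward else win.landing_deadline
    t_stop = win.landing_deadline if forward else win.takeoff
    time_sign = 1.0 if forward else -1.0
    dt_s = params.step.total_seconds()

    grid_t0, grid_t1 = grid.times[0].item(), grid.times[-1].item()
    for t in (win.takeoff, win.landing_deadline):
        if not (grid_t0 <= t <= grid_t1):
            raise ValueError(
                f"flight window instant {t} outside grid time range "
                f"[{grid_t0}, {grid_t1}]"
            )
    if not grid.contains(t_start, release.lat, release.lon,
                         min(params.altitudes_agl)):
        raise ValueError(
            f"release origin ({release.lat}, {release.lon}) outside grid domain"
        )

    out: list[Trajectory] = []
    for alt in params.altitudes_agl:
        u, v, temp = grid.sample(t_start, release.lat, release.lon, alt)
        first = TrajectoryPoint(t_start, release.lat, release.lon, alt, u, v, temp)
        if temp < params.temp_threshold:
            out.append(Trajectory(release, alt, [first], "temperature_stop"))
            continue

        points = [first]
        termination: Termination = "window_end"
        t, lat, lon = t_start, release.lat, release.lon
        while True:
            remaining = (t_stop - t).total_seconds() * time_sign
            if remaining < dt_s - 1e-9:
                break
            u, v, temp = points[-1].u, points[-1].v, points[-1].temperature
            if params.integrator == "midpoint":
                mid_t = t + timedelta(seconds=time_sign * dt_s / 2.0)
                mid_lat, mid_lon = _advance(lat, lon, u, v, dt_s / 2.0, time_sign)
                try:
                    u, v, temp = grid.sample(mid_t, mid_lat, mid_lon, alt)
                except OutOfDomainError:
                    termination = "boundary_exit"
                    break
            nxt_t = t + timedelta(seconds=time_sign * dt_s)
            nxt_lat, nxt_lon = _advance(lat, lon, u, v, dt_s, time_sign)
            try:
                su, sv, st = grid.sample(nxt_t, nxt_lat, nxt_lon, alt)
            except OutOfDomainError:
                termination = "boundary_exit"
                break
            t, lat, lon = nxt_t, nxt_lat, nxt_lon
            points.append(TrajectoryPoint(t, lat, lon, alt, su, sv, st))
            if params.temp_gate_mode == "continuous" and st < params.temp_threshold:
                termination = "temperature_stop"
                break
        out.append(Trajectory(release, alt, points, termination))
    return out


def endpoints(trajectories: Iterable[Trajectory]) -> list[TrajectoryPoint]:
    """Last point of each trajectory: candidate landing (forward) or
    take-off (backward) locations."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories given")
    return [t.endpoint for t in trajectories]


def batch_simulate(
    sites: Sequence[Site],
    dates: Sequence[_date],
    grid: WindGrid,
    params: TrajectoryParams = TrajectoryParams(),
    directions: Sequence[str] = ("forward", "backward"),
) -> tuple[list[Trajectory], list[dict]]:
    """Deterministically enumerate (date, direction, altitude) runs.

    Returns (trajectories, failures); a failing run is recorded with its
    key and message instead of aborting the batch.
    """
    results: list[Trajectory] = []
    failures: list[dict] = []
    for d in sorted(dates):
        for site in sites:
            try:
                win = flight_window(site, d)
            except Exception as exc:  # noqa: BLE001 - logged per run
                failures.append({"date": str(d), "site": site.name, "error": str(exc)})
                continue
            for direction in directions:
                spec = ReleaseSpec(site.lat, site.lon, d, direction, win,
                                   site_name=site.name)
                try:
                    results.extend(simulate(spec, grid, params))
                except Exception as exc:  # noqa: BLE001
                    failures.append({
                        "date": str(d), "site": site.name,
                        "direction": direction, "error": str(exc),
                    })
    return results, failures


# -- serialization ---------------------------------------------------------


def trajectories_to_csv(trajectories: Sequence[Trajectory], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run_id", "date", "direction", "altitude_agl", "time",
                    "lat", "lon", "u", "v", "temperature", "termination"])
        for i, tr in enumerate(trajectories):
            for p in tr.points:
                w.writerow([
                    i, tr.release.date.isoformat(), tr.release.direction,
                    f"{tr.altitude_agl:g}", p.time.isoformat(),
                    f"{p.lat:.6f}", f"{p.lon:.6f}", f"{p.u:.4f}",
                    f"{p.v:.4f}", f"{p.temperature:.3f}", tr.termination,
                ])


def endpoints_to_geojson(trajectories: Sequence[Trajectory], path) -> None:
    feats = []
    for i, tr in enumerate(trajectories):
        p = tr.endpoint
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(p.lon, 6), round(p.lat, 6)]},
            "properties": {
                "run_id": i,
                "date": tr.release.date.isoformat(),
                "direction": tr.release.direction,
                "altitude_agl": tr.altitude_agl,
                "termination": tr.termination,
                "time": p.time.isoformat(),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
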