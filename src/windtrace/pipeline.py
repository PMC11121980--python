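"""End-to-end run orchestration with reproducible outputs.

Wires the two workflows together: (a) peak-night trajectory analysis —
flight windows, forward/backward trajectory batches over a wind grid,
endpoint attribution to regions; (b) seasonal trap-catch analysis —
monthly summaries, sex-ratio tests, optimal segmentation, ovary summaries.
Every run writes a manifest with a config hash and per-file checksums so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .atmosphere import Domain, WindGrid, make_monsoon_field, read_netcdf
from .regions import (RegionSet, attribute, aggregate, demo_regions,
                      load_regions, season_of)
from .solar import RUILI, Site
from .synth_trap import TrapSimConfig, generate
from .trajectory import (TrajectoryParams, batch_simulate, endpoints_to_geojson,
                         trajectories_to_csv)
from .trapstats import monthly_summary, ovary_summary, segmentation_scan, sex_ratio_chisq

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_PEAK_DATES"]

#: Study peak migration nights (spring, autumn per monitoring year).
DEFAULT_PEAK_DATES = (
    _date(2019, 4, 26), _date(2019, 11, 2),
    _date(2020, 5, 16), _date(2020, 11, 15),
    _date(2021, 5, 17), _date(2021, 10, 11),
    _date(2022, 4, 27), _date(2022, 10, 28),
    _date(2023, 4, 15), _date(2023, 11, 11),
)


@dataclass
class RunConfig:
    site: Site = RUILI
    peak_dates: tuple[_date, ...] = DEFAULT_PEAK_DATES
    grid_path: str | None = None      # None -> synthetic monsoon fields
    regions_path: str | None = None   # None -> synthetic demo rectangles
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    trap_sim: TrapSimConfig = field(default_factory=TrapSimConfig)
    seed: int = 0
    out_dir: str = "runs/demo"

    def to_dict(self) -> dict:
        return {
            "site": {"name": self.site.name, "lat": self.site.lat,
                     "lon": self.site.lon, "utc_offset": self.site.utc_offset},
            "peak_dates": [d.isoformat() for d in self.peak_dates],
            "grid_path": self.grid_path,
            "regions_path": self.regions_path,
            "trajectory": {
                "step_minutes": self.trajectory.step.total_seconds() / 60.0,
                "altitudes_agl": list(self.trajectory.altitudes_agl),
                "temp_threshold": self.trajectory.temp_threshold,
                "temp_gate_mode": self.trajectory.temp_gate_mode,
                "integrator": self.trajectory.integrator,
            },
            "trap_sim_years": list(self.trap_sim.years),
            "seed": self.seed,
            "version": __version__,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _demo_grid_for(site: Site, d: _date, seed: int) -> WindGrid:
    """Synthetic monsoon field covering one peak night around the site."""
    season = season_of(d)
    season = season if season in ("spring", "autumn") else "spring"
    domain = Domain(
        lat_min=site.lat - 8, lat_max=site.lat + 8,
        lon_min=site.lon - 9, lon_max=site.lon + 9,
        height_min=0.0, height_max=2000.0,
        time_start=f"{d.isoformat()}T00:00:00",
        time_end=f"{(d + pd.Timedelta(days=2)).isoformat()[:10]}T00:00:00",
    )
    t_surface = 26.0 if season == "spring" else 21.0
    return make_monsoon_field(season, speed=6.0, t_surface=t_surface,
                              lapse=0.65, domain=domain,
                              resolution=(49, 6, 17, 19), seed=seed)


def run_pipeline(config: RunConfig) -> Path:
    """Execute both workflows and write a manifest-tracked run directory."""
    if config.grid_path is not None and not Path(config.grid_path).exists():
        raise FileNotFoundError(f"grid file not found: {config.grid_path}")
    if config.regions_path is not None and not Path(config.regions_path).exists():
        raise FileNotFoundError(f"regions file not found: {config.regions_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    regions: RegionSet = (load_regions(config.regions_path)
                          if config.regions_path else demo_regions())
    stage_errors: list[dict] = []

    # -- trajectory workflow ----------------------------------------------
    all_traj = []
    for d in sorted(config.peak_dates):
        grid = (read_netcdf(config.grid_path) if config.grid_path
                else _demo_grid_for(config.site, d, config.seed))
        trajs, failures = batch_simulate([config.site], [d], grid,
                                         config.trajectory)
        all_traj.extend(trajs)
        stage_errors.extend(failures)

    trajectories_to_csv(all_traj, out / "trajectories.csv")
    endpoints_to_geojson(all_traj, out / "endpoints.geojson")
    ep = pd.DataFrame([
        {
            "lat": t.endpoint.lat, "lon": t.endpoint.lon,
            "direction": t.release.direction,
            "season": season_of(t.release.date),
            "date": t.release.date.isoformat(),
            "altitude_agl": t.altitude_agl,
            "termination": t.termination,
        }
        for t in all_traj
    ])
    ep.to_csv(out / "endpoints.csv", index=False)
    table = attribute(ep, regions)
    table.counts.to_csv(out / "attribution_counts.csv")
    table.percentages.to_csv(out / "attribution_percentages.csv")
    (out / "attribution.md").write_text(table.to_markdown() + "\n")
    groups = {"South Asia": [r for r in ("India", "Bangladesh")
                             if r in table.percentages.index]}
    if groups["South Asia"]:
        aggregate(table, groups).to_csv(out / "attribution_aggregates.csv")

    # -- trap-catch workflow ----------------------------------------------
    series = generate(config.trap_sim)
    series.to_csv(out / "catches.csv", out / "dissections.csv")
    summ = monthly_summary(series)
    summ.table.to_csv(out / "monthly_summary.csv")
    monthly_f = series.nightly.assign(month=series.nightly["date"].dt.month)
    tests = []
    for month, sub in monthly_f.groupby("month"):
        t = sex_ratio_chisq(int(sub["females"].sum()), int(sub["males"].sum()))
        tests.append({"month": month, "females": t.females, "males": t.males,
                      "chi_square": t.chi_square, "p_value": t.p_value})
    pd.DataFrame(tests).to_csv(out / "sex_ratio_tests.csv", index=False)
    monthly_totals = (monthly_f.groupby("month")["total"].sum()
                      .reindex(range(1, 13), fill_value=0))
    scan = segmentation_scan(monthly_totals.to_numpy(float), k_max=4)
    scan.to_csv(out / "segmentation.csv")
    ovary = ovary_summary(series, lambda t: season_of(t.date()))
    ovary.to_csv(out / "ovary_summary.csv")

    # -- manifest ----------------------------------------------------------
    cfg = config.to_dict()
    files = sorted(p.name for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "grand_total_monthly_female_means": summ.grand_total,
        "suggested_k": int(scan.attrs["suggested_k"]),
        "n_trajectories": len(all_traj),
        "stage_errors": stage_errors,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    if stage_errors:
        raise RuntimeError(
            f"{len(stage_errors)} pipeline stage failure(s); see manifest"
        )
    return out


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (all keys optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "site" in raw:
        s = raw["site"]
        kwargs["site"] = Site(lat=s["lat"], lon=s["lon"],
                              utc_offset=s.get("utc_offset", 0.0),
                              name=s.get("name", ""))
    if "peak_dates" in raw:
        kwargs["peak_dates"] = tuple(_date.fromisoformat(d)
                                     for d in raw["peak_dates"])
    for key in ("grid_path", "regions_path", "seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "trajectory" in raw:
        t = raw["trajectory"]
        tp = {}
        if "step_minutes" in t:
            tp["step"] = pd.Timedelta(minutes=t["step_minutes"]).to_pytimedelta()
        for key in ("altitudes_agl", "temp_threshold", "temp_gate_mode",
                    "integrator"):
            if key in t:
                tp[key] = tuple(t[key]) if key == "altitudes_agl" else t[key]
        kwargs["trajectory"] = TrajectoryParams(**tp)
    if "trap_sim" in raw:
        kwargs["trap_sim"] = TrapSimConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["trap_sim"].items()
        })
    return RunConfig(**kwargs)
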