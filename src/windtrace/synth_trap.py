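"""Synthetic nightly trap-catch and dissection data.

Emulates the statistical structure of multi-year searchlight-trap
monitoring of a migratory moth: overdispersed nightly totals with two
seasonal migration peaks (spring centred in late April, autumn centred in
early November), a month-varying female fraction, a nightly dissection cap
of 20 females, and period-dependent ovarian-level and mating-count
distributions.  It is a statistical test harness, not a fit to any real
trap series.

Also provides :func:`generate_endpoint_cloud`, which turns a percentage
table into a labelled point cloud inside region polygons such that
attribution recovers the percentages exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .regions import RegionSet, season_of
from .trapstats import CatchSeries

__all__ = ["PeriodReproduction", "TrapSimConfig", "generate",
           "generate_endpoint_cloud", "DISSECTION_CAP"]

DISSECTION_CAP = 20  # females dissected per night (or all, if fewer)

#: Across-year monthly female fractions of the study's Table-2-shaped
#: summary (printed monthly female percentages / 100), Jan..Dec.
DEFAULT_FEMALE_FRACTION = (0.215, 0.258, 0.387, 0.604, 0.423, 0.289,
                           0.291, 0.257, 0.258, 0.283, 0.270, 0.212)


@dataclass(frozen=True)
class PeriodReproduction:
    """Ovary-level multinomial and mating distribution for one period."""

    ovary_probs: tuple[float, ...]   # levels 1..5
    mated_rate: float                # P(>=1 spermatophore)
    mating_mean: float               # mean of the zero-truncated Poisson

    def __post_init__(self) -> None:
        if len(self.ovary_probs) != 5 or abs(sum(self.ovary_probs) - 1.0) > 1e-9:
            raise ValueError("ovary_probs must be 5 probabilities summing to 1")
        if not 0.0 < self.mated_rate <= 1.0:
            raise ValueError("mated_rate must lie in (0, 1]")
        if self.mating_mean < 1.0:
            raise ValueError("mating_mean is conditional on mating; must be >= 1")

    @property
    def pct_matured(self) -> float:
        return 100.0 * sum(self.ovary_probs[2:])


# level probabilities chosen so matured (level > 2) and mated fractions
# equal the study's spring (92.3% / 83.3%) and autumn (74.2% / 62.9%) rates
DEFAULT_REPRODUCTION = {
    "spring": PeriodReproduction((0.030, 0.047, 0.250, 0.450, 0.223), 0.833, 1.9),
    "autumn": PeriodReproduction((0.108, 0.150, 0.300, 0.300, 0.142), 0.629, 1.5),
    "transition": PeriodReproduction((0.050, 0.080, 0.280, 0.400, 0.190), 0.880, 1.8),
}


@dataclass(frozen=True)
class SeasonalPeak:
    center_doy: float   # day of year of the bump centre
    width_days: float   # Gaussian sigma
    amplitude: float    # added mean catch at the centre

    def __post_init__(self) -> None:
        if self.width_days <= 0 or self.amplitude < 0:
            raise ValueError("peak width must be > 0 and amplitude >= 0")


@dataclass(frozen=True)
class TrapSimConfig:
    """Study-like defaults: 5 monitoring years, low winter baseline, a
    dominant spring peak (10x baseline) and a weaker autumn peak."""

    years: tuple[int, ...] = (2019, 2020, 2021, 2022, 2023)
    baseline: float = 5.0
    peaks: tuple[SeasonalPeak, ...] = (
        SeasonalPeak(center_doy=120.0, width_days=18.0, amplitude=50.0),
        SeasonalPeak(center_doy=310.0, width_days=25.0, amplitude=20.0),
    )
    nb_dispersion: float = 2.0   # NB size parameter; var = mu + mu^2/size
    female_fraction: tuple[float, ...] = DEFAULT_FEMALE_FRACTION
    reproduction: Mapping[str, PeriodReproduction] = field(
        default_factory=lambda: dict(DEFAULT_REPRODUCTION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline intensity must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if len(self.female_fraction) != 12 or not all(
            0.0 < f < 1.0 for f in self.female_fraction
        ):
            raise ValueError("female_fraction needs 12 values in (0, 1)")


def _nightly_mean(cfg: TrapSimConfig, doy: np.ndarray, year_len: int) -> np.ndarray:
    mu = np.full(doy.shape, cfg.baseline, dtype=float)
    for pk in cfg.peaks:
        delta = np.abs(doy - pk.center_doy)
        delta = np.minimum(delta, year_len - delta)  # day-of-year wraparound
        mu += pk.amplitude * np.exp(-0.5 * (delta / pk.width_days) ** 2)
    return mu


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    out = rng.poisson(lam, size=n)
    for _ in range(100):
        zero = out == 0
        if not zero.any():
            break
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
    out[out == 0] = 1
    return out


def generate(config: TrapSimConfig) -> CatchSeries:
    """Draw a multi-year nightly catch series plus dissection records.

    Nightly totals ~ NegBin(mean = baseline + seasonal bumps, size =
    nb_dispersion); females ~ Binomial(total, month female fraction); up to
    20 females per night get an ovary level (period multinomial) and a
    mating count (Bernoulli(mated) x zero-truncated Poisson).
    """
    rng = np.random.default_rng(config.seed)
    nightly_rows = []
    diss_rows = []
    for year in config.years:
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        mu = _nightly_mean(config, dates.dayofyear.to_numpy(float), len(dates))
        size = config.nb_dispersion
        totals = rng.negative_binomial(size, size / (size + mu))
        fem_p = np.array([config.female_fraction[m - 1] for m in dates.month])
        females = rng.binomial(totals, fem_p)
        males = totals - females
        for d, tot, f, m in zip(dates, totals, females, males):
            nightly_rows.append((d.date(), int(f), int(m), int(tot)))
            n_diss = min(DISSECTION_CAP, int(f))
            if n_diss == 0:
                continue
            period = season_of(d.date())
            rep = config.reproduction[period]
            levels = rng.choice(np.arange(1, 6), size=n_diss, p=rep.ovary_probs)
            mated = rng.random(n_diss) < rep.mated_rate
            counts = np.zeros(n_diss, dtype=int)
            if mated.any():
                counts[mated] = _zero_truncated_poisson(
                    rng, rep.mating_mean, int(mated.sum())
                )
            for lv, c in zip(levels, counts):
                diss_rows.append((d.date(), int(lv), int(c)))
    nightly = pd.DataFrame(nightly_rows,
                           columns=["date", "females", "males", "total"])
    dissections = pd.DataFrame(diss_rows,
                               columns=["date", "ovary_level", "mating_count"])
    series = CatchSeries(nightly=nightly, dissections=dissections)
    series.nightly.attrs["seed"] = config.seed
    return series


# -- endpoint-cloud fixture ------------------------------------------------


def _sample_in_polygon(rng: np.random.Generator, geom, n: int) -> np.ndarray:
    """Uniform points inside a polygon via rejection in its bounding box."""
    minx, miny, maxx, maxy = geom.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = np.column_stack([
            rng.uniform(minx, maxx, size=2 * (n - got)),
            rng.uniform(miny, maxy, size=2 * (n - got)),
        ])
        for x, y in cand:
            if got >= n:
                break
            if geom.contains(Point(x, y)):
                pts[got] = (x, y)
                got += 1
    return pts


def generate_endpoint_cloud(
    percentages: Mapping[tuple[str, str], Mapping[str, float]],
    n: int,
    regions: RegionSet,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a labelled endpoint cloud realising a percentage table.

    ``percentages`` maps (direction, season) -> {region: percent}; each
    column gets ``n`` points split as count = percent * n / 100 (counts
    must come out integral — e.g. one-decimal percentages with n = 1000).
    When the column sums below 100 the leftover points are placed outside
    every polygon, i.e. in the catch-all region, so attribution of the
    cloud reproduces the input percentages exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (direction, season), col in sorted(percentages.items()):
        total_pct = sum(col.values())
        if abs(total_pct - 100.0) > 0.5:
            raise ValueError(
                f"column ({direction}, {season}) percentages sum to {total_pct}"
            )
        missing = [r for r in col if r not in regions.geoms]
        if missing:
            raise ValueError(f"regions without a polygon: {missing}")
        counts = {r: int(round(p * n / 100.0)) for r, p in col.items()}
        for r, p in col.items():
            if abs(counts[r] - p * n / 100.0) > 1e-6:
                raise ValueError(
                    f"percent {p} for {r!r} does not give an integral count at n={n}"
                )
        residue = n - sum(counts.values())
        if residue < 0:
            raise ValueError("percentages exceed 100 at this n")
        for region, cnt in counts.items():
            if cnt == 0:
                continue
            pts = _sample_in_polygon(rng, regions.geoms[region], cnt)
            for x, y in pts:
                rows.append({
                    "lat": y, "lon": x, "region_true": region,
                    "direction": direction, "season": season,
                })
        # leftover share: points outside every named polygon (catch-all)
        for _ in range(residue):
            x, y = _point_outside(rng, regions)
            rows.append({
                "lat": y, "lon": x, "region_true": "other",
                "direction": direction, "season": season,
            })
    return pd.DataFrame(rows)


def _point_outside(rng: np.random.Generator, regions: RegionSet) -> tuple[float, float]:
    bounds = np.array([g.bounds for g in regions.geoms.values()])
    minx, miny = bounds[:, 0].min(), bounds[:, 1].min()
    maxx, maxy = bounds[:, 2].max(), bounds[:, 3].max()
    for _ in range(10_000):
        x = rng.uniform(minx - 5.0, maxx + 5.0)
        y = rng.uniform(max(miny - 5.0, -89.0), min(maxy + 5.0, 89.0))
        if not any(g.covers(Point(x, y)) for g in regions.geoms.values()):
            return x, y
    raise RuntimeError("could not find a point outside all regions")
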