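"""Independent brute-force oracles used by the test suite.

Each oracle is written from first principles, independent of the package's
implementation path: interpolation as an explicit 16-corner weighted sum,
segmentation by exhaustive enumeration, point-in-polygon by winding number,
and sunrise/sunset from the NOAA low-precision Fourier series (a different
formulation than the package's high-precision geometry).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

# -- quadrilinear interpolation: explicit 16-corner weighted sum ----------


def corner_sum_interpolate(axes, values, query):
    """Weighted sum over the 2^4 enclosing corners of a regular 4-D grid."""
    idx, frac = [], []
    for ax, q in zip(axes, query):
        j = int(np.searchsorted(ax, q, side="right") - 1)
        j = min(max(j, 0), len(ax) - 2)
        idx.append(j)
        frac.append((q - ax[j]) / (ax[j + 1] - ax[j]))
    out = 0.0
    for corner in range(16):
        w = 1.0
        pos = []
        for d in range(4):
            hi = (corner >> d) & 1
            w *= frac[d] if hi else (1.0 - frac[d])
            pos.append(idx[d] + hi)
        out += w * values[tuple(pos)]
    return out


# -- segmentation: exhaustive enumeration over contiguous partitions ------


def exhaustive_partition(x, k, standardize=True):
    """Minimal within-class SS over all contiguous k-partitions of x."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if standardize and x.std(ddof=1) > 0:
        x = (x - x.mean()) / x.std(ddof=1)
    best_err, best_cuts = math.inf, None
    for cuts in combinations(range(1, n), k - 1):
        starts = (0, *cuts)
        ends = (*cuts, n)
        err = sum(
            float(((x[s:e] - x[s:e].mean()) ** 2).sum())
            for s, e in zip(starts, ends)
        )
        if err < best_err - 1e-12:
            best_err, best_cuts = err, cuts
    return best_err, list(best_cuts)


# -- point in polygon: winding number -------------------------------------


def winding_number_contains(coords, x, y):
    """Nonzero winding number of (x, y) w.r.t. a closed polygon ring."""
    wn = 0
    n = len(coords)
    for i in range(n):
        x0, y0 = coords[i]
        x1, y1 = coords[(i + 1) % n]
        if y0 <= y:
            if y1 > y and (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0) > 0:
                wn += 1
        else:
            if y1 <= y and (x1 - x0) * (y - y0) - (x - x0) * (y1 - y0) < 0:
                wn -= 1
    return wn != 0


def random_star_polygon(rng, n_vertices=8, cx=0.0, cy=0.0, rmax=1.0):
    """A random star-shaped (hence simple) polygon around (cx, cy)."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(0.2 * rmax, rmax, size=n_vertices)
    return [(cx + r * np.cos(a), cy + r * np.sin(a))
            for a, r in zip(angles, radii)]


# -- solar ephemeris: NOAA low-precision Fourier series -------------------


def lowprec_sun_events(lat, lon, utc_offset, d):
    """Sunrise/sunset (local clock hours) via the fractional-year series."""
    doy = d.timetuple().tm_yday

    def geometry(hour_utc):
        g = 2.0 * math.pi / 365.0 * (doy - 1 + (hour_utc - 12.0) / 24.0)
        eqtime = 229.18 * (
            0.000075 + 0.001868 * math.cos(g) - 0.032077 * math.sin(g)
            - 0.014615 * math.cos(2 * g) - 0.040849 * math.sin(2 * g)
        )
        decl = (
            0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g)
        )
        return eqtime, decl

    out = []
    for rising in (True, False):
        hour_utc = (6.0 if rising else 18.0) - lon / 15.0
        for _ in range(3):
            eqtime, decl = geometry(hour_utc)
            latr = math.radians(lat)
            cos_ha = (
                math.cos(math.radians(90.833)) / (math.cos(latr) * math.cos(decl))
                - math.tan(latr) * math.tan(decl)
            )
            ha = math.degrees(math.acos(max(-1.0, min(1.0, cos_ha))))
            if not rising:
                ha = -ha
            minutes_utc = 720.0 - 4.0 * (lon + ha) - eqtime
            hour_utc = minutes_utc / 60.0
        out.append(hour_utc + utc_offset)
    return tuple(out)  # (sunrise_local_h, sunset_local_h)
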