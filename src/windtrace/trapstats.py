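"""Light-trap phenology statistics.

Covers the seasonal analysis of nightly searchlight-trap catches:

* monthly female-catch summaries (mean over years +/- SE, female
  percentage, grand total of monthly means);
* the 1:1 sex-ratio chi-square per month;
* Fisher's optimal partitioning of ordered samples — the exact
  dynamic-programming segmentation of an ordered series into contiguous
  classes minimising within-class sum of squared deviations — used to
  divide the year into migration periods;
* ovarian-development / mating summaries per period (a female with ovarian
  level > 2 counts as matured).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CatchSeries",
    "MonthlySummary",
    "SegmentationResult",
    "SexRatioTest",
    "monthly_summary",
    "sex_ratio_chisq",
    "fisher_partition",
    "segmentation_scan",
    "ovary_summary",
]

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass
class CatchSeries:
    """Nightly trap records plus optional per-female dissection records.

    ``nightly`` columns: date, females, males (total derived).
    ``dissections`` columns: date, ovary_level (1–5), mating_count (>=0).
    """

    nightly: pd.DataFrame
    dissections: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = self.nightly.copy()
        missing = {"date", "females", "males"} - set(n.columns)
        if missing:
            raise ValueError(f"nightly table missing columns: {sorted(missing)}")
        n["date"] = pd.to_datetime(n["date"])
        for c in ("females", "males"):
            if (n[c] < 0).any() or not np.issubdtype(n[c].dtype, np.integer):
                n[c] = n[c].astype(int)
            if (n[c] < 0).any():
                raise ValueError(f"negative counts in column {c!r}")
        if "total" in n.columns:
            if not (n["total"] == n["females"] + n["males"]).all():
                raise ValueError("total must equal females + males")
        else:
            n["total"] = n["females"] + n["males"]
        self.nightly = n
        if self.dissections is not None:
            d = self.dissections.copy()
            missing = {"date", "ovary_level", "mating_count"} - set(d.columns)
            if missing:
                raise ValueError(f"dissection table missing columns: {sorted(missing)}")
            d["date"] = pd.to_datetime(d["date"])
            if not d["ovary_level"].isin([1, 2, 3, 4, 5]).all():
                raise ValueError("ovary_level must be in {1..5}")
            if (d["mating_count"] < 0).any():
                raise ValueError("mating_count must be >= 0")
            self.dissections = d

    # -- CSV I/O (dialect shared with the synthetic generator) -------------

    def to_csv(self, nightly_path, dissections_path=None) -> None:
        out = self.nightly.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(nightly_path, index=False)
        if dissections_path is not None and self.dissections is not None:
            d = self.dissections.copy()
            d["date"] = d["date"].dt.strftime("%Y-%m-%d")
            d.to_csv(dissections_path, index=False)

    @classmethod
    def from_csv(cls, nightly_path, dissections_path=None) -> "CatchSeries":
        nightly = pd.read_csv(nightly_path)
        diss = pd.read_csv(dissections_path) if dissections_path else None
        return cls(nightly=nightly, dissections=diss)


@dataclass
class MonthlySummary:
    table: pd.DataFrame      # per-month mean/SE females, female percentage
    grand_total: float       # sum of the monthly mean female counts


def monthly_summary(series: CatchSeries) -> MonthlySummary:
    """Female catches by calendar month, averaged over years.

    For each (year, month) the nightly female counts are summed; the
    reported monthly mean and standard error are then taken across years.
    The female percentage is likewise the across-year mean of the yearly
    percentage 100*F/(F+M).  The grand total is the sum of the monthly
    means (so it estimates mean females per year).
    """
    n = series.nightly
    if n.empty:
        raise ValueError("empty catch series")
    g = n.assign(year=n["date"].dt.year, month=n["date"].dt.month)
    ym = g.groupby(["year", "month"])[["females", "males"]].sum().reset_index()
    ym["pct_female"] = 100.0 * ym["females"] / (ym["females"] + ym["males"]).replace(0, np.nan)

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    rows = []
    for month, sub in ym.groupby("month"):
        rows.append({
            "month": _MONTHS[month - 1],
            "month_num": month,
            "mean_females": float(sub["females"].mean()),
            "se_females": _se(sub["females"]),
            "mean_pct_female": float(sub["pct_female"].mean()),
            "se_pct_female": _se(sub["pct_female"].dropna()),
            "n_years": int(len(sub)),
        })
    table = pd.DataFrame(rows).sort_values("month_num").set_index("month")
    return MonthlySummary(table=table, grand_total=float(table["mean_females"].sum()))


@dataclass(frozen=True)
class SexRatioTest:
    females: int
    males: int
    chi_square: float
    p_value: float


def sex_ratio_chisq(females: int, males: int, yates: bool = False) -> SexRatioTest:
    """Pearson chi-square of an observed sex ratio against 1:1.

    With expected counts E = (F+M)/2 the two-cell statistic collapses to
    (F-M)^2/(F+M) on 1 df; the optional Yates correction gives
    (|F-M|-1)^2/(F+M).
    """
    f, m = int(females), int(males)
    if f < 0 or m < 0:
        raise ValueError("counts must be non-negative")
    if f + m == 0:
        raise ValueError("cannot test a sex ratio with zero moths")
    if yates:
        chi2 = max(abs(f - m) - 1.0, 0.0) ** 2 / (f + m)
    else:
        chi2 = (f - m) ** 2 / (f + m)
    return SexRatioTest(f, m, float(chi2), float(stats.chi2.sf(chi2, df=1)))


# -- Fisher's optimal partitioning of ordered samples ----------------------


@dataclass
class SegmentationResult:
    k: int
    boundaries: list[int]          # start index of classes 2..k (0-based)
    error_function: float          # minimal total within-class SS
    classes: list[tuple[int, int]]  # inclusive (start, end) index pairs
    class_means: list[float]
    standardized: bool = True


def _segment_costs(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-class SS of x[i..j] inclusive (prefix-sum trick)."""
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m = j - i + 1
            tot = s1[j + 1] - s1[i]
            cost[i, j] = max((s2[j + 1] - s2[i]) - tot * tot / m, 0.0)
    return cost


def fisher_partition(
    x: Sequence[float], k: int, standardize: bool = True
) -> SegmentationResult:
    """Globally optimal contiguous partition of an ordered series.

    Dynamic programme over all contiguous k-partitions minimising the total
    within-class sum of squared deviations (optionally of the z-scored
    series).  Ties are broken toward the leftmost boundaries.  The optimum
    is exact, which small-n exhaustive enumeration confirms in the tests.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have at least 2 observations")
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    xs = x
    did_standardize = False
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn("constant series: standardization skipped", stacklevel=2)
        else:
            xs = (x - x.mean()) / sd
            did_standardize = True

    cost = _segment_costs(xs)
    INF = float("inf")
    # D[m][j]: minimal error of splitting x[0..j] into m+1 classes
    D = np.full((k, n), INF)
    back = np.zeros((k, n), dtype=int)
    D[0, :] = cost[0, :]
    for m in range(1, k):
        for j in range(m, n):
            best, best_i = INF, m
            # ascending i + strict '<' keeps the leftmost optimal boundary
            for i in range(m, j + 1):
                c = D[m - 1, i - 1] + cost[i, j]
                if c < best - 1e-12:
                    best, best_i = c, i
            D[m, j], back[m, j] = best, best_i

    boundaries: list[int] = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = int(back[m, j])
        boundaries.append(i)
        j = i - 1
    boundaries.reverse()
    starts = [0] + boundaries
    ends = boundaries + [n]
    classes = [(s, e - 1) for s, e in zip(starts, ends)]
    means = [float(x[s:e].mean()) for s, e in zip(starts, ends)]
    return SegmentationResult(
        k=k,
        boundaries=boundaries,
        error_function=float(D[k - 1, n - 1]),
        classes=classes,
        class_means=means,
        standardized=did_standardize,
    )


def segmentation_scan(
    x: Sequence[float], k_max: int, standardize: bool = True
) -> pd.DataFrame:
    """Error-function curve over k = 2..k_max, with a suggested k.

    The curve is non-increasing in k (partitions nest); the suggested k is
    the one with the largest relative error drop from k-1 (k=2 compares
    against the single-class error).
    """
    x = np.asarray(x, dtype=float)
    if not 2 <= k_max < len(x):
        raise ValueError("k_max must be in [2, len(x) - 1]")
    xs = x
    if standardize and x.std(ddof=1) > 0:
        xs = (x - x.mean()) / x.std(ddof=1)
    e1 = float(((xs - xs.mean()) ** 2).sum())
    rows, prev = [], e1
    for k in range(2, k_max + 1):
        res = fisher_partition(x, k, standardize=standardize)
        drop = (prev - res.error_function) / prev if prev > 0 else 0.0
        rows.append({"k": k, "error_function": res.error_function,
                     "relative_drop": drop,
                     "segmentation": res.classes})
        prev = res.error_function
    df = pd.DataFrame(rows).set_index("k")
    df.attrs["suggested_k"] = int(df["relative_drop"].idxmax())
    return df


# -- ovarian / mating summaries --------------------------------------------


def ovary_summary(
    series: CatchSeries,
    period_of: Callable[[pd.Timestamp], str],
) -> pd.DataFrame:
    """Per-period reproductive state of dissected females.

    mated rate = fraction with >=1 spermatophore; matured = fraction with
    ovarian level > 2; means are over dissected females in the period.
    Periods with no dissection records are reported with NaN and n=0.
    """
    if series.dissections is None or series.dissections.empty:
        raise ValueError("catch series has no dissection records")
    d = series.dissections.copy()
    d["period"] = [period_of(t) for t in d["date"]]
    rows = []
    for period, sub in d.groupby("period"):
        rows.append({
            "period": period,
            "n_dissected": int(len(sub)),
            "mated_rate": float((sub["mating_count"] >= 1).mean()),
            "mean_ovary_level": float(sub["ovary_level"].mean()),
            "mean_mating_count": float(sub["mating_count"].mean()),
            "pct_matured": float(100.0 * (sub["ovary_level"] > 2).mean()),
        })
    return pd.DataFrame(rows).set_index("period")
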