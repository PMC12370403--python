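"""Percentile-of-center-medians DRL statistics.

A diagnostic reference level (DRL) is conventionally set as the 75th
percentile of the per-facility median doses. This module computes that
statistic for a single typical compressed-breast-thickness window (the
"simplest" approach, e.g. 50 ± 5 mm) and per 10-mm CBT bin (the "range"
approach), together with distribution-free confidence intervals for the
per-bin median AGD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .records import CohortTable

PercentileMethod = Literal["linear", "nearest"]


@dataclass(frozen=True)
class BinScheme:
    """Half-open CBT bins [b, b+width), last bin closed at ``hi``.

    ``representative`` picks the x-coordinate used when fitting a curve to the
    per-bin DRLs: the nominal bin midpoint (25, 35, ... for defaults) or the
    mean CBT of the records in the bin.
    """

    lo: float = 20.0
    hi: float = 100.0
    width: float = 10.0
    representative: Literal["midpoint", "bin_mean"] = "midpoint"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.hi <= self.lo:
            raise ValueError("need hi > lo and width > 0")
        n = (self.hi - self.lo) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(hi - lo) must be divisible by width")

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.n_bins + 1)

    def bin_index(self, cbt: float | np.ndarray) -> np.ndarray:
        """Index of the bin containing each CBT; -1 outside [lo, hi]."""
        cbt = np.asarray(cbt, dtype=float)
        idx = np.floor((cbt - self.lo) / self.width).astype(int)
        idx = np.where(cbt == self.hi, self.n_bins - 1, idx)  # last bin closed
        idx = np.where((cbt < self.lo) | (cbt > self.hi), -1, idx)
        return idx

    def midpoints(self) -> np.ndarray:
        return self.lo + self.width / 2 + self.width * np.arange(self.n_bins)


@dataclass
class MedianCI:
    """Distribution-free CI for a median from order statistics."""

    lo: float
    hi: float
    level: float
    n: int
    ranks: tuple[int, int] | None  # 1-indexed order statistics used
    low_n: bool = False  # n < 6: full data range returned instead

    def __iter__(self):
        return iter((self.lo, self.hi))


def median_ci(values, level: float = 0.95) -> MedianCI:
    """Order-statistic (binomial-rank) confidence interval for the median.

    The interval (x_(l), x_(u)) with u = n + 1 - l and l the largest rank
    whose one-sided binomial tail stays within (1 - level)/2 has coverage of
    at least ``level`` for any continuous distribution. Below n = 6 no such
    interval exists at 95%; the full data range is returned, flagged.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("median_ci of empty collection")
    if n < 6:
        return MedianCI(float(x[0]), float(x[-1]), level, n, None, low_n=True)
    alpha = 1.0 - level
    # smallest l (1-indexed) with P(Binom(n,1/2) <= l-1) <= alpha/2 maximal
    l = int(stats.binom.ppf(alpha / 2, n, 0.5))
    if stats.binom.cdf(l - 1, n, 0.5) > alpha / 2:  # guard against ppf edge
        l -= 1
    l = max(l, 1)
    u = n + 1 - l
    return MedianCI(float(x[l - 1]), float(x[u - 1]), level, n, (l, u))


def drl_percentile(medians, method: PercentileMethod = "linear") -> float:
    """75th percentile of per-center medians (the DRL statistic)."""
    arr = np.asarray(list(medians), dtype=float)
    if arr.size == 0:
        raise ValueError("drl_percentile of empty collection")
    return float(np.percentile(arr, 75, method=method))


def center_medians(
    table: CohortTable,
    view: str,
    cbt_range: tuple[float, float],
    last_closed: bool = False,
) -> dict[str, float]:
    """Median AGD per center for one view within [lo, hi) of CBT.

    Left and right lateralities are pooled. Centers with no records in range
    are omitted, never zero-filled.
    """
    lo, hi = cbt_range
    df = table.df
    m = (df["view"] == view) & (df["cbt"] >= lo)
    m &= (df["cbt"] <= hi) if last_closed else (df["cbt"] < hi)
    sub = df[m]
    if len(sub) == 0:
        return {}
    med = sub.groupby("center_id", sort=True)["agd"].median()
    return {str(k): float(v) for k, v in med.items()}


def simplest_drl(
    table: CohortTable,
    view: str,
    center_cbt: float = 50.0,
    half_width: float = 5.0,
    method: PercentileMethod = "linear",
) -> float:
    """DRL for the single typical-thickness window [center - hw, center + hw)."""
    rng = (center_cbt - half_width, center_cbt + half_width)
    med = center_medians(table, view, rng)
    if not med:
        raise ValueError(f"no records for view {view} in CBT range {rng}")
    return drl_percentile(med.values(), method=method)


@dataclass
class BinRow:
    lo: float
    hi: float
    representative_cbt: float
    center_medians: dict[str, float]
    n_records: int
    drl: float | None
    ci: MedianCI | None
    low_n_centers: list[str] = field(default_factory=list)
    empty: bool = False


@dataclass
class BinnedDRLTable:
    """Per-view table of CBT bins with center medians, DRL and median CI."""

    view: str
    scheme: BinScheme
    rows: list[BinRow]
    percentile_method: PercentileMethod = "linear"

    def nonempty_rows(self) -> list[BinRow]:
        return [r for r in self.rows if not r.empty]

    def fit_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(representative CBT, DRL) pairs over non-empty bins, for curve fitting."""
        rows = self.nonempty_rows()
        return (
            np.array([r.representative_cbt for r in rows]),
            np.array([r.drl for r in rows]),
        )

    def drl_at(self, cbt: float) -> float | None:
        """Step-function lookup: DRL of the bin containing ``cbt``."""
        idx = int(self.scheme.bin_index(cbt))
        if idx < 0:
            return None
        row = self.rows[idx]
        return None if row.empty else row.drl

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "bin_lo": r.lo,
                    "bin_hi": r.hi,
                    "representative_cbt": r.representative_cbt,
                    "n_records": r.n_records,
                    "n_centers": len(r.center_medians),
                    "drl_mGy": r.drl,
                    "median_ci_lo": r.ci.lo if r.ci else None,
                    "median_ci_hi": r.ci.hi if r.ci else None,
                    "low_n_centers": ";".join(r.low_n_centers),
                    "empty": r.empty,
                }
            )
        return pd.DataFrame(recs)

    def to_json(self) -> str:
        d = {
            "view": self.view,
            "percentile_method": self.percentile_method,
            "scheme": {
                "lo": self.scheme.lo,
                "hi": self.scheme.hi,
                "width": self.scheme.width,
                "representative": self.scheme.representative,
            },
            "rows": [
                {
                    "bin": [r.lo, r.hi],
                    "representative_cbt": r.representative_cbt,
                    "center_medians": r.center_medians,
                    "n_records": r.n_records,
                    "drl_mGy": r.drl,
                    "median_ci": [r.ci.lo, r.ci.hi] if r.ci else None,
                    "low_n_centers": r.low_n_centers,
                    "empty": r.empty,
                }
                for r in self.rows
            ],
        }
        return json.dumps(d, indent=2)


def binned_drl_table(
    table: CohortTable,
    view: str,
    scheme: BinScheme | None = None,
    method: PercentileMethod = "linear",
    ci_level: float = 0.95,
    low_n_threshold: int = 20,
) -> BinnedDRLTable:
    """DRL per CBT bin: 75th percentile of per-center median AGD.

    Bins with no contributing centers are kept as flagged empty rows. The
    median CI is computed on the bin's pooled AGD values. Centers with fewer
    than ``low_n_threshold`` in-bin records are flagged low-n.
    """
    scheme = scheme or BinScheme()
    df = table.df[table.df["view"] == view]
    rows: list[BinRow] = []
    for i in range(scheme.n_bins):
        lo = scheme.lo + i * scheme.width
        hi = lo + scheme.width
        last = i == scheme.n_bins - 1
        meds = center_medians(table, view, (lo, hi), last_closed=last)
        m = (df["cbt"] >= lo) & ((df["cbt"] <= hi) if last else (df["cbt"] < hi))
        sub = df[m]
        counts = sub.groupby("center_id")["agd"].size()
        low_n = sorted(str(c) for c, n in counts.items() if n < low_n_threshold)
        if scheme.representative == "bin_mean" and len(sub):
            rep = float(sub["cbt"].mean())
        else:
            rep = lo + scheme.width / 2
        if meds:
            rows.append(
                BinRow(
                    lo=lo,
                    hi=hi,
                    representative_cbt=rep,
                    center_medians=meds,
                    n_records=int(len(sub)),
                    drl=drl_percentile(meds.values(), method=method),
                    ci=median_ci(sub["agd"].to_numpy(), level=ci_level),
                    low_n_centers=low_n,
                )
            )
        else:
            rows.append(
                BinRow(
                    lo=lo,
                    hi=hi,
                    representative_cbt=rep,
                    center_medians={},
                    n_records=0,
                    drl=None,
                    ci=None,
                    empty=True,
                )
            )
    return BinnedDRLTable(view=view, scheme=scheme, rows=rows, percentile_method=method)
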