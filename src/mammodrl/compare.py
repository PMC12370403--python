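"""Disagreement statistics between DRL reporting approaches.

Quantifies, on an integer-mm CBT grid, how the continuous (equation) DRL
differs from the 10-mm-bin step function and from the single
typical-thickness DRL, tests the differences with a Wilcoxon signed-rank
test, and classifies a DRL curve against external acceptable/achievable
guideline limit curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import DRLCurve
from .estimator import BinnedDRLTable


def percent_diff(a: float, ref: float) -> float:
    """Absolute percent difference |a - ref| / ref × 100 (ref > 0)."""
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return abs(a - ref) / ref * 100.0


def compare_to_simplest(value: float, simplest: float) -> float:
    """Percent difference of an approach value relative to the simplest DRL."""
    if simplest <= 0:
        raise ValueError("simplest DRL must be positive")
    return abs(value - simplest) / simplest * 100.0


@dataclass
class SignedRankResult:
    statistic: float
    p_value: float
    n_pairs: int
    method: str
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def _exact_wplus_tail(ranks: np.ndarray, w: float) -> float:
    """P(W+ <= w) under the signed-rank null, by convolution over sign patterns.

    Ranks may be mid-ranks (half-integers); they are doubled to integers so
    the distribution of the doubled positive-rank sum is built exactly.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2 ** len(r2)
    w2 = int(np.floor(np.rint(2 * w * 1e9) / 1e9))  # guard float fuzz
    return float(dist[: w2 + 1].sum())


def signed_rank_test(diffs: Sequence[float], exact_max_n: int = 25) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention), tied absolute
    differences are mid-ranked. For n <= ``exact_max_n`` the null
    distribution of the positive-rank sum is enumerated exactly (valid with
    mid-ranks); above that a normal approximation with the tie-respecting
    variance Var(W+) = Σ r_i²/4 is used. All-zero differences yield a
    degenerate result with p = 1 rather than an error.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return SignedRankResult(
            statistic=0.0, p_value=1.0, n_pairs=0, method="degenerate", degenerate=True
        )
    if n < 6:
        raise ValueError(f"need at least 6 nonzero pairs, got {n}")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_minus = total - w_plus
    statistic = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = min(1.0, 2.0 * _exact_wplus_tail(ranks, statistic))
        method = "exact"
    else:
        mu = total / 2.0
        sigma = np.sqrt(float(ranks @ ranks) / 4.0)
        z = (abs(w_plus - mu) - 0.5) / sigma  # continuity-corrected
        p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        method = "normal"
    return SignedRankResult(statistic=statistic, p_value=p, n_pairs=n, method=method)


@dataclass
class ComparisonReport:
    """Pointwise and aggregate differences between DRL approaches."""

    view: str
    grid: np.ndarray
    eq_drl: np.ndarray
    range_drl: np.ndarray
    simplest_drl: float | None
    pct_diff_range: np.ndarray
    pct_diff_simplest: np.ndarray | None
    wilcoxon: SignedRankResult
    uncovered: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        d = {
            "cbt_mm": self.grid,
            "equation_drl_mGy": self.eq_drl,
            "range_drl_mGy": self.range_drl,
            "pct_diff_range": self.pct_diff_range,
        }
        if self.pct_diff_simplest is not None:
            d["pct_diff_simplest"] = self.pct_diff_simplest
        return pd.DataFrame(d)

    def to_json(self) -> str:
        return json.dumps(
            {
                "view": self.view,
                "simplest_drl_mGy": self.simplest_drl,
                "wilcoxon": self.wilcoxon.as_dict(),
                "grid_mm": self.grid.tolist(),
                "equation_drl_mGy": self.eq_drl.tolist(),
                "range_drl_mGy": [None if np.isnan(v) else v for v in self.range_drl],
                "pct_diff_range": [None if np.isnan(v) else v for v in self.pct_diff_range],
                "pct_diff_simplest": None
                if self.pct_diff_simplest is None
                else self.pct_diff_simplest.tolist(),
            },
            indent=2,
        )


def compare_equation_vs_ranges(
    curve: DRLCurve,
    table: BinnedDRLTable,
    grid_step: float = 1.0,
    simplest: float | None = None,
) -> ComparisonReport:
    """Pointwise equation-vs-bin comparison on an integer-mm CBT grid.

    Percent differences use the equation value as denominator. The Wilcoxon
    signed-rank test is run two-sided on the signed differences
    (range − equation) over grid points covered by a non-empty bin.
    """
    if curve.view != table.view:
        raise ValueError(f"view mismatch: curve {curve.view} vs table {table.view}")
    lo, hi = table.scheme.lo, table.scheme.hi
    if curve.domain[1] < lo or curve.domain[0] > hi:
        raise ValueError("curve domain and bin table domain are disjoint")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    eq = np.asarray(curve.evaluate(grid), dtype=float)
    rng_vals = np.array(
        [np.nan if (v := table.drl_at(c)) is None else v for c in grid]
    )
    covered = ~np.isnan(rng_vals)
    pct_range = np.where(covered, np.abs(rng_vals - eq) / eq * 100.0, np.nan)
    pct_simplest = None
    if simplest is not None:
        pct_simplest = np.abs(eq - simplest) / simplest * 100.0
    wil = signed_rank_test((rng_vals - eq)[covered]) if covered.sum() else SignedRankResult(
        0.0, 1.0, 0, "degenerate", True
    )
    return ComparisonReport(
        view=curve.view,
        grid=grid,
        eq_drl=eq,
        range_drl=rng_vals,
        simplest_drl=simplest,
        pct_diff_range=pct_range,
        pct_diff_simplest=pct_simplest,
        wilcoxon=wil,
        uncovered=~covered,
    )


# ---------------------------------------------------------------------------
# Guideline limit curves
# ---------------------------------------------------------------------------


@dataclass
class LimitCurves:
    """Acceptable/achievable dose-vs-thickness guideline boundaries.

    Tables of (CBT mm, dose mGy), piecewise-linearly interpolated; the
    achievable boundary must not exceed the acceptable one anywhere they
    are both defined.
    """

    acceptable: np.ndarray  # shape (k, 2)
    achievable: np.ndarray  # shape (m, 2)

    def __post_init__(self) -> None:
        self.acceptable = np.asarray(self.acceptable, dtype=float)
        self.achievable = np.asarray(self.achievable, dtype=float)
        for arr in (self.acceptable, self.achievable):
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("limit tables must be (cbt, mGy) pairs")
        shared_lo = max(self.acceptable[0, 0], self.achievable[0, 0])
        shared_hi = min(self.acceptable[-1, 0], self.achievable[-1, 0])
        if shared_hi > shared_lo:
            g = np.linspace(shared_lo, shared_hi, 50)
            if np.any(self._interp(self.achievable, g) > self._interp(self.acceptable, g) + 1e-12):
                raise ValueError("achievable limit exceeds acceptable limit")

    @staticmethod
    def _interp(arr: np.ndarray, x: np.ndarray) -> np.ndarray:
        out = np.interp(x, arr[:, 0], arr[:, 1])
        return np.where((x < arr[0, 0]) | (x > arr[-1, 0]), np.nan, out)

    @classmethod
    def from_csv(cls, acceptable_path: str | Path, achievable_path: str | Path) -> "LimitCurves":
        def load(p):
            df = pd.read_csv(p)
            return df.iloc[:, :2].to_numpy(dtype=float)

        return cls(acceptable=load(acceptable_path), achievable=load(achievable_path))

    def span(self) -> tuple[float, float]:
        return (
            max(self.acceptable[0, 0], self.achievable[0, 0]),
            min(self.acceptable[-1, 0], self.achievable[-1, 0]),
        )


@dataclass
class LimitClassification:
    grid: np.ndarray
    labels: list[str]  # below_achievable | between | above_acceptable | uncovered
    regions: list[tuple[str, float, float]]  # (label, cbt_from, cbt_to), contiguous

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cbt_mm": self.grid, "class": self.labels})


def classify_against_limits(
    curve: DRLCurve, limits: LimitCurves, grid_step: float = 1.0
) -> LimitClassification:
    """Classify a DRL curve pointwise against guideline limit curves.

    Boundaries are inclusive downward: a value equal to the acceptable limit
    is 'between'; equal to the achievable limit is 'below_achievable'. Grid
    points outside a limit table's span are flagged 'uncovered'.
    """
    lo, hi = curve.domain
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = np.asarray(curve.evaluate(grid), dtype=float)
    acc = LimitCurves._interp(limits.acceptable, grid)
    ach = LimitCurves._interp(limits.achievable, grid)
    labels = []
    for v, a_hi, a_lo in zip(vals, acc, ach):
        tol = 1e-9 * max(1.0, abs(v))  # equality on the boundary, float-safe
        if np.isnan(a_hi) or np.isnan(a_lo):
            labels.append("uncovered")
        elif v <= a_lo + tol:
            labels.append("below_achievable")
        elif v <= a_hi + tol:
            labels.append("between")
        else:
            labels.append("above_acceptable")
    regions: list[tuple[str, float, float]] = []
    for x, lab in zip(grid, labels):
        if regions and regions[-1][0] == lab:
            regions[-1] = (lab, regions[-1][1], float(x))
        else:
            regions.append((lab, float(x), float(x)))
    return LimitClassification(grid=grid, labels=labels, regions=regions)
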