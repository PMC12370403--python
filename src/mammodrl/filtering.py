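"""Examination-level inclusion/exclusion rules for DRL surveys.

Survey conventions remove erroneous acquisitions before dose statistics are
computed: extreme or zero compression force, implausibly low tube load,
zero tube voltage, and very thick compressed breasts with too few cases to
be reliable. Exclusion operates per examination — if any view of an exam
violates a rule, the whole exam is removed — and every removal is accounted
to exactly one rule (the first that triggered, in a fixed order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import CohortTable, VALID_VIEWS

#: Fixed evaluation order; each removed exam is attributed to the first rule hit.
RULE_ORDER: tuple[str, ...] = (
    "view_not_allowed",
    "compression_force",
    "low_mas",
    "zero_kvp",
    "cbt_above_max",
    "implant_present",
)


@dataclass
class FilterConfig:
    """Thresholds for the exclusion rules.

    Defaults implement the conventional survey rules: compression force above
    200 N or exactly 0 N, tube load in [0, 10) mAs, tube voltage of 0 kVp,
    compressed breast thickness above 100 mm, and implant-present exams.
    The mAs boundary is kept half-open ([0, 10) removed, 10 retained).
    """

    cf_max: float = 200.0
    cf_exclude_zero: bool = True
    mas_min: float = 10.0
    kvp_exclude_zero: bool = True
    cbt_max: float = 100.0
    allowed_views: frozenset = frozenset(VALID_VIEWS)
    exclude_implants: bool = True
    exam_level: bool = True

    def __post_init__(self) -> None:
        if self.cf_max <= 0:
            raise ValueError("cf_max must be positive")
        if self.mas_min < 0:
            raise ValueError("mas_min must be non-negative")
        if self.cbt_max <= 0:
            raise ValueError("cbt_max must be positive")
        self.allowed_views = frozenset(self.allowed_views)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**cfg)


@dataclass
class FilterReport:
    """Exact accounting of what was removed and why (in records)."""

    n_in: int
    n_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    exams_removed_by_rule: dict[str, int] = field(default_factory=dict)
    rule_order: tuple[str, ...] = RULE_ORDER
    warnings: list[str] = field(default_factory=list)

    def check(self) -> None:
        removed = sum(self.removed_by_rule.values())
        if self.n_out != self.n_in - removed:
            raise AssertionError(
                f"accounting violated: {self.n_in} - {removed} != {self.n_out}"
            )

    def to_json(self) -> str:
        d = asdict(self)
        d["rule_order"] = list(self.rule_order)
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        lines = [f"records in:  {self.n_in}", f"records out: {self.n_out}"]
        for rule in self.rule_order:
            n = self.removed_by_rule.get(rule, 0)
            ne = self.exams_removed_by_rule.get(rule, "-")
            lines.append(f"  removed by {rule}: {n} records ({ne} exams)")
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def group_exams(table: CohortTable) -> list[tuple[tuple[str, str], pd.DataFrame]]:
    """Partition records by (center_id, exam_id), stable in first-appearance order."""
    if len(table) == 0:
        return []
    return [
        (key, grp) for key, grp in table.df.groupby(["center_id", "exam_id"], sort=False)
    ]


def _rule_flags(df: pd.DataFrame, cfg: FilterConfig) -> dict[str, pd.Series]:
    """Per-record violation flags for rules 2-6 (NaN never triggers)."""
    cf, mas, kvp, cbt = df["compression_force"], df["mas"], df["kvp"], df["cbt"]
    flags = {
        "compression_force": (cf > cfg.cf_max) | (cfg.cf_exclude_zero & (cf == 0)),
        "low_mas": (mas >= 0) & (mas < cfg.mas_min),
        "zero_kvp": (kvp == 0) if cfg.kvp_exclude_zero else pd.Series(False, index=df.index),
        "cbt_above_max": cbt > cfg.cbt_max,
        "implant_present": df["implant_present"]
        if cfg.exclude_implants
        else pd.Series(False, index=df.index),
    }
    return {k: v.fillna(False) for k, v in flags.items()}


def apply_exclusions(
    table: CohortTable, cfg: FilterConfig | None = None
) -> tuple[CohortTable, FilterReport]:
    """Apply the exclusion rules and report exact removal accounting.

    Records with a non-allowed view are dropped record-wise first; the
    remaining rules act per examination (any violating view removes the whole
    exam) when ``cfg.exam_level``, else per record. Each removal is counted
    under the first rule (in :data:`RULE_ORDER`) that triggered for it.
    """
    cfg = cfg or FilterConfig()
    df = table.df
    n_in = len(df)
    removed: dict[str, int] = {r: 0 for r in RULE_ORDER}
    exams_removed: dict[str, int] = {r: 0 for r in RULE_ORDER[1:]}
    warnings: list[str] = []

    view_ok = df["view"].isin(cfg.allowed_views)
    removed["view_not_allowed"] = int((~view_ok).sum())
    df = df[view_ok]

    flags = _rule_flags(df, cfg)
    if cfg.exam_level and len(df):
        keys = list(zip(df["center_id"], df["exam_id"]))
        exam = pd.Series(keys, index=df.index)
        doomed = pd.Series(False, index=df.index)
        already: set = set()
        for rule in RULE_ORDER[1:]:
            hit_exams = set(exam[flags[rule]]) - already
            hit = exam.isin(hit_exams)
            removed[rule] = int(hit.sum())
            exams_removed[rule] = len(hit_exams)
            doomed |= hit
            already |= hit_exams
        df = df[~doomed]
    elif len(df):
        doomed = pd.Series(False, index=df.index)
        for rule in RULE_ORDER[1:]:
            hit = flags[rule] & ~doomed
            removed[rule] = int(hit.sum())
            doomed |= hit
        df = df[~doomed]

    if len(df) == 0:
        warnings.append("no records remain after exclusions")

    report = FilterReport(
        n_in=n_in,
        n_out=len(df),
        removed_by_rule=removed,
        exams_removed_by_rule=exams_removed,
        warnings=warnings,
    )
    report.check()
    out = CohortTable(
        df.reset_index(drop=True),
        provenance=table.provenance + f"; filtered ({n_in}->{len(df)})",
        n_dropped=table.n_dropped,
    )
    return out, report
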