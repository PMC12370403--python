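"""End-to-end orchestration: records -> filter -> binned DRLs -> curve -> comparison.

``run_pipeline`` writes every intermediate artifact (filter report, per-view
binned DRL tables, all model fits ranked by SSE, the selected curve with its
printable equation, the approach-comparison report and figure analogues) into
a run directory, together with a machine-readable manifest that records every
convention in force (percentile method, bin scheme, seeds, thresholds) so a
run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import plots
from .compare import LimitCurves, classify_against_limits, compare_equation_vs_ranges
from .curves import FAMILIES, DRLCurveModel
from .estimator import BinScheme, binned_drl_table, simplest_drl
from .filtering import FilterConfig, apply_exclusions
from .records import CohortTable, CsvDialect, read_csv


@dataclass
class RunConfig:
    input_path: str | None = None
    dialect: CsvDialect | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    bins: BinScheme = field(default_factory=BinScheme)
    families: tuple[str, ...] = tuple(FAMILIES)
    seed: int = 0
    views: tuple[str, ...] = ("CC", "MLO")
    stratify_by: str | None = None
    typical_cbt: float = 50.0
    typical_half_width: float = 5.0
    percentile_method: str = "linear"
    limits_acceptable: str | None = None
    limits_achievable: str | None = None
    output_dir: str = "drl_run"


def modal_cbt_window(table: CohortTable, width: float = 10.0) -> tuple[int, int]:
    """Integer-mm sliding window of given width holding the most records.

    Returns (nominal center, count); ties resolved to the lowest center.
    The window is half-open: [center - width/2, center + width/2).
    """
    cbt = table.df["cbt"].to_numpy(dtype=float)
    if len(cbt) == 0:
        raise ValueError("modal_cbt_window of empty table")
    lo = int(np.floor(cbt.min()))
    hi = int(np.ceil(cbt.max()))
    half = width / 2.0
    best_center, best_count = lo, -1
    for c in range(lo, hi + 1):
        n = int(np.count_nonzero((cbt >= c - half) & (cbt < c + half)))
        if n > best_count:
            best_center, best_count = c, n
    return best_center, best_count


def _manifest_base(cfg: RunConfig) -> dict:
    d = {
        "seed": cfg.seed,
        "views": list(cfg.views),
        "families": list(cfg.families),
        "percentile_method": cfg.percentile_method,
        "bin_scheme": {
            "lo": cfg.bins.lo,
            "hi": cfg.bins.hi,
            "width": cfg.bins.width,
            "representative": cfg.bins.representative,
        },
        "filter": {k: (sorted(v) if isinstance(v, frozenset) else v) for k, v in asdict(cfg.filter).items()},
        "typical_window": {"center": cfg.typical_cbt, "half_width": cfg.typical_half_width},
        "stratify_by": cfg.stratify_by,
        "stages": {},
    }
    return d


def run_pipeline(cfg: RunConfig, table: CohortTable | None = None) -> Path:
    """Run the full DRL pipeline; returns the run directory.

    ``table`` may be passed directly (e.g. a synthetic cohort); otherwise
    ``cfg.input_path`` is read as CSV with the configured dialect. On a stage
    failure, partial outputs are retained and the manifest records the
    failure point.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_base(cfg)

    def save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        if table is None:
            if cfg.input_path is None:
                raise ValueError("either a table or cfg.input_path is required")
            table = read_csv(cfg.input_path, cfg.dialect)
        manifest["stages"]["load"] = {"n_records": len(table), "provenance": table.provenance}

        filtered, report = apply_exclusions(table, cfg.filter)
        (out / "filter_report.json").write_text(report.to_json())
        (out / "filter_report.txt").write_text(report.to_text())
        manifest["stages"]["filter"] = {"n_in": report.n_in, "n_out": report.n_out}
        if len(filtered) == 0:
            raise RuntimeError("no records remain after exclusions")

        center, count = modal_cbt_window(filtered)
        manifest["stages"]["modal_cbt_window"] = {"center_mm": center, "n_records": count}
        plots.cbt_histogram(filtered, (center, count), out / "cbt_distribution.png")

        strata: list[tuple[str, CohortTable]] = [("all", filtered)]
        if cfg.stratify_by:
            strata += [
                (str(val), CohortTable(grp.reset_index(drop=True)))
                for val, grp in filtered.df.groupby(cfg.stratify_by, sort=True)
            ]

        for stratum, sub in strata:
            tag = "" if stratum == "all" else f"_{stratum.replace(' ', '_')}"
            sinfo: dict = {}
            for view in cfg.views:
                binned = binned_drl_table(
                    sub, view, cfg.bins, method=cfg.percentile_method
                )
                binned.to_frame().to_csv(out / f"binned{tag}_{view}.csv", index=False)
                (out / f"binned{tag}_{view}.json").write_text(binned.to_json())

                try:
                    s_drl = simplest_drl(
                        sub, view, cfg.typical_cbt, cfg.typical_half_width,
                        method=cfg.percentile_method,
                    )
                except ValueError:
                    s_drl = None

                res = DRLCurveModel.from_binned_table(binned, cfg.families).fit(seed=cfg.seed)
                res.as_frame().to_csv(out / f"fits{tag}_{view}.csv", index=False)
                (out / f"fits{tag}_{view}.json").write_text(
                    json.dumps([f.to_dict() for f in res.fits], indent=2)
                )
                (out / f"curve{tag}_{view}.json").write_text(res.curve.to_json())
                (out / f"summary{tag}_{view}.txt").write_text(res.summary())

                comp = compare_equation_vs_ranges(res.curve, binned, simplest=s_drl)
                comp.to_frame().to_csv(out / f"comparison{tag}_{view}.csv", index=False)
                (out / f"comparison{tag}_{view}.json").write_text(comp.to_json())

                limits = None
                if cfg.limits_acceptable and cfg.limits_achievable:
                    limits = LimitCurves.from_csv(cfg.limits_acceptable, cfg.limits_achievable)
                    cls = classify_against_limits(res.curve, limits)
                    cls.to_frame().to_csv(out / f"limit_class{tag}_{view}.csv", index=False)
                    sinfo[f"{view}_limit_regions"] = cls.regions

                plots.binned_drl_bars(binned, out / f"drl_bins{tag}_{view}.png")
                plots.step_vs_curve(
                    binned, res.curve, out / f"step_vs_curve{tag}_{view}.png", limits=limits
                )
                sinfo[view] = {
                    "n_bins": len(binned.rows),
                    "n_nonempty_bins": len(binned.nonempty_rows()),
                    "n_fits": len(res.fits),
                    "selected_family": res.best.family.name,
                    "equation": res.best.equation_string(),
                    "simplest_drl_mGy": s_drl,
                    "wilcoxon_p": comp.wilcoxon.p_value,
                }
            manifest["stages"][f"stratum:{stratum}"] = sinfo
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        save_manifest()
        raise
    save_manifest()
    return out
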