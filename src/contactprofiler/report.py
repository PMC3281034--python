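"""End-to-end analysis driver.

Runs the full diary-analysis sequence on a dataset (synthetic or
user-supplied): presence and tool comparison, PCH extraction, nesting
diagnostics, measure ratios, contact location profiles, tertile trends,
mixing-type clustering, cluster occupancy by day, and per-subject
membership diversity.  Writes a JSON report plus CSV tables, with a run
log carrying the seed, a config hash and every exclusion count, so each
number in the bundle traces to a named stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .clustering import (
    average_linkage,
    distance_matrix,
    membership_diversity,
    occupancy_table,
    select_k,
)
from .diary_model import SETTINGS, DiaryDataset, read_dataset
from .pch_measures import daily_totals, measure_ratio, nesting_check, pch_table
from .profiles import normalize, profile_matrix, tertile_partition, tertile_trend_test
from .tool_comparison import (
    bland_altman,
    locations_visited,
    presence_proportions,
    presence_test,
    setting_rank_comparison,
)

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    """Options for a full analysis run.

    ``tool`` defaults to the paper diary — the instrument with the best
    ascertainment — while the tool-comparison stage still contrasts every
    pair of tools present in the data.
    """

    input_dir: str | Path
    out_dir: str | Path
    tool: str = "paper"
    measures: tuple[str, ...] = ("interaction", "setting")
    linkage: str = "average"
    k_max: int = 10
    cap: int | None = 6
    seed: int = 0
    compare_tools: tuple[str, str] = ("paper", "pda")

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input dir not found: {self.input_dir}")
        for m in self.measures:
            if m not in ("interaction", "reach", "setting"):
                raise ValueError(f"unknown measure {m!r}")


def run_full_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the report."""
    config.validate()
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dataset, validation = read_dataset(
        in_dir / "visits.csv", in_dir / "encounters.csv", in_dir / "subjects.csv"
    )
    report: dict[str, Any] = {
        "run": {
            "seed": config.seed,
            "tool": config.tool,
            "config_hash": _config_hash(config),
            "input_hash": _input_hash(in_dir),
            "n_flagged_headcount_rows": validation.n_flagged,
        },
        "stages": {},
    }

    has_encounters = len(dataset.encounters) > 0
    measures = tuple(
        m for m in config.measures if m != "interaction" or has_encounters
    )
    if not has_encounters and "interaction" in config.measures:
        report["run"]["notices"] = [
            "encounters table empty: interaction-based stages skipped"
        ]

    # --- tool comparison -------------------------------------------------
    props = presence_proportions(dataset)
    props.to_csv(out_dir / "presence_proportions.csv", index=False)
    tools_present = sorted(dataset.visits["tool"].unique())
    tc: dict[str, Any] = {"tools_present": tools_present}
    ta, tb = config.compare_tools
    if ta in tools_present and tb in tools_present:
        tests = {}
        for s in SETTINGS:
            p, (bx, by) = presence_test(dataset, ta, tb, s)
            tests[s] = {"p": p, "only_" + ta: bx, "only_" + tb: by}
        tc["presence_mcnemar"] = tests
        tc["bland_altman_daily_totals"] = _ba_daily_totals(dataset, ta, tb, measures)
    report["stages"]["tool_comparison"] = tc

    # --- PCH on the analysis tool ----------------------------------------
    ds_tool = dataset.for_tool(config.tool)
    table = pch_table(ds_tool)
    table.to_csv(out_dir / "pch.csv", index=False)
    totals = daily_totals(table)
    totals.to_csv(out_dir / "daily_totals.csv", index=False)
    nesting = nesting_check(table)
    report["stages"]["pch"] = {
        "n_subject_days": int(len(totals)),
        "n_rows": int(len(table)),
        "nesting_overall_violation_fraction": nesting.overall_fraction,
        "nesting_per_setting": {
            s: (None if pd.isna(v) else float(v))
            for s, v in nesting.per_setting_fraction.items()
        },
    }

    ratio = measure_ratio(table, "pch_interaction", "pch_setting")
    by_setting = {
        s: grp["ratio"].to_numpy()
        for s, grp in ratio.ratios.groupby("setting")
        if len(grp)
    }
    ratio_stage: dict[str, Any] = {"n_excluded_zero_denominator": ratio.n_excluded}
    if len(by_setting) >= 2:
        cmp = setting_rank_comparison(by_setting)
        ratio_stage.update(
            {
                "kw_statistic": cmp.kw_statistic,
                "kw_p": cmp.kw_p,
                "n_pairwise": cmp.n_comparisons,
                "median_by_setting": {
                    s: float(pd.Series(v).median()) for s, v in by_setting.items()
                },
            }
        )
        cmp.pairwise.to_csv(out_dir / "ratio_pairwise_tests.csv", index=False)
    report["stages"]["interaction_setting_ratio"] = ratio_stage

    # --- profiles, tertiles, clustering per measure ----------------------
    for measure in measures:
        stage: dict[str, Any] = {}
        prof = normalize(table, measure)
        prof.profiles.to_csv(out_dir / f"profiles_{measure}.csv", index=False)
        stage["n_profiles"] = int(len(prof.profiles))
        stage["n_excluded_zero_total"] = prof.n_excluded
        if len(prof.profiles) < 3:
            report["stages"][f"profiles_{measure}"] = stage
            continue

        part = tertile_partition(prof.profiles["total"])
        stage["tertile_counts"] = {
            k: int(v) for k, v in part.counts().items()
        }
        stage["tertile_trend_p"] = {
            s: tertile_trend_test(prof.profiles, part, s)[1] for s in SETTINGS
        }

        x = profile_matrix(prof.profiles)
        dend = average_linkage(distance_matrix(x), method=config.linkage)
        result = select_k(x, dend, k_max=config.k_max, cap=config.cap)
        point_labels = [result.labels[c] for c in result.assignments]
        occ = occupancy_table(point_labels, prof.profiles["day"].tolist())
        occ.to_csv(out_dir / f"occupancy_{measure}.csv")
        assignments = prof.profiles[["subject_id", "day", "tool"]].copy()
        assignments["cluster"] = result.assignments
        assignments["label"] = point_labels
        assignments.to_csv(out_dir / f"clusters_{measure}.csv", index=False)
        _, diversity = membership_diversity(assignments)
        stage["clustering"] = {
            "chosen_k": result.chosen_k,
            "argmax_k": result.argmax_k,
            "pseudo_f": {str(k): v for k, v in sorted(result.pseudo_f.items())},
            "labels": result.labels,
            "duplicate_labels": result.duplicate_labels,
            "occupancy": {
                day: {c: int(occ.loc[day, c]) for c in occ.columns}
                for day in occ.index
            },
            "membership_diversity": diversity,
        }
        report["stages"][f"profiles_{measure}"] = stage

    # --- locations visited ------------------------------------------------
    locs = locations_visited(ds_tool)
    locs.to_csv(out_dir / "locations_visited.csv", index=False)
    report["stages"]["locations_visited"] = {
        "mean": float(locs["n_settings"].mean()),
        "median": float(locs["n_settings"].median()),
        "q1": float(locs["n_settings"].quantile(0.25)),
        "q3": float(locs["n_settings"].quantile(0.75)),
    }

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def _ba_daily_totals(
    dataset: DiaryDataset, tool_a: str, tool_b: str, measures: tuple[str, ...]
) -> dict[str, Any]:
    out: dict[str, Any] = {}
    col = {"interaction": "pch_interaction", "reach": "pch_reach",
           "setting": "pch_setting"}
    tot_a = daily_totals(pch_table(dataset.for_tool(tool_a))).set_index(
        ["subject_id", "day"]
    )
    tot_b = daily_totals(pch_table(dataset.for_tool(tool_b))).set_index(
        ["subject_id", "day"]
    )
    common = tot_a.index.intersection(tot_b.index)
    for m in measures:
        ba = bland_altman(
            tot_a.loc[common, col[m]].to_numpy(),
            tot_b.loc[common, col[m]].to_numpy(),
        )
        out[m] = {
            "mean_difference": ba.mean_difference,
            "ci_low": ba.ci_low,
            "ci_high": ba.ci_high,
            "n_pairs": ba.n_pairs,
        }
    return out


def _config_hash(config: AnalysisConfig) -> str:
    # hash the analysis parameters only; input content is covered by the
    # input hash and filesystem locations are not analysis choices
    payload = json.dumps(
        {
            k: str(v)
            for k, v in vars(config).items()
            if k not in ("input_dir", "out_dir")
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _input_hash(in_dir: Path) -> str:
    h = hashlib.sha256()
    for name in ("subjects.csv", "visits.csv", "encounters.csv"):
        p = in_dir / name
        if p.exists():
            h.update(p.read_bytes())
    return h.hexdigest()[:16]
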