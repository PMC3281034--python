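"""Person-contact-hours (PCH) measures per subject-day-setting.

Three exposure proxies are extracted from each diary day:

* ``pch_setting``   — sum over visits of duration x (people in the whole
  setting): the most inclusive measure, counting everyone sharing the
  space for the time it was shared;
* ``pch_reach``     — duration x (people within arm's reach): close
  proximity exposure;
* ``pch_interaction`` — cumulative duration of face-to-face conversational
  or touch encounters: two-way interaction only.  Repeated encounters with
  the same contact all count (cumulative person-time), and simultaneous
  conversations with several contacts accumulate once per contact.

Encounters are attributed to a setting through their parent visit (the
diary opens a new page per location).  For self-consistent reports the
measures nest: interaction <= reach <= setting; ``nesting_check``
quantifies how often diarists' headcount estimates break that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diary_model import SETTINGS, DiaryDataset, DiaryValidationError

__all__ = [
    "PCH_MEASURES",
    "NestingReport",
    "pch_setting",
    "pch_reach",
    "pch_interaction",
    "pch_table",
    "daily_totals",
    "measure_ratio",
    "nesting_check",
]

PCH_MEASURES: tuple[str, ...] = ("pch_interaction", "pch_reach", "pch_setting")

_KEY = ["subject_id", "day", "tool", "setting"]
_DAY_KEY = ["subject_id", "day", "tool"]


def pch_setting(visits: pd.DataFrame) -> pd.Series:
    """Whole-setting person-hours: sum of duration x n_setting per key."""
    return _visit_product(visits, "n_setting")


def pch_reach(visits: pd.DataFrame) -> pd.Series:
    """Arm's-reach person-hours: sum of duration x n_reach per key.

    Visits whose reach headcount exceeds the setting headcount are still
    computed here; the inconsistency is reported by :func:`nesting_check`.
    """
    return _visit_product(visits, "n_reach")


def pch_interaction(encounters: pd.DataFrame, visits: pd.DataFrame) -> pd.Series:
    """Cumulative face-to-face interaction person-hours per key.

    Each encounter row contributes its full duration: repeated encounters
    with one contact and simultaneous encounters with several contacts all
    accumulate.  The setting is taken from the parent visit.
    """
    if len(encounters) == 0:
        return pd.Series(dtype=float, name="pch_interaction")
    merged = encounters.merge(
        visits[["subject_id", "day", "tool", "visit_id", "setting"]],
        on=["subject_id", "day", "tool", "visit_id"],
        how="left",
    )
    if merged["setting"].isna().any():
        row = int(merged["setting"].isna().idxmax())
        raise DiaryValidationError(
            f"encounter row {row} references a visit that does not exist"
        )
    out = merged.groupby(_KEY, sort=True)["duration_h"].sum()
    out.name = "pch_interaction"
    return out


def pch_table(dataset: DiaryDataset) -> pd.DataFrame:
    """All three PCH measures, one row per (subject, day, tool, setting).

    Rows exist for every setting with at least one visit under the tool;
    absent settings are simply missing (they contribute 0 to totals).
    """
    setting = pch_setting(dataset.visits).rename("pch_setting")
    reach = pch_reach(dataset.visits).rename("pch_reach")
    inter = pch_interaction(dataset.encounters, dataset.visits)
    table = pd.concat([setting, reach], axis=1)
    if len(inter):
        table = table.join(inter, how="left")
        table["pch_interaction"] = table["pch_interaction"].fillna(0.0)
    else:
        table["pch_interaction"] = 0.0
    table = table.reset_index()[_KEY + list(PCH_MEASURES)]
    return table.sort_values(_KEY, kind="stable").reset_index(drop=True)


def daily_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject-day-tool totals of each measure (sums over settings).

    A ``zero_total`` flag marks subject-days whose every measure is 0;
    they are retained here and excluded only at normalization.
    """
    totals = table.groupby(_DAY_KEY, sort=True)[list(PCH_MEASURES)].sum().reset_index()
    totals["zero_total"] = (totals[list(PCH_MEASURES)] == 0).all(axis=1)
    return totals


@dataclass
class RatioResult:
    """Per-row measure ratios plus the count of zero-denominator exclusions."""

    ratios: pd.DataFrame
    n_excluded: int


def measure_ratio(
    table: pd.DataFrame, numerator: str, denominator: str
) -> RatioResult:
    """Ratio of two PCH measures per subject-day-setting.

    Rows with a zero denominator are excluded and counted; a zero
    numerator yields a 0 ratio.
    """
    for m in (numerator, denominator):
        if m not in PCH_MEASURES:
            raise ValueError(f"unknown measure {m!r}; expected one of {PCH_MEASURES}")
    keep = table[denominator] > 0
    out = table.loc[keep, _KEY].copy()
    out["ratio"] = (table.loc[keep, numerator] / table.loc[keep, denominator]).to_numpy()
    return RatioResult(ratios=out.reset_index(drop=True), n_excluded=int((~keep).sum()))


@dataclass
class NestingReport:
    """Where and how often the interaction <= reach <= setting order breaks."""

    flags: pd.DataFrame  # per-row booleans for both violation kinds
    per_setting_fraction: pd.Series  # fraction of rows violating either
    overall_fraction: float
    n_rows: int

    @property
    def n_violations(self) -> int:
        return int(
            (
                self.flags["violates_reach_le_setting"]
                | self.flags["violates_interaction_le_reach"]
            ).sum()
        )


def nesting_check(table: pd.DataFrame, atol: float = 1e-9) -> NestingReport:
    """Flag subject-day-settings that break the nesting of the measures."""
    flags = table[_KEY].copy()
    flags["violates_reach_le_setting"] = (
        table["pch_reach"] > table["pch_setting"] + atol
    )
    flags["violates_interaction_le_reach"] = (
        table["pch_interaction"] > table["pch_reach"] + atol
    )
    either = flags["violates_reach_le_setting"] | flags["violates_interaction_le_reach"]
    per_setting = either.groupby(table["setting"]).mean()
    per_setting = per_setting.reindex(list(SETTINGS)).astype(float)
    overall = float(either.mean()) if len(table) else 0.0
    return NestingReport(
        flags=flags,
        per_setting_fraction=per_setting,
        overall_fraction=overall,
        n_rows=len(table),
    )


def _visit_product(visits: pd.DataFrame, count_col: str) -> pd.Series:
    if len(visits) == 0:
        return pd.Series(dtype=float)
    prod = visits["duration_h"].to_numpy(float) * visits[count_col].to_numpy(float)
    if not np.all(np.isfinite(prod)) or (prod < 0).any():
        raise DiaryValidationError("visit durations/headcounts must be finite and >= 0")
    return pd.Series(prod, index=visits.index).groupby(
        [visits[k] for k in _KEY], sort=True
    ).sum()
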