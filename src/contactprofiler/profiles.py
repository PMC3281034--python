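"""Contact location profiles: normalized PCH shares, tertiles, trends.

A subject-day's *contact location profile* is its setting-specific PCH
divided by its total daily PCH for the same measure — a 6-vector of shares
summing to 1 in canonical setting order.  Profiles make subject-days with
very different daily totals comparable, and are the clustering space for
the mixing-type analysis.

Subject-days are also partitioned by total daily PCH into empirical
tertiles (low / medium / high) and each setting's share is tested for a
trend across tertiles with a tie-corrected Kruskal–Wallis rank test.
Person-days are treated as independent observations throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diary_model import SETTINGS
from .pch_measures import PCH_MEASURES, daily_totals

__all__ = [
    "ProfileResult",
    "TertilePartition",
    "normalize",
    "tertile_partition",
    "tertile_trend_test",
    "mean_profile_by_group",
    "profile_matrix",
]

_DAY_KEY = ["subject_id", "day", "tool"]

MEASURE_COLUMN = {
    "interaction": "pch_interaction",
    "reach": "pch_reach",
    "setting": "pch_setting",
}


@dataclass
class ProfileResult:
    """Profiles (one row per subject-day-tool) plus the exclusion count.

    ``profiles`` has the key columns, one share column per setting in
    canonical order, and ``total`` (the subject-day's total daily PCH for
    the chosen measure).  Subject-days with zero total are excluded and
    counted in ``n_excluded``.
    """

    profiles: pd.DataFrame
    measure: str
    n_excluded: int


def normalize(table: pd.DataFrame, measure: str) -> ProfileResult:
    """Normalize one PCH measure into contact location profiles.

    Each subject-day-setting value is divided by the subject-day total; the
    resulting shares sum to 1.  Subject-days whose total is 0 carry no
    profile and are excluded with a count.
    """
    col = _measure_column(measure)
    wide = table.pivot_table(
        index=_DAY_KEY, columns="setting", values=col, aggfunc="sum", fill_value=0.0
    )
    wide = wide.reindex(columns=list(SETTINGS), fill_value=0.0)
    totals = wide.sum(axis=1)
    keep = totals > 0
    n_excluded = int((~keep).sum())
    shares = wide.loc[keep].div(totals.loc[keep], axis=0)
    out = shares.reset_index()
    out.columns.name = None
    out["total"] = totals.loc[keep].to_numpy()
    return ProfileResult(profiles=out, measure=measure, n_excluded=n_excluded)


@dataclass
class TertilePartition:
    """Low/medium/high labels by empirical percentile of total daily PCH."""

    labels: pd.Series  # aligned with the totals passed in
    cut_points: tuple[float, float]  # total at the 33.3 and 66.7 boundaries

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(
            ["low", "medium", "high"], fill_value=0
        )


def tertile_partition(totals: pd.Series | np.ndarray) -> TertilePartition:
    """Partition totals into empirical tertiles of percentile rank.

    The percentile of an observation is its minimum rank / n x 100, so tied
    totals share the lower label; percentile <= 33.33 is "low",
    <= 66.67 "medium", else "high".
    """
    totals = pd.Series(totals).astype(float)
    n = len(totals)
    if n < 3:
        raise ValueError("tertile partition requires at least 3 observations")
    ranks = stats.rankdata(totals.to_numpy(), method="min")
    pct = ranks / n * 100.0
    eps = 1e-9
    labels = np.where(
        pct <= 100.0 / 3.0 + eps,
        "low",
        np.where(pct <= 200.0 / 3.0 + eps, "medium", "high"),
    )
    labels = pd.Series(labels, index=totals.index, name="tertile")
    lows = totals[labels == "low"]
    mids = totals[labels != "high"]
    cut_low = float(lows.max()) if len(lows) else float("nan")
    cut_mid = float(mids.max()) if len(mids) else float("nan")
    return TertilePartition(labels=labels, cut_points=(cut_low, cut_mid))


def tertile_trend_test(
    profiles: pd.DataFrame, partition: TertilePartition, setting: str
) -> tuple[float, float]:
    """Kruskal–Wallis test of one setting's share across tertile groups.

    Returns the tie-corrected H statistic and its chi-square p-value
    (df = number of groups - 1).  If every observation is identical the
    test is vacuous and (0.0, 1.0) is returned by convention.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    values = profiles[setting]
    groups = [
        values[partition.labels == g].to_numpy()
        for g in ("low", "medium", "high")
        if (partition.labels == g).any()
    ]
    if len(groups) < 2:
        raise ValueError("tertile trend test requires >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mean_profile_by_group(
    profiles: pd.DataFrame, grouping: pd.Series
) -> pd.DataFrame:
    """Arithmetic mean share per group and setting (rows sum to 1)."""
    grouping = pd.Series(grouping)
    if len(grouping) != len(profiles):
        raise ValueError("grouping must align with profiles")
    means = profiles[list(SETTINGS)].groupby(grouping.to_numpy()).mean()
    means.index.name = grouping.name or "group"
    return means


def profile_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Share columns as an (n, 6) float array in canonical setting order."""
    return profiles[list(SETTINGS)].to_numpy(dtype=float)


def _measure_column(measure: str) -> str:
    if measure in MEASURE_COLUMN:
        return MEASURE_COLUMN[measure]
    if measure in PCH_MEASURES:
        return measure
    raise ValueError(
        f"unknown measure {measure!r}; expected one of {sorted(MEASURE_COLUMN)}"
    )
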