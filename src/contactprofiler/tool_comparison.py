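"""Diary-tool and between-group comparison statistics.

Cross-over diary studies record the same subject-day under several
instruments, so tool comparisons are paired within subject-day:

* Bland–Altman mean differences (with a t-based 95% CI of the mean
  difference) quantify agreement between paired PCH measurements;
* presence in a setting is compared between tools with an exact McNemar
  test on the discordant subject-days;
* distributions of a quantity across settings (or days) are compared with
  a tie-corrected Kruskal–Wallis omnibus test followed by all pairwise
  two-sided Wilcoxon rank-sum tests under a Bonferroni correction;
* predictors of the number of distinct setting categories visited per day
  are explored with univariate NB2 negative binomial regression
  (incidence-rate ratios with Wald CIs).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diary_model import SETTINGS, DiaryDataset

__all__ = [
    "BlandAltmanResult",
    "RegressionResult",
    "RankComparisonResult",
    "bland_altman",
    "presence_proportions",
    "presence_table",
    "presence_test",
    "mcnemar_exact",
    "setting_rank_comparison",
    "nb_regression",
    "locations_visited",
]


@dataclass
class BlandAltmanResult:
    """Mean paired difference with its 95% confidence interval."""

    mean_difference: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_dropped: int = 0


def bland_altman(
    paired_a: np.ndarray | pd.Series, paired_b: np.ndarray | pd.Series
) -> BlandAltmanResult:
    """Bland–Altman mean difference a - b with a t-based 95% CI.

    Pairs with a missing value on either side are dropped and counted.
    A significantly non-zero mean difference signals a bias between the
    two measurement routes.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int((~ok).sum())
    diff = a[ok] - b[ok]
    n = len(diff)
    if n < 2:
        raise ValueError("Bland-Altman requires at least 2 complete pairs")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return BlandAltmanResult(
        mean_difference=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_pairs=n,
        n_dropped=n_dropped,
    )


def presence_table(dataset: DiaryDataset) -> pd.DataFrame:
    """Presence indicator per (subject, day, tool, setting).

    One row per subject-day observed under a tool, with a boolean column
    per setting: True if the diary reports at least one visit there.
    """
    vis = dataset.visits
    obs = vis[["subject_id", "day", "tool"]].drop_duplicates()
    wide = (
        vis.assign(present=True)
        .pivot_table(
            index=["subject_id", "day", "tool"],
            columns="setting",
            values="present",
            aggfunc="any",
            fill_value=False,
        )
        .reindex(columns=list(SETTINGS), fill_value=False)
        .astype(bool)
    )
    out = obs.merge(wide.reset_index(), on=["subject_id", "day", "tool"], how="left")
    out.columns.name = None
    return out.sort_values(["subject_id", "day", "tool"]).reset_index(drop=True)


def presence_proportions(dataset: DiaryDataset) -> pd.DataFrame:
    """Proportion of subject-days reporting presence, per tool-setting-day.

    The denominator is the number of subject-days observed under the tool
    on that day; tools without observations are omitted.
    """
    table = presence_table(dataset)
    if len(table) == 0:
        raise ValueError("dataset has no visits")
    rows = []
    for (tool, day), grp in table.groupby(["tool", "day"]):
        for s in SETTINGS:
            rows.append(
                {
                    "tool": tool,
                    "day": day,
                    "setting": s,
                    "proportion": float(grp[s].mean()),
                    "n_subject_days": len(grp),
                }
            )
    return pd.DataFrame(rows)


def mcnemar_exact(n_only_x: int, n_only_y: int) -> float:
    """Exact two-sided McNemar p from the discordant-pair counts.

    Under no tool bias the discordant pairs split Binomial(b + c, 1/2);
    concordant pairs are uninformative.  Zero discordant pairs returns 1.
    """
    if n_only_x < 0 or n_only_y < 0:
        raise ValueError("discordant counts must be >= 0")
    n = n_only_x + n_only_y
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_only_x, n, 0.5, alternative="two-sided").pvalue)


def presence_test(
    dataset: DiaryDataset, tool_x: str, tool_y: str, setting: str
) -> tuple[float, tuple[int, int]]:
    """Exact McNemar test of presence ascertainment between two tools.

    Pairs subject-days observed under both tools; returns the p-value and
    the discordant counts (present under x only, present under y only).
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    table = presence_table(dataset)
    x = table[table["tool"] == tool_x].set_index(["subject_id", "day"])[setting]
    y = table[table["tool"] == tool_y].set_index(["subject_id", "day"])[setting]
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner")
    only_x = int((joined["x"] & ~joined["y"]).sum())
    only_y = int((~joined["x"] & joined["y"]).sum())
    return mcnemar_exact(only_x, only_y), (only_x, only_y)


@dataclass
class RankComparisonResult:
    """Kruskal–Wallis omnibus plus Bonferroni-adjusted pairwise tests."""

    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adjusted
    n_comparisons: int


def setting_rank_comparison(
    values_by_group: dict[str, np.ndarray | pd.Series],
) -> RankComparisonResult:
    """Compare a quantity's distribution across groups by ranks.

    Tie-corrected Kruskal–Wallis across all groups, then every pairwise
    two-sided Wilcoxon rank-sum test (exact enumeration for small tie-free
    samples, normal approximation with continuity correction otherwise).
    Raw pairwise p-values are multiplied by the number of comparisons
    performed (Bonferroni), capped at 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v for k, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = stats.kruskal(*arrays)
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        stat, p_raw = _ranksum(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": stat,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * m),
            }
        )
    return RankComparisonResult(
        kw_statistic=float(kw_h),
        kw_p=float(kw_p),
        pairwise=pd.DataFrame(rows),
        n_comparisons=m,
    )


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float("nan"), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionResult:
    """Univariate negative binomial regression summary."""

    irr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    intercept: float
    alpha: float  # NB2 dispersion: Var = mu + alpha mu^2
    log_likelihood: float
    converged: bool


class RegressionError(RuntimeError):
    """The regression is degenerate or the optimiser failed to converge."""


def nb_regression(
    counts: np.ndarray | pd.Series, covariate: np.ndarray | pd.Series
) -> RegressionResult:
    """Univariate NB2 regression of a count on one covariate.

    Log link: mu = exp(b0 + b1 x), Var = mu + alpha mu^2, fit by maximum
    likelihood.  Returns the incidence-rate ratio exp(b1) with its Wald
    95% CI and p-value.  Two-level categorical covariates should be coded
    0/1 by the caller.
    """
    import statsmodels.api as sm

    y = np.asarray(counts, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("counts and covariate must be 1-D and aligned")
    if len(y) < 3:
        raise RegressionError("too few observations")
    if (y < 0).any() or np.any(y % 1 != 0):
        raise ValueError("counts must be non-negative integers")
    if not y.any():
        raise RegressionError("all counts are zero; the model is degenerate")
    if np.all(x == x[0]):
        raise RegressionError("covariate is constant; slope is unidentified")

    exog = sm.add_constant(x)
    model = sm.NegativeBinomial(y, exog, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(method="newton", maxiter=200, disp=0, tol=1e-10)
        except Exception:
            fit = None
        if fit is None or not _converged(fit):
            try:
                fit = model.fit(method="bfgs", maxiter=500, disp=0)
            except Exception as exc:  # pragma: no cover - pathological data
                raise RegressionError(f"NB fit failed: {exc}") from exc
    if not _converged(fit):
        raise RegressionError("NB fit did not converge")
    b0, b1 = float(fit.params[0]), float(fit.params[1])
    se1 = float(np.sqrt(fit.cov_params()[1, 1]))
    z = stats.norm.ppf(0.975)
    return RegressionResult(
        irr=float(np.exp(b1)),
        ci_low=float(np.exp(b1 - z * se1)),
        ci_high=float(np.exp(b1 + z * se1)),
        p=float(2 * stats.norm.sf(abs(b1 / se1))),
        beta=b1,
        intercept=b0,
        alpha=float(fit.params[2]),
        log_likelihood=float(fit.llf),
        converged=True,
    )


def _converged(fit) -> bool:
    # Newton can report success with NaN parameters when the dispersion
    # tends to the Poisson boundary; treat that as non-convergence.
    if not np.all(np.isfinite(fit.params)):
        return False
    if not np.all(np.isfinite(np.diag(fit.cov_params()))):
        return False
    retvals = getattr(fit, "mle_retvals", None)
    return bool(retvals.get("converged", True)) if retvals else True


def locations_visited(dataset: DiaryDataset) -> pd.DataFrame:
    """Distinct setting categories visited per subject-day-tool (1..6)."""
    vis = dataset.visits
    counts = (
        vis.groupby(["subject_id", "day", "tool"])["setting"]
        .nunique()
        .rename("n_settings")
        .reset_index()
    )
    return counts
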