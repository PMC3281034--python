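"""Paired tool statistics: Bland-Altman, McNemar, rank tests, NB regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from contactprofiler import (
    GeneratorConfig,
    RegressionError,
    bland_altman,
    generate,
    locations_visited,
    mcnemar_exact,
    nb_regression,
    presence_proportions,
    presence_test,
    setting_rank_comparison,
)
from contactprofiler.diary_model import SETTINGS
from oracles import mcnemar_exact_formula, wilcoxon_exact_enumeration


class TestBlandAltman:
    def test_identical_samples_give_zero_difference(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        res = bland_altman(a, a)
        assert res.mean_difference == 0.0
        assert res.ci_low == res.ci_high == 0.0

    def test_constant_difference_gives_degenerate_ci(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        res = bland_altman(a, a - 1.0)
        assert res.mean_difference == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_closed_form_on_arithmetic_progression(self):
        # a - b = (0, 1, 2, 3, 4): mean 2, sd sqrt(2.5), t_{0.975,4} = 2.776
        b = np.zeros(5)
        a = np.arange(5.0)
        res = bland_altman(a, b)
        t975 = float(stats.t.ppf(0.975, 4))
        half = t975 * np.sqrt(2.5) / np.sqrt(5)
        assert res.mean_difference == pytest.approx(2.0)
        assert res.ci_low == pytest.approx(2.0 - half)
        assert res.ci_high == pytest.approx(2.0 + half)
        assert round(t975, 3) == 2.776
        assert res.n_pairs == 5

    def test_missing_pairs_dropped_and_counted(self):
        a = np.array([1.0, np.nan, 3.0, 4.0])
        b = np.array([0.0, 1.0, np.nan, 1.0])
        res = bland_altman(a, b)
        assert res.n_pairs == 2
        assert res.n_dropped == 2

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestMcNemar:
    def test_one_sided_discordance_exact_tail(self):
        # (10, 0): p = 2 * 0.5^10
        assert mcnemar_exact(10, 0) == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance_is_null(self):
        assert mcnemar_exact(3, 3) == pytest.approx(1.0)

    def test_no_discordant_pairs_convention(self):
        assert mcnemar_exact(0, 0) == 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=12), st.integers(min_value=0, max_value=12))
    def test_matches_binomial_tail_oracle(self, b, c):
        assert mcnemar_exact(b, c) == pytest.approx(mcnemar_exact_formula(b, c))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=8), st.integers(min_value=0, max_value=8))
    def test_depends_only_on_discordant_counts(self, b, c):
        # invariance to the concordant cells is structural: the function
        # only receives the discordant counts, and symmetric swap holds
        assert mcnemar_exact(b, c) == pytest.approx(mcnemar_exact(c, b))


class TestPresence:
    def test_home_presence_proportion_is_one(self, default_study):
        dataset, _ = default_study
        props = presence_proportions(dataset)
        paper_home = props.query("tool == 'paper' and setting == 'home'")
        assert (paper_home["proportion"] == 1.0).all()

    def test_travel_bias_halves_pda_presence(self):
        cfg = GeneratorConfig(n_subjects=65)
        cfg.tool_bias["pda"] = {**{s: 1.0 for s in SETTINGS}, "travel": 0.5}
        dataset, _ = generate(cfg, seed=6)
        props = presence_proportions(dataset).set_index(["tool", "day", "setting"])
        ratios = []
        for day in ("Wed", "Fri", "Sun"):
            paper = props.loc[("paper", day, "travel"), "proportion"]
            pda = props.loc[("pda", day, "travel"), "proportion"]
            if paper > 0:
                ratios.append(pda / paper)
        # visit-level thinning at 0.5; subject-days mostly hold one travel
        # visit, so presence drops to about half, within 3 binomial SE
        n = 195
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(ratios) - 0.5) <= 3 * se / np.mean(
            [props.loc[("paper", d, "travel"), "proportion"] for d in ("Wed", "Fri", "Sun")]
        ) + 0.05

    def test_presence_test_detects_planted_bias(self):
        cfg = GeneratorConfig(n_subjects=65)
        cfg.tool_bias["pda"] = {**{s: 1.0 for s in SETTINGS}, "travel": 0.3}
        dataset, _ = generate(cfg, seed=7)
        p, (only_paper, only_pda) = presence_test(dataset, "paper", "pda", "travel")
        assert only_paper > only_pda
        assert p < 1e-4

    def test_presence_test_null_on_unbiased_tools(self):
        cfg = GeneratorConfig(n_subjects=40)
        cfg.tool_bias["pda"] = {s: 1.0 for s in SETTINGS}
        dataset, _ = generate(cfg, seed=8)
        p, (only_paper, only_pda) = presence_test(dataset, "paper", "pda", "work")
        assert (only_paper, only_pda) == (0, 0)
        assert p == 1.0


class TestRankComparison:
    def test_six_groups_give_fifteen_comparisons(self):
        rng = np.random.default_rng(15)
        groups = {s: rng.random(8) for s in SETTINGS}
        res = setting_rank_comparison(groups)
        assert res.n_comparisons == 15
        assert len(res.pairwise) == 15

    def test_bonferroni_multiplies_raw_p(self):
        rng = np.random.default_rng(16)
        groups = {s: rng.random(12) for s in SETTINGS[:4]}
        res = setting_rank_comparison(groups)
        m = res.n_comparisons
        for _, row in res.pairwise.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * m))
            assert row["p_adjusted"] >= row["p_raw"] - 1e-15

    def test_wilcoxon_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            pooled = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = pooled[:n1], pooled[n1:]
            res = setting_rank_comparison({"a": x, "b": y})
            want = wilcoxon_exact_enumeration(x, y)
            assert res.pairwise["p_raw"].iloc[0] == pytest.approx(want)

    def test_identical_values_return_null_result(self):
        res = setting_rank_comparison({"a": np.ones(5), "b": np.ones(4)})
        assert res.kw_statistic == 0.0
        assert res.kw_p == 1.0
        assert res.pairwise["p_raw"].iloc[0] == 1.0

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            setting_rank_comparison({"a": np.array([1.0]), "b": np.array([])})


class TestNBRegression:
    def test_recovers_planted_irr_at_large_n(self):
        rng = np.random.default_rng(7)
        n, irr, alpha = 5000, 0.8, 0.3
        x = rng.integers(0, 2, n).astype(float)
        mu = np.exp(np.log(4.0) + np.log(irr) * x)
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        res = nb_regression(y, x)
        assert abs(res.irr - irr) / irr < 0.05
        assert res.ci_low <= irr <= res.ci_high
        assert res.converged

    def test_poisson_limit_matches_poisson_ml_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(18)
        x = rng.integers(0, 2, 4000).astype(float)
        y = rng.poisson(np.exp(0.5 + 0.3 * x))
        nb = nb_regression(y, x)
        po = sm.Poisson(y, sm.add_constant(x)).fit(disp=0)
        assert abs(nb.beta - po.params[1]) < 1e-4
        assert abs(nb.intercept - po.params[0]) < 1e-4

    def test_constant_covariate_is_degenerate(self):
        y = np.array([1, 2, 3, 4, 5])
        with pytest.raises(RegressionError, match="constant"):
            nb_regression(y, np.ones(5))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(RegressionError, match="zero"):
            nb_regression(np.zeros(10), np.arange(10.0))

    def test_ci_brackets_irr(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=800)
        mu = np.exp(1.0 + 0.2 * x)
        y = rng.negative_binomial(1 / 0.4, 1 / (1 + 0.4 * mu))
        res = nb_regression(y, x)
        assert res.ci_low < res.irr < res.ci_high
        assert np.exp((np.log(res.ci_low) + np.log(res.ci_high)) / 2) == pytest.approx(
            res.irr
        )


class TestLocationsVisited:
    def test_single_setting_day(self, tiny_dataset):
        counts = locations_visited(tiny_dataset)
        assert counts["n_settings"].tolist() == [2]  # home + work

    def test_counts_match_distinct_scan_oracle(self, default_study):
        dataset, _ = default_study
        counts = locations_visited(dataset.for_tool("paper")).set_index(
            ["subject_id", "day"]
        )["n_settings"]
        vis = dataset.for_tool("paper").visits
        rng = np.random.default_rng(20)
        keys = vis[["subject_id", "day"]].drop_duplicates().to_numpy()
        for sid, day in keys[rng.choice(len(keys), 25, replace=False)]:
            want = len(
                set(
                    vis[(vis["subject_id"] == sid) & (vis["day"] == day)]["setting"]
                )
            )
            assert counts.loc[(sid, day)] == want
            assert 1 <= want <= 6
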