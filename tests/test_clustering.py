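"""Clustering: linkage oracle equivalence, pseudo-F, labels, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactprofiler import (
    average_linkage,
    calinski_harabasz,
    cut,
    distance_matrix,
    label_clusters,
    membership_diversity,
    occupancy_table,
    profile_distance,
    select_k,
)
from contactprofiler.diary_model import SETTINGS
from oracles import (
    brute_force_average_linkage,
    brute_force_partition,
    calinski_harabasz_formula,
)


def _partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


class TestDistance:
    def test_zero_for_identical_profiles(self):
        p = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert profile_distance(p, p) == 0.0

    def test_orthogonal_indicators(self):
        p = np.zeros(6); p[0] = 1.0
        q = np.zeros(6); q[1] = 1.0
        assert profile_distance(p, q) == pytest.approx(np.sqrt(2))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=1, max_value=2**31 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = rng.dirichlet(np.ones(6), size=3)
        dpq = profile_distance(p, q)
        assert dpq == pytest.approx(profile_distance(q, p))
        assert dpq <= profile_distance(p, r) + profile_distance(r, q) + 1e-12

    def test_matrix_matches_pairwise_function(self):
        rng = np.random.default_rng(4)
        x = rng.dirichlet(np.ones(6), size=8)
        d = distance_matrix(x)
        for i in range(8):
            for j in range(8):
                assert d[i, j] == pytest.approx(profile_distance(x[i], x[j]))


class TestAverageLinkage:
    def test_hand_computable_three_point_line(self):
        # 1-D points {0, 1, 10}: first merge {0,1} at 1, then at (10+9)/2
        d = distance_matrix(np.array([[0.0], [1.0], [10.0]]))
        dend = average_linkage(d)
        assert dend.merges[0][:3].tolist() == [0.0, 1.0, 1.0]
        assert dend.merges[1][2] == pytest.approx(9.5)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            x = rng.random((n, 3))
            d = distance_matrix(x)
            dend = average_linkage(d)
            oracle = brute_force_average_linkage(d)
            for got, want in zip(dend.merges, oracle):
                assert (int(got[0]), int(got[1])) == (want[0], want[1])
                assert got[2] == pytest.approx(want[2], abs=1e-9)
                assert int(got[3]) == want[3]

    def test_leaf_permutation_preserves_partitions(self):
        rng = np.random.default_rng(6)
        n = 10
        x = rng.random((n, 4))
        d = distance_matrix(x)
        perm = rng.permutation(n)
        d_perm = d[np.ix_(perm, perm)]
        dend = average_linkage(d)
        dend_perm = average_linkage(d_perm)
        for k in range(1, n + 1):
            a = _partition(cut(dend, k))
            b_perm = cut(dend_perm, k)
            b = _partition([b_perm[np.where(perm == i)[0][0]] for i in range(n)])
            assert a == b

    def test_average_heights_are_monotone(self):
        rng = np.random.default_rng(7)
        x = rng.random((15, 3))
        dend = average_linkage(distance_matrix(x))
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_rejects_asymmetric_input(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(d)

    def test_agrees_with_scipy_on_tie_free_instances(self):
        # independent library cross-check (scipy breaks ties differently,
        # so only tie-free random instances are compared)
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.random((12, 4))
            dend = average_linkage(distance_matrix(x))
            scipy_z = linkage(pdist(x), method="average")
            assert np.allclose(dend.heights, scipy_z[:, 2])
            for k in (2, 3, 5):
                ours = _partition(cut(dend, k))
                theirs = _partition(fcluster(scipy_z, k, criterion="maxclust"))
                assert ours == theirs


class TestCut:
    @pytest.fixture
    def line_dend(self):
        return average_linkage(distance_matrix(np.array([[0.0], [1.0], [10.0]])))

    def test_k_equals_n_gives_singletons(self, line_dend):
        assert cut(line_dend, 3).tolist() == [0, 1, 2]

    def test_k_one_gives_single_cluster(self, line_dend):
        assert cut(line_dend, 1).tolist() == [0, 0, 0]

    def test_k_two_separates_the_outlier(self, line_dend):
        assert cut(line_dend, 2).tolist() == [0, 0, 1]

    def test_cut_matches_oracle_partitions(self):
        rng = np.random.default_rng(9)
        x = rng.random((11, 2))
        d = distance_matrix(x)
        dend = average_linkage(d)
        oracle = brute_force_average_linkage(d)
        for k in range(1, 12):
            assert _partition(cut(dend, k)) == brute_force_partition(oracle, 11, k)


class TestPseudoF:
    def test_two_blob_line_formula(self):
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        assert calinski_harabasz(x, labels) == pytest.approx(200.0)

    def test_singleton_clusters_give_infinity(self):
        x = np.array([[0.0], [1.0], [2.0]])
        assert calinski_harabasz(x, np.array([0, 1, 2])) == np.inf

    def test_matches_direct_formula_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            k = int(rng.integers(2, min(n - 1, 6)))
            x = rng.random((n, 4))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_harabasz(x, labels) == pytest.approx(
                calinski_harabasz_formula(x, labels)
            )

    def test_invariant_to_label_permutation_and_rotation(self):
        rng = np.random.default_rng(11)
        x = rng.random((20, 3))
        labels = rng.integers(0, 3, size=20)
        base = calinski_harabasz(x, labels)
        relabelled = (labels + 1) % 3
        assert calinski_harabasz(x, relabelled) == pytest.approx(base)
        q, _ = np.linalg.qr(rng.random((3, 3)))
        assert calinski_harabasz(x @ q, labels) == pytest.approx(base)

    def test_matches_sklearn_on_random_instances(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(12)
        x = rng.random((40, 5))
        labels = rng.integers(0, 4, size=40)
        assert calinski_harabasz(x, labels) == pytest.approx(
            calinski_harabasz_score(x, labels)
        )


class TestSelection:
    def test_two_well_separated_blobs_choose_k2(self):
        rng = np.random.default_rng(13)
        x = np.vstack(
            [rng.normal(0, 0.05, (20, 2)), rng.normal(5, 0.05, (20, 2))]
        )
        dend = average_linkage(distance_matrix(x))
        result = select_k(x, dend, k_max=8, cap=None)
        assert result.chosen_k == 2

    def test_cap_rule_truncates_argmax(self):
        rng = np.random.default_rng(14)
        centers = np.arange(9) * 10.0
        x = np.vstack(
            [rng.normal(c, 0.01, (6, 1)) for c in centers]
        )
        dend = average_linkage(distance_matrix(x))
        uncapped = select_k(x, dend, k_max=12, cap=None)
        assert uncapped.argmax_k > 6
        capped = select_k(x, dend, k_max=12, cap=6)
        assert capped.argmax_k == uncapped.argmax_k
        assert capped.chosen_k == 6
        assert len(np.unique(capped.assignments)) == 6


class TestLabels:
    def test_dominant_setting_labels(self):
        x = np.array(
            [
                [0.8, 0.04, 0.04, 0.04, 0.04, 0.04],
                [0.7, 0.06, 0.06, 0.06, 0.06, 0.06],
                [0.05, 0.05, 0.05, 0.05, 0.05, 0.75],
            ]
        )
        labels, means, duplicated = label_clusters(x, np.array([0, 0, 1]))
        assert labels == ["HD", "WD"]
        assert not duplicated
        assert means.loc[0, "home"] == pytest.approx(0.75)

    def test_duplicate_dominance_is_flagged(self):
        x = np.array(
            [
                [0.8, 0.04, 0.04, 0.04, 0.04, 0.04],
                [0.9, 0.02, 0.02, 0.02, 0.02, 0.02],
            ]
        )
        labels, _, duplicated = label_clusters(x, np.array([0, 1]))
        assert labels == ["HD", "HD"]
        assert duplicated

    def test_tie_breaks_by_canonical_order(self):
        x = np.array([[0.5, 0.5, 0, 0, 0, 0]])
        labels, _, _ = label_clusters(x, np.array([0]))
        assert labels == ["HD"]  # home precedes other in canonical order


class TestSummaries:
    def test_occupancy_counts_and_totals(self):
        labels = ["HD", "HD", "HD", "WD"]
        days = ["Sun", "Sun", "Sun", "Wed"]
        table = occupancy_table(labels, days)
        assert table.loc["Sun", "HD"] == 3
        assert table.loc["Total", "HD"] == 3
        assert table.loc["Total", "WD"] == 1
        # conservation: row sums equal per-day clustered counts
        assert table.drop(index="Total").sum(axis=1).tolist() == [1, 3]

    def test_membership_diversity_hand_fixture(self):
        df = pd.DataFrame(
            {
                "subject_id": ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3 + ["E"] * 3,
                "label": ["HD", "HD", "HD",
                          "HD", "WD", "SD",
                          "HD", "WD", "HD",
                          "SD", "SD", "OD",
                          "HD", "HD", "WD"],
            }
        )
        counts, summary = membership_diversity(df)
        assert counts.loc["A"] == 1
        assert counts.loc["B"] == 3
        # direct enumeration: (1 + 3 + 2 + 2 + 2) / 5
        assert summary["mean"] == pytest.approx(2.0)
        assert summary["median"] == 2.0
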