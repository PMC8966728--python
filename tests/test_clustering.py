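"""Ward tree, pruning cuts, silhouettes, within-cluster pairs and the sweep."""

import numpy as np
import pytest

from formsem import (
    ParameterError,
    WardHeightClusterer,
    cut_at_percent,
    enumerate_pairs,
    extract_cluster,
    fill_similarities,
    height_for_cluster_count,
    run_pairwise,
    run_sweep,
    silhouette,
    ward_linkage,
    within_cluster_pairs,
)
from formsem.pairwise import pearson

from conftest import direct_silhouette, naive_ward_heights


def two_triplet_data():
    """Two tight triplets far apart: the final merge must join the triplets."""
    a = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1]])
    b = a + 100.0
    return np.vstack([a, b])


class TestWardLinkage:
    def test_two_points_merge_at_their_euclidean_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_linkage(X)
        assert tree.Z[0, 2] == pytest.approx(5.0)

    def test_two_far_triplets_join_last(self):
        tree = ward_linkage(two_triplet_data())
        last = tree.Z[-1]
        assert last[3] == 6  # final merge contains all points
        assert tree.Z[-1, 2] > 10 * tree.Z[-2, 2]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        tree = ward_linkage(rng.normal(size=(25, 4)))
        assert np.all(np.diff(tree.Z[:, 2]) >= -1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_heights_match_naive_cubic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        X = rng.normal(size=(n, 3))
        tree = ward_linkage(X)
        np.testing.assert_allclose(tree.Z[:, 2], naive_ward_heights(X), atol=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ParameterError):
            ward_linkage(np.zeros((1, 3)))


class TestCutAtPercent:
    def test_height_zero_gives_all_singletons(self):
        tree = ward_linkage(two_triplet_data())
        sol = cut_at_percent(tree, 0)
        assert sol.n_clusters == 6

    def test_height_hundred_gives_one_cluster(self):
        tree = ward_linkage(two_triplet_data())
        sol = cut_at_percent(tree, 100)
        assert sol.n_clusters == 1

    def test_two_triplets_at_fifty_percent(self):
        tree = ward_linkage(two_triplet_data())
        sol = cut_at_percent(tree, 50)
        assert sol.n_clusters == 2
        assert sol.labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_labels_stable_by_smallest_member(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        sol = cut_at_percent(ward_linkage(X), 40)
        firsts = [np.flatnonzero(sol.labels == c)[0] for c in range(sol.n_clusters)]
        assert firsts == sorted(firsts)

    def test_n_clusters_weakly_decreasing_in_height(self):
        rng = np.random.default_rng(2)
        tree = ward_linkage(rng.normal(size=(40, 5)))
        counts = [cut_at_percent(tree, h).n_clusters for h in range(0, 101, 5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_out_of_range_height_rejected(self):
        tree = ward_linkage(two_triplet_data())
        with pytest.raises(ParameterError):
            cut_at_percent(tree, 101)


class TestSilhouette:
    def test_two_tight_separated_pairs_score_high(self):
        X = np.array([[0.0, 0], [0.1, 0], [50.0, 0], [50.1, 0]])
        s = silhouette(X, np.array([0, 0, 1, 1]))
        assert s > 0.9
        assert s == pytest.approx(direct_silhouette(X, np.array([0, 0, 1, 1])), abs=1e-12)

    def test_random_labels_on_one_blob_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 3))
        labels = rng.integers(0, 2, 80)
        assert abs(silhouette(X, labels)) < 0.1

    def test_matches_direct_formula_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(10, 60))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, 4, n)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(X, labels) == pytest.approx(
                direct_silhouette(X, labels), abs=1e-12
            )

    def test_label_name_swap_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        labels = rng.integers(0, 2, 30)
        assert silhouette(X, labels) == pytest.approx(silhouette(X, 1 - labels))

    def test_undefined_for_one_cluster_or_all_singletons(self):
        X = np.random.default_rng(6).normal(size=(5, 2))
        assert np.isnan(silhouette(X, np.zeros(5, dtype=int)))
        assert np.isnan(silhouette(X, np.arange(5)))


class TestWithinClusterPairs:
    def test_closed_form_counts(self):
        sol = cut_at_percent(ward_linkage(two_triplet_data()), 50)
        pairs = within_cluster_pairs(sol)
        assert len(pairs) == 3 + 3

    def test_explicit_small_partition(self):
        from formsem.clustering import ClusterSolution

        sol = ClusterSolution(0, 0.0, np.array([0, 0, 0, 1, 1]), 2)
        pairs = within_cluster_pairs(sol)
        assert pairs.tolist() == [[0, 1], [0, 2], [1, 2], [3, 4]]

    def test_height_zero_has_no_pairs(self):
        sol = cut_at_percent(ward_linkage(two_triplet_data()), 0)
        assert len(within_cluster_pairs(sol)) == 0

    def test_height_hundred_equals_full_enumeration(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 3))
        sol = cut_at_percent(ward_linkage(X), 100)
        pairs = within_cluster_pairs(sol)
        np.testing.assert_array_equal(pairs, enumerate_pairs(15).pairs)

    def test_pair_count_weakly_increasing_in_height(self):
        rng = np.random.default_rng(8)
        tree = ward_linkage(rng.normal(size=(30, 4)))
        counts = [len(within_cluster_pairs(cut_at_percent(tree, h)))
                  for h in range(0, 101, 10)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestRunSweep:
    def test_grid_schema_and_height_zero_row(self, small_synthetic):
        _, _, al = small_synthetic
        res = run_sweep(al, heights=[0], scopes=("entire",))
        row = res.grid.iloc[0]
        assert row["n_within_pairs"] == 0
        assert np.isnan(row["r"]) and not row["significant"]

    def test_full_height_matches_lexicon_wide_correlation(self, small_synthetic):
        _, _, al = small_synthetic
        res = run_sweep(al, heights=[100], scopes=("entire",))
        row = res.grid.iloc[0]
        global_r = run_pairwise(al, scopes=("entire",))["entire"]
        assert row["r"] == pytest.approx(global_r.r, abs=1e-10)
        assert row["df"] == global_r.df

    def test_pooled_correlation_matches_manual_pooling(self, small_synthetic):
        _, _, al = small_synthetic
        tree = ward_linkage(al.sem_vectors)
        h = height_for_cluster_count(tree, 4)
        res = run_sweep(al, heights=[h], scopes=("entire",))
        sol = cut_at_percent(tree, h)
        pairs = within_cluster_pairs(sol)
        pt = fill_similarities(enumerate_pairs(al), al, scopes=("entire",))
        key = {(i, j): k for k, (i, j) in enumerate(map(tuple, pt.pairs))}
        idx = [key[tuple(p)] for p in map(tuple, pairs)]
        manual = pearson(pt.sem_sim[idx], pt.phono_sim["entire"][idx])
        assert res.grid.iloc[0]["r"] == pytest.approx(manual.r, abs=1e-10)

    def test_height_for_cluster_count_finds_generative_granularity(self, small_synthetic):
        cfg, syn, al = small_synthetic
        tree = ward_linkage(al.sem_vectors)
        h = height_for_cluster_count(tree, cfg.n_clusters)
        sol = cut_at_percent(tree, h)
        assert sol.n_clusters == cfg.n_clusters
        # well-separated planted clusters: cut must recover the truth exactly
        truth = np.asarray(syn.truth["cluster_of"])
        match = {}
        for c in range(sol.n_clusters):
            members = truth[sol.labels == c]
            assert len(set(members)) == 1
            match[c] = members[0]
        assert len(set(match.values())) == cfg.n_clusters


class TestExtractCluster:
    def test_query_returns_cluster_membership_and_pairs(self, small_synthetic):
        cfg, syn, al = small_synthetic
        tree = ward_linkage(al.sem_vectors)
        sol = cut_at_percent(tree, height_for_cluster_count(tree, cfg.n_clusters))
        g = al.glosses[0]
        membership, pairs = extract_cluster(sol, al, [g], scopes=("entire",))
        assert any(g in m for m in membership.values())
        (c, members), = membership.items()
        s = len(members)
        assert len(pairs) == s * (s - 1) // 2

    def test_absent_gloss_yields_empty_result_with_warning(self, small_synthetic, caplog):
        _, _, al = small_synthetic
        sol = cut_at_percent(ward_linkage(al.sem_vectors), 50)
        with caplog.at_level("WARNING"):
            membership, pairs = extract_cluster(sol, al, ["nonexistent"])
        assert membership == {} and pairs.empty
        assert "no query gloss" in caplog.text


class TestWardHeightClusterer:
    def test_sklearn_estimator_api(self):
        X = two_triplet_data()
        est = WardHeightClusterer(height_percent=50.0)
        labels = est.fit_predict(X)
        assert est.n_clusters_ == 2
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert est.get_params() == {"height_percent": 50.0}
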