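"""Risk computation, 1-D k-means (Lloyd vs exact DP), validity indices, gap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

from edrisk import cluster
from .conftest import make_records


# ---------------------------------------------------------------- risk profiles

class TestRiskProfiles:
    def test_code_risk_is_admission_fraction(self):
        df = make_records(["A09"] * 4, [1, 0, 0, 0])
        out = cluster.compute_code_risks(df)
        assert out.loc[0, "risk"] == 0.25

    def test_extreme_risks(self):
        df = make_records(["A09"] * 3 + ["J10"] * 2, [1, 1, 1, 0, 0])
        out = cluster.compute_code_risks(df).set_index("code")
        assert out.loc["A09", "risk"] == 1.0 and out.loc["J10", "risk"] == 0.0

    def test_profile_counts_conserve_records(self, small_registry):
        _, df = small_registry
        out = cluster.compute_code_risks(df)
        assert out["n"].sum() == len(df)

    def test_empty_input_empty_output(self):
        assert len(cluster.compute_code_risks(make_records([], []))) == 0

    def test_block_risk_pools_member_codes(self):
        from edrisk import blocks
        df = make_records(["J10"] * 20 + ["J12"] * 20, [1] * 10 + [0] * 30)
        out = cluster.compute_block_risks(df, blocks.parse_block_table())
        assert out.loc[0, "code"] == "J09-J18"
        assert out.loc[0, "risk"] == 0.25
        assert out["n"].sum() == len(df)


# -------------------------------------------------------------------- k-means

def brute_force_1d(values, k):
    """Exhaustive minimum WCSS over contiguous partitions of sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        wcss = sum(((seg := v[a:b]) - seg.mean()) @ (seg - seg.mean())
                   for a, b in zip(bounds, bounds[1:]))
        best = min(best, wcss)
    return best


class TestKmeans:
    def test_obvious_two_cluster_split(self):
        model = cluster.kmeans_1d([0.10, 0.12, 0.80, 0.82], 2, seed=0)
        np.testing.assert_allclose(model.centroids, [0.11, 0.81])
        np.testing.assert_array_equal(model.labels, [1, 1, 2, 2])

    def test_k1_closed_form(self):
        v = np.array([0.2, 0.4, 0.9])
        model = cluster.kmeans_1d(v, 1, seed=0)
        assert model.wcss == pytest.approx(((v - v.mean()) ** 2).sum())

    def test_k_larger_than_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            cluster.kmeans_1d([0.1, 0.1, 0.2], 3, seed=0)
        with pytest.raises(ValueError):
            cluster.kmeans_1d([0.1, 0.2], 0, seed=0)

    def test_exact_dp_example(self):
        model = cluster.kmeans_1d_exact([0, 1, 2, 10], 2)
        assert model.wcss == pytest.approx(2.0)
        np.testing.assert_array_equal(model.labels, [1, 1, 1, 2])

    def test_exact_k_equals_n_gives_zero_wcss(self):
        assert cluster.kmeans_1d_exact([1.0, 2.0, 5.0], 3).wcss == 0.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            v = rng.random(10)
            for k in (2, 3, 4):
                assert cluster.kmeans_1d_exact(v, k).wcss == pytest.approx(
                    brute_force_1d(v, k), abs=1e-12)

    def test_lloyd_never_beats_exact_and_matches_with_restarts(self):
        rng = np.random.default_rng(1)
        for i in range(40):
            n = int(rng.integers(4, 13))
            v = rng.random(n)
            k = int(rng.integers(2, min(4, n) + 1))
            exact = cluster.kmeans_1d_exact(v, k).wcss
            lloyd = cluster.kmeans_1d(v, k, n_init=50, seed=i).wcss
            assert lloyd >= exact - 1e-12
            assert lloyd == pytest.approx(exact, abs=1e-10)

    def test_labels_ordered_by_centroid(self):
        rng = np.random.default_rng(2)
        v = rng.random(30)
        model = cluster.kmeans_1d(v, 4, seed=3)
        assert np.all(np.diff(model.centroids) > 0)
        for lab in range(1, 4):
            assert v[model.labels == lab].max() <= v[model.labels == lab + 1].min()

    def test_weighted_clustering_moves_centroid(self):
        v = np.array([0.0, 1.0])
        m = cluster.kmeans_1d(v, 1, weights=np.array([3.0, 1.0]), seed=0)
        assert m.centroids[0] == pytest.approx(0.25)


# ------------------------------------------------------------ validity indices

def silhouette_by_definition(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(values)):
        own = np.flatnonzero((labels == labels[i]))
        if len(own) == 1:
            scores.append(0.0)
            continue
        a = np.mean([abs(values[i] - values[j]) for j in own if j != i])
        b = min(np.mean([abs(values[i] - values[j])
                         for j in np.flatnonzero(labels == lab)])
                for lab in set(labels) - {labels[i]})
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores)), np.array(scores)


class TestIndices:
    def test_silhouette_perfect_duplicate_pairs(self):
        mean, pts = cluster.silhouette([0, 0, 1, 1], [1, 1, 2, 2])
        assert mean == 1.0 and np.all(pts == 1.0)

    def test_swapped_point_scores_negative(self):
        values = [0.0, 0.01, 0.02, 1.0, 1.01, 0.015]
        labels = [1, 1, 1, 2, 2, 2]     # last point sits in the wrong blob
        _, pts = cluster.silhouette(values, labels)
        assert pts[-1] < 0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster.silhouette([0, 1], [1, 1])

    def test_calinski_harabasz_hand_value(self):
        assert cluster.calinski_harabasz(
            [0, 0.2, 1.0, 1.2], [1, 1, 2, 2]) == pytest.approx(50.0)

    def test_calinski_harabasz_scale_invariance(self):
        v = np.array([0, 0.2, 1.0, 1.2])
        labs = [1, 1, 2, 2]
        assert cluster.calinski_harabasz(2 * v, labs) == pytest.approx(
            cluster.calinski_harabasz(v, labs))

    def test_davies_bouldin_hand_value(self):
        assert cluster.davies_bouldin(
            [0, 0.2, 1.0, 1.2], [1, 1, 2, 2]) == pytest.approx(0.2)

    def test_davies_bouldin_halves_when_separation_doubles(self):
        near = cluster.davies_bouldin([0, 0.2, 1.0, 1.2], [1, 1, 2, 2])
        far = cluster.davies_bouldin([0, 0.2, 2.0, 2.2], [1, 1, 2, 2])
        assert far == pytest.approx(near / 2)

    def test_indices_match_definition_and_sklearn(self):
        # dual-route oracle: per-definition recomputation plus the library's
        # euclidean implementations (equivalent to |.| in one dimension)
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.random(30)
            labs = cluster.kmeans_1d(v, 3, seed=1).labels
            mean_s, pts = cluster.silhouette(v, labs)
            dmean, dpts = silhouette_by_definition(v, labs)
            np.testing.assert_allclose(pts, dpts, atol=1e-10)
            np.testing.assert_allclose(
                pts, silhouette_samples(v.reshape(-1, 1), labs), atol=1e-10)
            assert cluster.calinski_harabasz(v, labs) == pytest.approx(
                calinski_harabasz_score(v.reshape(-1, 1), labs), rel=1e-10)
            assert cluster.davies_bouldin(v, labs) == pytest.approx(
                davies_bouldin_score(v.reshape(-1, 1), labs), rel=1e-10)


# ------------------------------------------------------------- model selection

class TestSelection:
    def test_gap_prefers_two_clusters_for_two_blobs(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0.1, 0.01, 30), rng.normal(0.8, 0.01, 30)])
        gaps = cluster.gap_statistic(v, [1, 2, 3], n_reference=50, seed=6)
        assert gaps[2][0] > gaps[1][0]

    def test_gap_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        v = rng.random(40)
        a = cluster.gap_statistic(v, [1, 2, 3], n_reference=20, seed=8)
        b = cluster.gap_statistic(v, [1, 2, 3], n_reference=20, seed=8)
        assert a == b

    def test_gap_peaks_at_four_well_separated_tiers(self):
        rng = np.random.default_rng(9)
        v = np.concatenate([rng.normal(c, 0.012, 60)
                            for c in (0.047, 0.195, 0.478, 0.78)])
        gaps = cluster.gap_statistic(v, range(1, 7), n_reference=50, seed=10)
        assert max(gaps, key=lambda k: gaps[k][0]) == 4

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            cluster.gap_statistic([0.3, 0.3, 0.3], [1, 2], n_reference=10, seed=0)

    def test_select_k_rules(self):
        rep = cluster.ClusterSelectionReport(
            k_range=(1, 2, 3, 4),
            wcss={}, gap={1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
            gap_se={k: 1e-6 for k in range(1, 5)})
        assert cluster.select_k(rep, "gap_1se") == 1       # flat gaps, tiny se
        rep_peak = cluster.ClusterSelectionReport(
            k_range=(1, 2, 3, 4, 5),
            wcss={}, gap={1: 0.1, 2: 0.5, 3: 0.9, 4: 1.4, 5: 1.1},
            gap_se={k: 0.01 for k in range(1, 6)})
        assert cluster.select_k(rep_peak, "gap_max") == 4
        assert cluster.select_k(rep_peak, "manual", manual_k=4) == 4
        with pytest.raises(ValueError):
            cluster.select_k(rep_peak, "manual")

    def test_wcss_nonincreasing_in_k(self):
        rng = np.random.default_rng(11)
        v = rng.random(60)
        rep = cluster.selection_report(v, range(1, 6), n_init=10,
                                       n_reference=10, seed=12)
        wcss = [rep.wcss[k] for k in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(wcss, wcss[1:]))


# ------------------------------------------------------------------ propagation

class TestPropagation:
    def test_presentations_inherit_code_cluster(self):
        df = make_records(["A09"] * 3 + ["J10"] * 2, [0, 0, 0, 1, 1])
        risks = cluster.compute_code_risks(df)
        model = cluster.kmeans_1d(risks["risk"].to_numpy(), 2, seed=0,
                                  codes=risks["code"].tolist())
        out = cluster.propagate_clusters(df, model)
        assert (out.groupby("icd10")["cluster"].nunique() == 1).all()
        assert len(out) == len(df)

    def test_unassigned_code_rejected(self):
        df = make_records(["A09", "J10"], [0, 1])
        risks = cluster.compute_code_risks(df.iloc[:1])
        model = cluster.kmeans_1d(risks["risk"].to_numpy(), 1, seed=0,
                                  codes=risks["code"].tolist())
        with pytest.raises(KeyError):
            cluster.propagate_clusters(df, model)

    def test_weighted_cluster_rates_reproduce_overall_rate(self, small_registry):
        from edrisk import preprocess
        _, df = small_registry
        filt, _ = preprocess.filter_low_frequency_codes(df, 15)
        risks = cluster.compute_code_risks(filt)
        model = cluster.kmeans_1d(risks["risk"].to_numpy(), 4, seed=1,
                                  codes=risks["code"].tolist())
        out = cluster.propagate_clusters(filt, model)
        summ = cluster.cluster_presentation_summary(out)
        assert summ["n"].sum() == len(filt)
        weighted = (summ["share"] * summ["admission_rate"]).sum()
        assert weighted == pytest.approx(filt["admitted"].mean(), abs=5e-4)
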