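import numpy as np
import pandas as pd
import pytest

from stagetraj import (
    RunConfig,
    StageProfileMatrix,
    WcssCurve,
    kmeans_fit,
    label_clusters,
    select_k,
    wcss_sweep,
)

STAGES = ["E18.5", "12wk", "39wk"]


def _profiles(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=genes, columns=STAGES[: arr.shape[1]])
    return StageProfileMatrix(df, condition="Natural")


def _planted(rng, centers, n_per, spread):
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(c + rng.normal(0, spread, size=(n_per, len(c))))
        labels += [i] * n_per
    return np.vstack(rows), np.array(labels)


class TestKmeansFit:
    def test_two_well_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        x, truth = _planted(rng, [np.zeros(3), np.full(3, 10.0)], 25, 0.3)
        model = kmeans_fit(_profiles(x), k=2, n_restarts=10, seed=1)
        got = model.assignments.to_numpy()
        # agreement up to relabeling, checked by brute force over both labelings
        agree = max(
            (got == truth + 1).mean(), (got == 2 - truth).mean()
        )
        assert agree == 1.0

    def test_k_equals_n_gives_zero_wcss(self):
        x = np.arange(12, dtype=float).reshape(4, 3)
        model = kmeans_fit(_profiles(x), k=4, n_restarts=5, seed=0)
        assert model.wcss == 0.0
        assert sorted(model.cluster_sizes) == [1, 1, 1, 1]

    def test_k1_wcss_is_total_ss_about_grand_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 3))
        model = kmeans_fit(_profiles(x), k=1, n_restarts=3, seed=0)
        expected = ((x - x.mean(axis=0)) ** 2).sum()
        assert model.wcss == pytest.approx(expected, rel=1e-10)

    def test_k_above_distinct_rows_rejected(self):
        x = np.array([[1.0, 0, 0]] * 3 + [[0, 1.0, 0]] * 3)
        with pytest.raises(ValueError, match="distinct"):
            kmeans_fit(_profiles(x), k=3, seed=0)

    def test_bit_reproducible_with_same_seed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(60, 3))
        m1 = kmeans_fit(_profiles(x), k=4, n_restarts=7, seed=99)
        m2 = kmeans_fit(_profiles(x), k=4, n_restarts=7, seed=99)
        assert m1.wcss == m2.wcss
        assert (m1.assignments == m2.assignments).all()
        assert (m1.centroids == m2.centroids).all().all()

    def test_centroids_are_member_means_and_no_empty_cluster(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 3))
        model = kmeans_fit(_profiles(x), k=6, n_restarts=5, seed=2)
        assert (model.cluster_sizes > 0).all()
        for c in model.centroids.index:
            members = x[(model.assignments == c).to_numpy()]
            assert np.allclose(model.centroids.loc[c], members.mean(axis=0), atol=1e-8)

    def test_matches_sklearn_inertia_on_shared_problem(self):
        """Independent cross-check: a strong generic k-means should find the
        same optimum on an easy, well-separated problem."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(11)
        centers = [np.array(c, dtype=float) for c in
                   [(0, 0, 0), (8, 0, 0), (0, 8, 0), (0, 0, 8)]]
        x, _ = _planted(rng, centers, 30, 0.5)
        ours = kmeans_fit(_profiles(x), k=4, n_restarts=20, seed=5)
        theirs = sklearn_cluster.KMeans(n_clusters=4, n_init=20, random_state=0).fit(x)
        assert ours.wcss == pytest.approx(theirs.inertia_, rel=1e-6)


class TestWcssSweep:
    def test_curve_covers_k_range(self, tiny_sim):
        rng = np.random.default_rng(1)
        x, _ = _planted(rng, [np.zeros(3), np.full(3, 5.0), np.array([0, 5, 0.0])],
                        20, 0.4)
        cfg = RunConfig(k_min=2, k_max=15, n_restarts=10, seed=0)
        curve, models = wcss_sweep(_profiles(x), cfg)
        assert len(curve.k_values) == 14
        assert set(models) == set(range(2, 16))

    def test_wcss_zero_at_k_equal_distinct_rows(self):
        x = np.repeat(np.array([[0.0, 0, 0], [5, 5, 5], [9, 0, 9]]), 4, axis=0)
        cfg = RunConfig(k_min=2, k_max=3, n_restarts=10, seed=0)
        curve, models = wcss_sweep(_profiles(x), cfg)
        assert curve.wcss[-1] == pytest.approx(0.0, abs=1e-12)

    def test_wcss_matches_recomputation_from_model(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 3))
        cfg = RunConfig(k_min=2, k_max=6, n_restarts=10, seed=3)
        curve, models = wcss_sweep(_profiles(x), cfg)
        for k, model in models.items():
            recomputed = 0.0
            for g, c in model.assignments.items():
                diff = x[list(model.assignments.index).index(g)] - \
                    model.centroids.loc[c].to_numpy()
                recomputed += float(diff @ diff)
            assert model.wcss == pytest.approx(recomputed, rel=1e-8)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 3))
        cfg = RunConfig(k_min=2, k_max=10, n_restarts=50, seed=1)
        curve, _ = wcss_sweep(_profiles(x), cfg)
        assert (np.diff(curve.wcss) <= 1e-9).all()

    def test_subseeds_stable_under_range_extension(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 3))
        short = RunConfig(k_min=2, k_max=4, n_restarts=5, seed=42)
        long = RunConfig(k_min=2, k_max=8, n_restarts=5, seed=42)
        _, m_short = wcss_sweep(_profiles(x), short)
        _, m_long = wcss_sweep(_profiles(x), long)
        for k in (2, 3, 4):
            assert m_short[k].wcss == m_long[k].wcss
            assert (m_short[k].assignments == m_long[k].assignments).all()


class TestSelectK:
    def test_worked_curve_selects_four(self):
        curve = WcssCurve(np.arange(2, 7), np.array([100.0, 60, 50, 48, 47]))
        gains = curve.gains
        assert gains[3] == pytest.approx(0.40)
        assert gains[4] == pytest.approx(1 / 6, rel=1e-9)
        assert gains[5] == pytest.approx(0.04)
        assert gains[6] == pytest.approx(1 / 48, rel=1e-9)
        k, rationale = select_k(curve, 0.05)
        assert k == 4
        assert rationale["rule"] == "elbow"

    def test_geometric_curve_has_no_elbow(self):
        ks = np.arange(2, 16)
        curve = WcssCurve(ks, 0.5 ** ks)
        k, rationale = select_k(curve, 0.05)
        assert k == 15
        assert rationale["rule"] == "no-elbow"

    def test_piecewise_linear_elbow_family(self):
        # wcss[k] = A*max(k0-k,0) + B: gains vanish exactly after k0
        for k0 in (4, 7, 11):
            ks = np.arange(2, 16)
            wcss = 50.0 * np.maximum(k0 - ks, 0) + 10.0
            k, _ = select_k(WcssCurve(ks, wcss), 0.05)
            assert k == k0

    def test_non_monotone_curve_is_hard_error(self):
        curve = WcssCurve(np.arange(2, 6), np.array([100.0, 80, 85, 70]))
        with pytest.raises(ValueError, match="monotone"):
            select_k(curve, 0.05)

    def test_planted_archetype_count_recovered(self):
        """A simulation with nine well-separated planted archetypes yields
        a WCSS curve whose elbow sits at nine.

        The relative-gain rule needs the planted count to be reasonably
        large: with very few clusters, splitting even a pure noise blob
        reclaims more than the threshold share of the total WCSS.
        """
        from stagetraj import (
            SimDesign,
            compute_cpm,
            log2_cpm,
            simulate_counts,
            stage_profiles,
            zscore_genes,
        )

        design = SimDesign(genes_per_archetype=40, seed=14)
        counts, meta, _ = simulate_counts(design)
        zm, _ = zscore_genes(log2_cpm(compute_cpm(counts)))
        prof = stage_profiles(zm, meta, "Natural")
        cfg = RunConfig(k_min=2, k_max=12, n_restarts=20, seed=0)
        curve, _ = wcss_sweep(prof, cfg)
        k, _ = select_k(curve, 0.05)
        assert k == len(design.archetypes)


class TestLabelClusters:
    def test_orders_by_first_stage_centroid(self):
        x = np.vstack([np.tile([1.2, 0, -1], (5, 1)), np.tile([-0.8, 0, 1], (7, 1))])
        model = kmeans_fit(_profiles(x), k=2, n_restarts=3, seed=0)
        relabeled = label_clusters(model)
        assert relabeled.centroids.iloc[0, 0] == pytest.approx(-0.8)
        assert relabeled.centroids.iloc[1, 0] == pytest.approx(1.2)
        # genes with first-stage -0.8 must now be in cluster 1
        assert (relabeled.assignments.iloc[5:] == 1).all()

    def test_gene_order_permutation_leaves_labels_unchanged(self):
        rng = np.random.default_rng(12)
        x, _ = _planted(rng, [np.zeros(3), np.full(3, 6.0)], 10, 0.2)
        prof = _profiles(x)
        m = label_clusters(kmeans_fit(prof, 2, n_restarts=5, seed=4))
        perm = rng.permutation(prof.profiles.index)
        prof2 = StageProfileMatrix(prof.profiles.loc[perm], "Natural")
        m2 = label_clusters(kmeans_fit(prof2, 2, n_restarts=5, seed=4))
        assert m.assignments.sort_index().equals(m2.assignments.sort_index())

    def test_wcss_preserved(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(40, 3))
        m = kmeans_fit(_profiles(x), 5, n_restarts=5, seed=7)
        assert label_clusters(m).wcss == m.wcss


class TestRecoveryBenchmark:
    def test_ari_against_planted_labels_with_k_given(self):
        """Well-separated planted archetypes (>= 4 sd) are recovered with
        ARI >= 0.90 when the true k is supplied."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(21)
        centers = [4.0 * np.array([np.cos(t), np.sin(t), 0.0])
                   for t in 2 * np.pi * np.arange(6) / 6]
        spread = 4.0 * 2 * np.sin(np.pi / 6) / 4  # adjacent sep = 4 sd
        x, truth = _planted(rng, centers, 80, spread / np.sqrt(3))
        model = kmeans_fit(_profiles(x), k=6, n_restarts=50, seed=9)
        ari = sklearn_metrics.adjusted_rand_score(truth, model.assignments)
        assert ari >= 0.90
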