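"""Feature preparation, graph clustering, embedding and cluster statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mexquant.calibration import amount_col
from mexquant.phenotyping import (
    ClusterResult,
    FeatureMatrix,
    cluster_heatmap,
    cluster_phenograph,
    compare_clusters,
    embed_umap,
    filter_outliers,
    project_amounts,
    project_clusters,
    scale_features,
    size_normalize,
)
from mexquant.types import SegmentationMask, total_col


def blobs(rng, n_per=100, dim=5, sd=0.02, k=3, min_sep=0.5):
    centers = rng.uniform(0, 1, (k, dim))
    from scipy.spatial.distance import pdist

    while pdist(centers).min() < min_sep:
        centers = rng.uniform(0, 1, (k, dim))
    x = np.vstack([rng.normal(c, sd, (n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return FeatureMatrix(pd.DataFrame(x)), labels


class TestSizeNormalize:
    def cells(self):
        return pd.DataFrame(
            {
                "cell_id": [1, 2],
                "area_px": [100, 50],
                total_col("59Co"): [200.0, 100.0],
            }
        )

    def test_counts_per_square_micron(self):
        fm = size_normalize(self.cells(), pixel_size_um=1.0)
        assert fm.values.loc[1, "59Co"] == pytest.approx(2.0)
        assert fm.state == ("raw", "size-normalized")

    def test_pixel_size_scaling(self):
        fm1 = size_normalize(self.cells(), pixel_size_um=1.0)
        fm2 = size_normalize(self.cells(), pixel_size_um=2.0)
        np.testing.assert_allclose(fm2.values, fm1.values / 4.0)


class TestOutlierFilter:
    def test_extreme_cell_removed(self, rng):
        vals = rng.normal(10, 1, 1000)
        vals[17] = 10 * np.quantile(vals, 0.995)
        fm = FeatureMatrix(
            pd.DataFrame({"59Co": vals}, index=pd.RangeIndex(1000, name="cell_id"))
        )
        with pytest.warns(UserWarning, match="removed"):
            out = filter_outliers(fm, 99.5)
        assert 17 not in out.values.index
        # percentile oracle: exactly the cells above the cutoff are gone
        cutoff = np.quantile(vals, 0.995)
        expected_removed = set(np.flatnonzero(vals > cutoff))
        assert set(range(1000)) - set(out.values.index) == expected_removed

    def test_pct_100_is_identity(self, rng):
        fm = FeatureMatrix(pd.DataFrame({"a": rng.normal(size=50)}))
        out = filter_outliers(fm, 100)
        pd.testing.assert_frame_equal(out.values, fm.values)

    def test_removal_count_bound(self, rng):
        n, c = 500, 4
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(n, c))))
        with pytest.warns(UserWarning):
            out = filter_outliers(fm, 99.0)
        removed = n - out.n_cells
        assert removed <= int(np.ceil(n * 0.01)) * c


class TestScaleFeatures:
    def test_minmax_example(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        out = scale_features(fm)
        np.testing.assert_allclose(out.values["a"], [0.0, 0.5, 1.0])

    def test_constant_channel_zeroed_with_warning(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]}))
        with pytest.warns(UserWarning, match="constant"):
            out = scale_features(fm)
        assert (out.values["a"] == 0).all()

    def test_minmax_idempotent_on_unit_interval(self, rng):
        fm = FeatureMatrix(pd.DataFrame({"a": np.linspace(0, 1, 11)}))
        once = scale_features(fm)
        twice = scale_features(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_zscore(self, rng):
        fm = FeatureMatrix(pd.DataFrame({"a": rng.normal(3, 2, 100)}))
        out = scale_features(fm, method="zscore")
        assert out.values["a"].mean() == pytest.approx(0, abs=1e-12)
        assert out.values["a"].std(ddof=0) == pytest.approx(1)


class TestPhenograph:
    def test_separated_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        fm, truth = blobs(rng, n_per=100, dim=5, sd=0.02)
        res = cluster_phenograph(fm, k_neighbors=30, seed=0)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_duplicate_rows_share_labels(self, rng):
        fm, _ = blobs(rng, n_per=40, dim=3, sd=0.01)
        dup = pd.concat([fm.values, fm.values.iloc[:10]], ignore_index=True)
        res = cluster_phenograph(FeatureMatrix(dup), k_neighbors=15, seed=0)
        np.testing.assert_array_equal(res.labels[120:], res.labels[:10])

    def test_deterministic_for_fixed_seed(self, rng):
        fm, _ = blobs(rng, n_per=60, dim=4, sd=0.05)
        a = cluster_phenograph(fm, k_neighbors=20, seed=3)
        b = cluster_phenograph(fm, k_neighbors=20, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_row_permutation_invariance_up_to_relabeling(self, rng):
        from sklearn.metrics import adjusted_rand_score

        fm, _ = blobs(rng, n_per=60, dim=4, sd=0.02)
        perm = rng.permutation(fm.n_cells)
        res1 = cluster_phenograph(fm, k_neighbors=20, seed=0)
        res2 = cluster_phenograph(
            FeatureMatrix(fm.values.iloc[perm].reset_index(drop=True)),
            k_neighbors=20,
            seed=0,
        )
        assert adjusted_rand_score(res1.labels[perm], res2.labels) == 1.0

    def test_too_few_cells_errors(self, rng):
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(10, 3))))
        with pytest.raises(ValueError, match="smaller k"):
            cluster_phenograph(fm, k_neighbors=30)


class TestUmap:
    def test_row_count_and_determinism(self, rng):
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(60, 4))))
        a = embed_umap(fm, seed=5)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, embed_umap(fm, seed=5))

    def test_far_blobs_stay_separated(self, rng):
        x = np.vstack(
            [rng.normal(0, 0.01, (50, 4)), rng.normal(5, 0.01, (50, 4))]
        )
        emb = embed_umap(FeatureMatrix(pd.DataFrame(x)), seed=0)
        a, b = emb[:50], emb[50:]
        gap = np.linalg.norm(a.mean(0) - b.mean(0))
        spread = max(
            np.percentile(np.linalg.norm(a - a.mean(0), axis=1), 95),
            np.percentile(np.linalg.norm(b - b.mean(0), axis=1), 95),
        )
        assert gap > spread


class TestClusterHeatmap:
    def test_single_cluster_equals_column_means(self, rng):
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc")))
        res = ClusterResult(
            labels=np.zeros(20, dtype=int), k=1, quality=0.0,
            k_neighbors=5, resolution=1.0, seed=0, cell_ids=np.arange(20),
        )
        heat = cluster_heatmap(fm, res)
        np.testing.assert_allclose(heat.loc[0], fm.values.mean())

    def test_weighted_row_mean_equals_global_mean(self, rng):
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(30, 2))))
        labels = rng.integers(0, 3, 30)
        res = ClusterResult(
            labels=labels, k=3, quality=0.0, k_neighbors=5,
            resolution=1.0, seed=0, cell_ids=np.arange(30),
        )
        heat = cluster_heatmap(fm, res)
        sizes = np.bincount(labels)
        weighted = (heat.to_numpy() * sizes[:, None]).sum(0) / 30
        np.testing.assert_allclose(weighted, fm.values.mean().to_numpy())


class TestProjections:
    def mask(self):
        lab = np.zeros((5, 5), dtype=int)
        lab[0:2, 0:2] = 1
        lab[3:5, 3:5] = 2
        return SegmentationMask(lab)

    def test_cluster_projection_values(self):
        res = ClusterResult(
            labels=np.array([0, 1]), k=2, quality=0.0, k_neighbors=1,
            resolution=1.0, seed=0, cell_ids=np.array([1, 2]),
        )
        overlay = project_clusters(self.mask(), res)
        assert overlay.shape == (5, 5)
        assert set(np.unique(overlay)) == {0, 1, 2}  # bg, cluster0+1, cluster1+1

    def test_amount_projection(self):
        q = pd.DataFrame({"cell_id": [1, 2], amount_col("59Co"): [2.0, 0.5]})
        overlay = project_amounts(self.mask(), q, "59Co")
        assert (overlay[0:2, 0:2] == 2.0).all()
        assert (overlay[3:5, 3:5] == 0.5).all()
        assert overlay[2, 2] == 0.0


def exact_two_sided_p(x, y):
    """Enumerate all label assignments; two-sided p from U's null extremity."""
    pooled = list(x) + list(y)
    n1 = len(x)
    nx = np.array(x, dtype=float)

    def u_stat(a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        gt = (a[:, None] > b[None, :]).sum()
        eq = (a[:, None] == b[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(x, y)
    center = len(x) * len(y) / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(a, b) - center) >= dev - 1e-12:
            count += 1
    return count / total


class TestCompareClusters:
    def quantified(self, groups):
        values = np.concatenate(groups)
        labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        q = pd.DataFrame({amount_col("59Co"): values})
        res = ClusterResult(
            labels=labels, k=len(groups), quality=0.0, k_neighbors=5,
            resolution=1.0, seed=0, cell_ids=np.arange(len(values)),
        )
        return q, res

    def test_disjoint_samples_exact_p(self):
        q, res = self.quantified([[1, 2, 3], [4, 5, 6]])
        out = compare_clusters(q, res, "59Co")
        assert out.loc[0, "u_statistic"] == 0.0
        assert out.loc[0, "p_value"] == pytest.approx(0.1)
        assert out.loc[0, "method"] == "exact"

    def test_identical_samples_p_one(self):
        q, res = self.quantified([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5]])
        # same ranks interleaved -> large p; exact identical values force ties
        q2, res2 = self.quantified([[1, 2, 3], [1, 2, 3]])
        out = compare_clusters(q2, res2, "59Co")
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_u_matches_brute_force_on_random_samples(self, rng):
        for _ in range(5):
            x = rng.integers(0, 20, rng.integers(4, 8)).astype(float)
            y = rng.integers(0, 20, rng.integers(4, 8)).astype(float)
            q, res = self.quantified([x, y])
            out = compare_clusters(q, res, "59Co")
            u_brute = float(
                (x[:, None] > y[None, :]).sum()
                + 0.5 * (x[:, None] == y[None, :]).sum()
            )
            u_scipy = out.loc[0, "u_statistic"]
            assert u_scipy == pytest.approx(u_brute)

    def test_exact_p_matches_enumeration_without_ties(self, rng):
        for _ in range(3):
            pool = rng.permutation(40)[:11].astype(float)  # distinct values
            x, y = pool[:5], pool[5:]
            q, res = self.quantified([x, y])
            out = compare_clusters(q, res, "59Co")
            assert out.loc[0, "p_value"] == pytest.approx(exact_two_sided_p(x, y))

    def test_symmetry_and_bonferroni(self, rng):
        g = [rng.normal(i, 1, 10) for i in range(3)]
        q, res = self.quantified(g)
        out = compare_clusters(q, res, "59Co").set_index(["cluster_a", "cluster_b"])
        p01 = stats.mannwhitneyu(g[0], g[1], alternative="two-sided").pvalue
        p10 = stats.mannwhitneyu(g[1], g[0], alternative="two-sided").pvalue
        assert p01 == pytest.approx(p10)  # symmetric by construction
        assert out.loc[(0, 1), "p_adjusted"] == pytest.approx(
            min(out.loc[(0, 1), "p_value"] * 3, 1.0)
        )

    def test_small_clusters_rejected(self):
        q, res = self.quantified([[1, 2], [3, 4, 5]])
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_clusters(q, res, "59Co")
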