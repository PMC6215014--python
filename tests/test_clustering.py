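"""Two-stage regionalisation: features, pre-clustering, Ward, cuts, sieve."""

import itertools

import numpy as np
import pytest

from dhiregio.clustering import (
    Dendrogram,
    FeatureTable,
    Regionalisation,
    build_feature_table,
    cut_tree,
    kmeans_pp_precluster,
    label_map,
    sieve,
    validity_curve,
    ward_dendrogram,
)
from dhiregio.dhi import DhiLayers


def _features(X):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        data=X,
        pixel_index=np.arange(X.shape[0]),
        grid_shape=(1, X.shape[0]),
        centers=np.zeros(X.shape[1]),
        spreads=np.ones(X.shape[1]),
        outlier_quantile=0.0,
        clip_bounds=np.zeros((2, X.shape[1])),
    )


def _dhi(cum, mn=None, var=None, mask=None):
    cum = np.asarray(cum, dtype=float)
    mn = np.full_like(cum, 0.2) if mn is None else np.asarray(mn, float)
    var = np.full_like(cum, 0.5) if var is None else np.asarray(var, float)
    mask = np.isfinite(cum) if mask is None else mask
    return DhiLayers(cum, mn, var, valid_mask=mask)


class TestFeatureTable:
    def test_zero_cumulative_pixels_excluded(self, rng):
        cum = rng.uniform(1, 30, (4, 4))
        cum[0, 0] = 0.0
        lat = np.linspace(-10, 10, 16).reshape(4, 4)
        ft = build_feature_table(_dhi(cum), lat)
        assert ft.n_pixels == 15
        assert 0 not in ft.pixel_index

    def test_columns_standardised(self, rng):
        cum = rng.uniform(1, 30, (10, 10))
        lat = rng.uniform(-60, 60, (10, 10))
        ft = build_feature_table(_dhi(cum, rng.uniform(0, 1, (10, 10)),
                                      rng.uniform(0, 2, (10, 10))), lat,
                                 outlier_quantile=0.0)
        np.testing.assert_allclose(ft.data.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(ft.data.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_latitude_enters_as_absolute_degrees(self, rng):
        cum = rng.uniform(1, 30, (3, 3))
        lat = np.array([[-30.0, 0.0, 30.0]] * 3)
        ft = build_feature_table(_dhi(cum), lat, outlier_quantile=0.0)
        col = ft.data[:, 3] * ft.spreads[3] + ft.centers[3]
        # |−30| and |+30| coincide after the absolute-value transform
        assert set(np.round(col, 9)) == {0.0, 30.0}
        # the equator pixel maps to the z-score of 0 degrees
        eq = (col == 0.0)
        np.testing.assert_allclose(
            ft.data[eq, 3], (0.0 - ft.centers[3]) / ft.spreads[3]
        )

    def test_winsorisation_applied(self, rng):
        cum = np.concatenate([rng.uniform(5, 10, 98), [1e6, 1e-3]])
        dhi = _dhi(cum.reshape(10, 10))
        ft = build_feature_table(dhi, np.zeros((10, 10)), outlier_quantile=0.05)
        raw_max = ft.data[:, 0].max() * ft.spreads[0] + ft.centers[0]
        assert raw_max < 1e6
        assert (ft.clip_bounds[1, 0] < 1e6)

    def test_all_masked_rejected(self):
        dhi = _dhi(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_feature_table(dhi, np.zeros((2, 2)))


class TestKmeansPrecluster:
    def test_k_equals_points_gives_singletons(self, rng):
        X = rng.normal(size=(12, 3))
        pre = kmeans_pp_precluster(_features(X), k=12, seed=0)
        assert pre.k == 12
        assert sorted(pre.sizes) == [1] * 12
        # within-cluster sum of squares is zero
        wss = sum(
            ((X[pre.assignment == j] - pre.centroids[j]) ** 2).sum()
            for j in range(pre.k)
        )
        assert wss == pytest.approx(0.0, abs=1e-12)

    def test_two_blobs_partition_exactly(self, rng):
        a = rng.normal(0, 0.1, size=(40, 2))
        b = rng.normal(50, 0.1, size=(40, 2))
        X = np.vstack([a, b])
        pre = kmeans_pp_precluster(_features(X), k=2, seed=1)
        # brute-force nearest-centroid partition must coincide with the blobs
        d = ((X[:, None, :] - pre.centroids[None]) ** 2).sum(-1)
        expect = np.argmin(d, axis=1)
        np.testing.assert_array_equal(pre.assignment, expect)
        assert len(set(pre.assignment[:40])) == 1
        assert len(set(pre.assignment[40:])) == 1
        assert pre.assignment[0] != pre.assignment[40]

    def test_determinism(self, rng):
        X = rng.normal(size=(100, 4))
        p1 = kmeans_pp_precluster(_features(X), k=10, seed=7)
        p2 = kmeans_pp_precluster(_features(X), k=10, seed=7)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        np.testing.assert_allclose(p1.centroids, p2.centroids)

    def test_invalid_k_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            kmeans_pp_precluster(_features(X), k=0)
        with pytest.raises(ValueError):
            kmeans_pp_precluster(_features(X), k=6)


class TestWardDendrogram:
    def _three_point_pre(self, positions, sizes=None):
        from dhiregio.clustering import PreClusters

        X = np.asarray(positions, dtype=float)[:, None]
        n = X.shape[0]
        sizes = np.ones(n, dtype=int) if sizes is None else np.asarray(sizes)
        return PreClusters(
            k=n, centroids=X, sizes=sizes,
            assignment=np.repeat(np.arange(n), sizes),
        )

    def test_first_merge_minimises_ward_cost(self):
        # centroids {0, 1, 10}: of the three possible first merges the Ward
        # cost (wA wB/(wA+wB) ||cA−cB||²) is minimal for {0,1}
        pre = self._three_point_pre([0.0, 1.0, 10.0])
        costs = {
            (i, j): 0.5 * (pre.centroids[i, 0] - pre.centroids[j, 0]) ** 2
            for i, j in itertools.combinations(range(3), 2)
        }
        assert min(costs, key=costs.get) == (0, 1)
        dend = ward_dendrogram(pre)
        mapping = cut_tree(dend, 2, method="static")
        assert mapping[0] == mapping[1] != mapping[2]

    def test_merge_heights_non_decreasing(self, rng):
        from dhiregio.clustering import PreClusters

        X = rng.normal(size=(30, 3))
        pre = PreClusters(k=30, centroids=X, sizes=np.ones(30, int),
                          assignment=np.arange(30))
        dend = ward_dendrogram(pre)
        assert np.all(np.diff(dend.linkage[:, 2]) >= -1e-12)

    def test_identical_centroids_merge_at_zero(self):
        pre = self._three_point_pre([3.0, 3.0, 9.0])
        dend = ward_dendrogram(pre)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_single_centroid_rejected(self):
        pre = self._three_point_pre([1.0])
        with pytest.raises(ValueError):
            ward_dendrogram(pre)

    def test_size_weighted_matches_unit_weights_when_sizes_one(self, rng):
        from dhiregio.clustering import PreClusters

        X = rng.normal(size=(12, 2))
        pre = PreClusters(k=12, centroids=X, sizes=np.ones(12, int),
                          assignment=np.arange(12))
        zu = ward_dendrogram(pre, weighting="none").linkage
        zw = ward_dendrogram(pre, weighting="size").linkage
        np.testing.assert_allclose(zu[:, 2], zw[:, 2], rtol=1e-8)
        np.testing.assert_allclose(zu[:, 3], zw[:, 3])

    def test_size_weighting_resists_merging_heavy_clusters(self):
        # two heavy centroids close together merge later than in the
        # unweighted tree relative to light satellites
        pre_u = self._three_point_pre([0.0, 1.0, 2.5])
        pre_w = self._three_point_pre([0.0, 1.0, 2.5], sizes=[100, 100, 1])
        hu = ward_dendrogram(pre_u, "none").linkage[0]
        hw = ward_dendrogram(pre_w, "size").linkage[0]
        assert {int(hu[0]), int(hu[1])} == {0, 1}
        assert {int(hw[0]), int(hw[1])} == {1, 2}


class TestCutTree:
    def _dend(self, positions):
        from dhiregio.clustering import PreClusters

        X = np.asarray(positions, dtype=float)[:, None]
        pre = PreClusters(k=len(positions), centroids=X,
                          sizes=np.ones(len(positions), int),
                          assignment=np.arange(len(positions)))
        return pre, ward_dendrogram(pre)

    def test_k1_and_kn_trivial_cuts(self):
        _, dend = self._dend([0.0, 1.0, 10.0, 11.0])
        assert len(set(cut_tree(dend, 1))) == 1
        assert len(set(cut_tree(dend, 4))) == 4

    def test_static_three_leaf_cut(self):
        _, dend = self._dend([0.0, 1.0, 10.0])
        m = cut_tree(dend, 2, method="static")
        assert m[0] == m[1] != m[2]

    def test_dynamic_cut_reaches_target(self, rng):
        from dhiregio.clustering import PreClusters

        X = np.vstack([rng.normal(c, 0.3, size=(20, 2)) for c in (0, 10, 20, 30)])
        pre = PreClusters(k=80, centroids=X, sizes=np.ones(80, int),
                          assignment=np.arange(80))
        dend = ward_dendrogram(pre)
        for k in (2, 3, 4, 6):
            m = cut_tree(dend, k, method="dynamic")
            assert m.max() + 1 == k

    def test_cut_nesting(self, rng):
        # static cuts at k and k+1 differ by exactly one split
        from dhiregio.clustering import PreClusters

        X = rng.normal(size=(25, 3))
        pre = PreClusters(k=25, centroids=X, sizes=np.ones(25, int),
                          assignment=np.arange(25))
        dend = ward_dendrogram(pre)
        for k in range(2, 24):
            a = cut_tree(dend, k)
            b = cut_tree(dend, k + 1)
            # every cluster of b is contained in a cluster of a, and exactly
            # one cluster of a splits in two
            split = 0
            for c in set(a):
                subs = set(b[a == c])
                assert len(subs) in (1, 2)
                split += len(subs) - 1
            assert split == 1

    def test_out_of_range_k_rejected(self):
        _, dend = self._dend([0.0, 1.0, 10.0])
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 4)


class TestLabelMap:
    def _setup(self, rng):
        X = rng.normal(size=(30, 2))
        ft = _features(X)
        ft.grid_shape = (5, 6)
        pre = kmeans_pp_precluster(ft, k=6, seed=0)
        return ft, pre

    def test_identity_mapping_renumbers_by_area(self, rng):
        ft, pre = self._setup(rng)
        region = label_map(ft, pre, np.arange(pre.k))
        counts = np.bincount(region.labels.ravel())[1:]
        assert np.all(np.diff(counts[counts > 0]) <= 0)  # descending areas
        assert region.labels.min() >= 1  # no masked pixels in this table

    def test_constant_mapping_gives_uniform_raster(self, rng):
        ft, pre = self._setup(rng)
        region = label_map(ft, pre, np.zeros(pre.k, dtype=int))
        assert set(region.labels.ravel()) == {1}

    def test_composition(self, rng):
        # mapping pre -> m1 -> m2 equals applying the composed mapping,
        # up to the area-based renumbering (compare partitions)
        from sklearn.metrics import adjusted_rand_score

        ft, pre = self._setup(rng)
        m1 = np.array([0, 0, 1, 1, 2, 2])[: pre.k]
        m2 = np.array([1, 1, 0])
        direct = label_map(ft, pre, m2[m1])
        first = label_map(ft, pre, m1)
        assert adjusted_rand_score(
            direct.labels.ravel(), m2[m1][pre.assignment]
        ) == pytest.approx(1.0)
        _ = first

    def test_incomplete_mapping_rejected(self, rng):
        ft, pre = self._setup(rng)
        with pytest.raises(ValueError):
            label_map(ft, pre, np.zeros(pre.k - 1, dtype=int))


class TestSieve:
    def _region(self, labels, n=None):
        labels = np.asarray(labels, dtype=np.int32)
        return Regionalisation(labels=labels,
                               n_clusters=int(labels.max()) or 1)

    def test_uniform_raster_unchanged(self):
        r = self._region(np.ones((10, 10), int))
        out = sieve(r, min_pixels=20)
        np.testing.assert_array_equal(out.labels, r.labels)

    def test_isolated_pixel_absorbed(self):
        lab = np.ones((10, 10), int)
        lab[5, 5] = 2
        out = sieve(self._region(lab), min_pixels=20)
        assert out.labels[5, 5] == 1

    def test_component_of_exactly_min_pixels_retained(self):
        lab = np.ones((10, 10), int)
        lab[2:7, 3:7] = 2  # 20 pixels exactly
        out = sieve(self._region(lab), min_pixels=20)
        assert (out.labels == 2).sum() == 20

    def test_masked_pixels_never_touched(self):
        lab = np.ones((8, 8), int)
        lab[0, :] = 0
        lab[4, 4] = 2
        out = sieve(self._region(lab), min_pixels=10)
        np.testing.assert_array_equal(out.labels[0, :], 0)
        assert out.labels[4, 4] == 1

    def test_component_enclosed_by_mask_left_alone(self):
        lab = np.zeros((7, 7), int)
        lab[3, 3] = 2
        out = sieve(self._region(lab), min_pixels=5)
        assert out.labels[3, 3] == 2

    def test_tie_goes_to_lower_label(self):
        # isolated pixel with two equally common neighbour labels
        lab = np.zeros((3, 3), int)
        lab[:, 0] = 3
        lab[:, 2] = 2
        lab[1, 1] = 1
        lab[0, 1] = 0
        lab[2, 1] = 0
        out = sieve(self._region(lab), min_pixels=2, connectivity=4)
        assert out.labels[1, 1] == 2

    def test_idempotence(self, small_world):
        r = self._region(small_world.truth_labels)
        once = sieve(r, min_pixels=20)
        twice = sieve(once, min_pixels=20)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_no_undersized_components_remain(self, small_world):
        from scipy.ndimage import label as cc

        out = sieve(self._region(small_world.comparator_labels), min_pixels=20)
        struct = np.ones((3, 3), bool)
        for val in np.unique(out.labels):
            if val == 0:
                continue
            comp, n = cc(out.labels == val, structure=struct)
            sizes = np.bincount(comp.ravel())[1:]
            assert sizes.min() >= 20 or _enclosed_by_mask(out.labels, comp, sizes)


def _enclosed_by_mask(labels, comp, sizes):
    # small components are acceptable only when fully surrounded by mask
    from scipy.ndimage import binary_dilation

    for c in np.nonzero(sizes < 20)[0] + 1:
        m = comp == c
        border = binary_dilation(m, np.ones((3, 3), bool)) & ~m
        if np.any(labels[border] > 0):
            return False
    return True


class TestValidityCurve:
    def test_separated_blobs_high_silhouette(self, rng):
        from dhiregio.clustering import PreClusters

        X = np.vstack([rng.normal(0, 0.05, (15, 2)), rng.normal(20, 0.05, (15, 2))])
        pre = PreClusters(k=30, centroids=X, sizes=np.ones(30, int),
                          assignment=np.arange(30))
        dend = ward_dendrogram(pre)
        tab = validity_curve(pre, dend, [2, 3])
        assert tab.loc[tab.k == 2, "silhouette"].iloc[0] > 0.9

    def test_wss_non_increasing_and_zero_at_leaves(self, rng):
        from dhiregio.clustering import PreClusters

        X = rng.normal(size=(20, 3))
        pre = PreClusters(k=20, centroids=X, sizes=np.ones(20, int),
                          assignment=np.arange(20))
        dend = ward_dendrogram(pre)
        tab = validity_curve(pre, dend, range(2, 21))
        wss = tab["wss"].to_numpy()
        assert np.all(np.diff(wss) <= 1e-9)
        assert wss[-1] == pytest.approx(0.0, abs=1e-12)

    def test_k_below_two_excluded_with_warning(self, rng):
        from dhiregio.clustering import PreClusters

        X = rng.normal(size=(6, 2))
        pre = PreClusters(k=6, centroids=X, sizes=np.ones(6, int),
                          assignment=np.arange(6))
        dend = ward_dendrogram(pre)
        with pytest.warns(RuntimeWarning):
            tab = validity_curve(pre, dend, [1, 2])
        assert list(tab["k"]) == [2]


class TestEndToEndRecovery:
    def test_pipeline_recovers_archetypes(self, small_world, small_dhi):
        from sklearn.metrics import adjusted_rand_score

        from dhiregio import DhiRegionalization

        res = DhiRegionalization(
            small_dhi, small_world.latitude,
            n_clusters=small_world.config.n_archetypes, k_pre=100,
        ).fit(seed=0)
        ari = adjusted_rand_score(
            small_world.truth_labels.ravel(), res.labels.ravel()
        )
        assert ari >= 0.8

    def test_pipeline_deterministic(self, small_world, small_dhi):
        from dhiregio import DhiRegionalization

        m = DhiRegionalization(small_dhi, small_world.latitude,
                               n_clusters=4, k_pre=60)
        a = m.fit(seed=3)
        b = m.fit(seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
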