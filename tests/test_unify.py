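import numpy as np
import pytest

import splitsort as ss
from splitsort.unify import SubCluster, distance_stats, tukey_quartiles


def make_subcluster(idx, region, rows=None):
    """Minimal SubCluster with a prescribed region, for graph-level tests."""
    region = ss.BoundedRegion(np.asarray(region, dtype=float))
    rows = np.asarray([idx] if rows is None else rows, dtype=int)
    pt = region.bounds.mean(axis=1)[None, :]
    stats = distance_stats(pt)
    return SubCluster(subset_index=0, local_label=idx, member_rows=rows,
                      centroid=pt[0], stats=stats, dist_class="symmetric",
                      of_min=0.0, of_max=0.0,
                      inlier_mask=np.ones(len(rows), dtype=bool), region=region)


def brute_force_components(regions):
    """Oracle: repeated pairwise merging of overlap sets until fixpoint."""
    groups = [{i} for i in range(len(regions))]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(ss.regions_overlap(regions[i], regions[j])
                       for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


class TestDistanceStats:
    def test_two_point_worked_example(self):
        stats = distance_stats(np.array([[0.0, 0.0], [6.0, 8.0]]))
        np.testing.assert_allclose(stats.edm, [5.0, 5.0])
        assert stats.mu == 5.0 and stats.sigma == 0.0
        np.testing.assert_array_equal(stats.z, [0.0, 0.0])

    def test_single_member(self):
        stats = distance_stats(np.array([[1.0, 2.0, 3.0]]))
        assert stats.edm.tolist() == [0.0] and stats.sigma == 0.0

    def test_1d_worked_example(self):
        # members 0,2,4,6,8 -> centroid 4, sorted distances [0,2,2,4,4]
        stats = distance_stats(np.array([[0.0], [2.0], [4.0], [6.0], [8.0]]))
        assert stats.mu == pytest.approx(2.4)
        assert stats.sigma == pytest.approx(np.sqrt(2.24))
        assert (stats.q1, stats.median, stats.q3) == (1.0, 2.0, 4.0)
        assert stats.iqr == 3.0

    def test_z_scores_standardized(self):
        rng = np.random.default_rng(0)
        stats = distance_stats(rng.normal(size=(100, 5)))
        assert stats.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert stats.z.std() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distance_stats(np.empty((0, 3)))


class TestQuartiles:
    @pytest.mark.parametrize("values,expected", [
        ([0, 2, 2, 4, 4], (1.0, 2.0, 4.0)),       # odd n: median excluded from halves
        ([1, 2, 2, 2, 3, 4, 4, 6, 50], (2.0, 3.0, 5.0)),
        ([1, 2, 3, 4], (1.5, 2.5, 3.5)),           # even n: clean halves
        ([7], (7.0, 7.0, 7.0)),
    ])
    def test_tukey_convention(self, values, expected):
        assert tukey_quartiles(np.array(values, dtype=float)) == expected


class TestClassify:
    def test_equidistant_symmetric(self):
        assert ss.classify_distribution(1.5, 3.0, 4.5) == "symmetric"

    def test_skewed(self):
        assert ss.classify_distribution(2.0, 3.0, 5.0) == "skewed"

    def test_zero_iqr_symmetric(self):
        assert ss.classify_distribution(2.0, 2.0, 2.0) == "symmetric"

    def test_strict_rule_recovered_at_zero_tolerance(self):
        assert ss.classify_distribution(1.0, 2.0, 3.1, tol_frac=0.0) == "skewed"
        assert ss.classify_distribution(1.0, 2.0, 3.0, tol_frac=0.0) == "symmetric"

    def test_bad_ordering(self):
        with pytest.raises(ValueError):
            ss.classify_distribution(3.0, 2.0, 1.0)


def stats_from_edm(edm):
    """1-D points at the given distances from 0 reproduce that EDM exactly
    once shifted so the centroid sits at the origin — instead build stats
    directly for fence tests."""
    edm = np.asarray(edm, dtype=float)
    mu = float(edm.mean())
    sigma = float(edm.std())
    z = (edm - mu) / sigma if sigma > 0 else np.zeros_like(edm)
    q1, med, q3 = tukey_quartiles(np.sort(edm))
    return ss.DistanceStats(edm=edm, mu=mu, sigma=sigma, z=z, q1=q1,
                            median=med, q3=q3, iqr=q3 - q1)


class TestOutlierFilter:
    def test_symmetric_worked_example(self):
        of_min, of_max, mask = ss.outlier_filter(stats_from_edm([1, 2, 3, 4, 5]))
        assert of_min == pytest.approx(3 - 2 * np.sqrt(2))
        assert of_max == pytest.approx(3 + 2 * np.sqrt(2))
        assert mask.all()

    def test_skewed_worked_example(self):
        of_min, of_max, mask = ss.outlier_filter(
            stats_from_edm([1, 2, 2, 2, 3, 4, 4, 6, 50]))
        assert (of_min, of_max) == (-2.5, 9.5)
        assert mask.sum() == 8 and not mask[-1]

    def test_degenerate_all_equal(self):
        of_min, of_max, mask = ss.outlier_filter(stats_from_edm([3.0] * 6))
        assert of_min == of_max == 3.0
        assert mask.all()

    def test_matches_direct_formula_on_random_vectors(self):
        """Fence agrees with direct evaluation of the defining formulas."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = rng.integers(3, 40)
            edm = np.abs(rng.normal(2, 1, size=n)) + rng.exponential(1, size=n)
            stats = stats_from_edm(edm)
            of_min, of_max, mask = ss.outlier_filter(stats)
            cls = ss.classify_distribution(stats.q1, stats.median, stats.q3)
            if cls == "symmetric":
                lo, hi = stats.mu - 2 * stats.sigma, stats.mu + 2 * stats.sigma
            else:
                lo, hi = stats.q1 - 1.5 * stats.iqr, stats.q3 + 1.5 * stats.iqr
            assert (of_min, of_max) == (lo, hi)
            expected_mask = (edm >= lo) & (edm <= hi)
            if expected_mask.any():
                np.testing.assert_array_equal(mask, expected_mask)


class TestBoundedRegion:
    def test_minmax_enumeration(self):
        region = ss.bounded_region(np.array([[0.0, 1.0], [2.0, -1.0]]))
        np.testing.assert_array_equal(region.bounds, [[0, 2], [-1, 1]])

    def test_single_point(self):
        region = ss.bounded_region(np.array([[3.0, 4.0]]))
        assert np.all(region.bounds[:, 0] == region.bounds[:, 1])

    def test_mask_excludes_outlier(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [100.0, 100.0]])
        region = ss.bounded_region(pts, np.array([True, True, False]))
        np.testing.assert_array_equal(region.bounds, [[0, 1], [0, 1]])

    def test_filtering_only_shrinks(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pts = rng.normal(size=(rng.integers(2, 30), 3))
            mask = rng.random(len(pts)) < 0.7
            if not mask.any():
                continue
            full = ss.bounded_region(pts)
            sub = ss.bounded_region(pts, mask)
            assert np.all(sub.bounds[:, 0] >= full.bounds[:, 0])
            assert np.all(sub.bounds[:, 1] <= full.bounds[:, 1])


class TestRegionsOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ([[0, 2]], [[2, 3]], True),                    # boundary touch counts
        ([[0, 1], [0, 1]], [[0.5, 2], [3, 4]], False),  # disjoint in second dim
        ([[0, 1], [2, 3]], [[0, 1], [2, 3]], True),     # identical
    ])
    def test_cases(self, a, b, expected):
        ra, rb = ss.BoundedRegion(np.array(a, float)), ss.BoundedRegion(np.array(b, float))
        assert ss.regions_overlap(ra, rb) is expected
        assert ss.regions_overlap(rb, ra) is expected

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ss.regions_overlap(ss.BoundedRegion(np.zeros((1, 2))),
                               ss.BoundedRegion(np.zeros((2, 2))))


class TestBuildSubclusters:
    def test_one_subset_two_clusters(self):
        part = ss.subdivide(3, 3)
        X = np.array([[0.0, 0], [0.1, 0], [5.0, 5]])
        subs = ss.build_subclusters(part, [np.array([0, 0, 1])], X)
        assert len(subs) == 2
        assert subs[0].member_rows.tolist() == [0, 1]
        assert subs[1].member_rows.tolist() == [2]

    def test_two_subsets_two_labels_each(self):
        part = ss.subdivide(8, 4)
        X = np.arange(16, dtype=float).reshape(8, 2)
        labels = [np.array([0, 0, 1, 1]), np.array([0, 1, 1, 0])]
        subs = ss.build_subclusters(part, labels, X)
        assert len(subs) == 4
        # member rows are global indices
        assert subs[2].member_rows.tolist() == [4, 7]

    def test_noise_subset_contributes_nothing(self):
        part = ss.subdivide(4, 2)
        X = np.zeros((4, 2))
        subs = ss.build_subclusters(part, [np.array([-1, -1]), np.array([0, 0])], X)
        assert len(subs) == 1 and subs[0].subset_index == 1

    def test_all_noise_everywhere_raises(self):
        part = ss.subdivide(4, 2)
        with pytest.raises(ValueError, match="no sub-clusters"):
            ss.build_subclusters(part, [np.array([-1, -1])] * 2, np.zeros((4, 2)))


class TestUnify:
    def test_three_disjoint_regions(self):
        subs = [make_subcluster(i, [[10 * i, 10 * i + 1]]) for i in range(3)]
        result = ss.unify(subs, n_total=3)
        assert result.n_global == 3

    def test_transitive_chain_merges(self):
        # A-B overlap, B-C overlap, A-C do not: all three must merge
        subs = [make_subcluster(0, [[0.0, 2.0]]),
                make_subcluster(1, [[1.0, 3.0]]),
                make_subcluster(2, [[2.5, 4.0]])]
        result = ss.unify(subs, n_total=3)
        assert result.n_global == 1
        assert set(result.labels) == {0}

    def test_single_subcluster(self):
        sub = make_subcluster(0, [[0.0, 1.0]], rows=[0, 2])
        result = ss.unify([sub], n_total=4)
        assert result.n_global == 1
        assert result.labels.tolist() == [0, -1, 0, -1]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ss.unify([], n_total=0)

    def test_union_find_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            k = rng.integers(2, 11)
            dim = rng.integers(1, 4)
            lows = rng.uniform(0, 10, size=(k, dim))
            widths = rng.uniform(0.1, 4, size=(k, dim))
            regions = [ss.BoundedRegion(np.stack([lo, lo + w], axis=1))
                       for lo, w in zip(lows, widths)]
            subs = [make_subcluster(i, r.bounds) for i, r in enumerate(regions)]
            result = ss.unify(subs, n_total=k)
            got = {}
            for i, g in enumerate(result.subcluster_to_global):
                got.setdefault(g, set()).add(i)
            assert {frozenset(v) for v in got.values()} == \
                brute_force_components(regions), f"trial {trial}"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        k = 8
        lows = rng.uniform(0, 6, size=(k, 2))
        subs = [make_subcluster(i, np.stack([lo, lo + 1.5], axis=1)) for i, lo in enumerate(lows)]
        base = ss.unify(subs, n_total=k).labels
        for _ in range(5):
            perm = rng.permutation(k)
            labels = ss.unify([subs[i] for i in perm], n_total=k).labels
            np.testing.assert_array_equal(labels, base)

    def test_degenerate_reduction_reproduces_backend_labels(self):
        # single subset, well-separated clusters: unify must not alter labels
        X, y = ss.generate_feature_mixture(k=3, dim=4, separation=15, n_per=30, sd=1, seed=1)
        part = ss.subdivide(len(X), len(X))
        labels = ss.run_backend(X, ss.BackendSpec("kmeans", {"k": 3}, seed=0))
        subs = ss.build_subclusters(part, [labels], X)
        result = ss.unify(subs, n_total=len(X))
        from splitsort.backends import relabel_dense
        np.testing.assert_array_equal(result.labels, relabel_dense(labels))

    def test_every_spike_labeled_outliers_keep_membership(self):
        # an extreme member is excluded from the region but keeps its label
        X = np.vstack([np.random.default_rng(0).normal(0, 0.5, size=(20, 2)),
                       [[30.0, 30.0]],
                       np.random.default_rng(1).normal(100, 0.5, size=(20, 2))])
        part = ss.subdivide(len(X), len(X))
        labels = np.array([0] * 21 + [1] * 20)
        subs = ss.build_subclusters(part, [labels], X)
        assert not subs[0].inlier_mask.all()  # the far point is fenced out
        assert subs[0].region.bounds[0, 1] < 10
        result = ss.unify(subs, n_total=len(X))
        assert (result.labels >= 0).all()
        assert result.labels[20] == result.labels[0]
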