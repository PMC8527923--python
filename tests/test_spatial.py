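"""Nearest-neighbour distances, 1.1-μm histograms, density clusters."""

import numpy as np
import pandas as pd
import pytest

from immunotme import spatial
from immunotme.spatial import PointSet


def make_points(xy, ids=None, label="pop"):
    xy = np.asarray(xy, dtype=float)
    if ids is None:
        ids = np.arange(len(xy))
    return PointSet(cell_ids=np.asarray(ids), xy=xy, label=label)


def brute_force_nn(query, target):
    out = []
    for qi, q in zip(query.cell_ids, query.xy):
        best = np.inf
        for ti, t in zip(target.cell_ids, target.xy):
            if ti == qi:
                continue
            best = min(best, float(np.hypot(*(q - t))))
        out.append(best)
    return np.array(out)


def dbscan_oracle(points, eps, min_pts):
    """Exhaustive O(n^2) region-query DBSCAN: returns (core set, partition).

    The partition is a frozenset of frozensets of cell ids (cluster labels
    are compared only up to relabeling); border points reachable from
    several clusters are assigned to the cluster of their lowest-cell-id
    core neighbour, matching the documented tie-break.
    """
    n = len(points)
    d = np.hypot(
        points.xy[:, 0][:, None] - points.xy[:, 0][None, :],
        points.xy[:, 1][:, None] - points.xy[:, 1][None, :],
    )
    nbrs = [np.where(d[i] <= eps)[0] for i in range(n)]
    core = {i for i in range(n) if len(nbrs[i]) >= min_pts}
    # union-find over core points
    parent = {i: i for i in core}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in core:
        for j in nbrs[i]:
            if j in core:
                parent[find(i)] = find(j)
    clusters: dict[int, set] = {}
    for i in core:
        clusters.setdefault(find(i), set()).add(i)
    for i in range(n):
        if i in core:
            continue
        core_nbs = [j for j in nbrs[i] if j in core]
        if core_nbs:
            best = min(core_nbs, key=lambda j: points.cell_ids[j])
            clusters[find(best)].add(i)
    partition = frozenset(
        frozenset(points.cell_ids[list(members)].tolist())
        for members in clusters.values()
    )
    return {points.cell_ids[i] for i in core}, partition


def cluster_partition(result, points):
    return frozenset(
        frozenset(c.member_ids.tolist()) for c in result.clusters
    )


class TestNearestNeighbor:
    def test_three_four_five_triangle(self):
        q = make_points([(0, 0)])
        t = make_points([(3, 4)], ids=[100])
        assert spatial.nearest_neighbor_distances(q, t)[0] == pytest.approx(5.0)

    def test_self_exclusion(self):
        pts = make_points([(0, 0), (1, 0), (5, 0)])
        d = spatial.nearest_neighbor_distances(pts, pts)
        assert np.all(d > 0)
        assert d[0] == pytest.approx(1.0)
        assert d[2] == pytest.approx(4.0)

    def test_matches_brute_force_oracle(self, rng):
        q = make_points(rng.uniform(0, 100, size=(200, 2)), ids=np.arange(200))
        t = make_points(rng.uniform(0, 100, size=(150, 2)),
                        ids=np.arange(100, 250))  # partial id overlap
        assert np.allclose(
            spatial.nearest_neighbor_distances(q, t), brute_force_nn(q, t)
        )

    def test_empty_target_is_an_error_not_zero(self):
        q = make_points([(0, 0)])
        t = make_points(np.empty((0, 2)), ids=[])
        with pytest.raises(ValueError, match="no target cells"):
            spatial.nearest_neighbor_distances(q, t)

    def test_adding_targets_never_increases_distances(self, rng):
        q = make_points(rng.uniform(0, 50, (40, 2)), ids=np.arange(40))
        t1 = make_points(rng.uniform(0, 50, (20, 2)), ids=np.arange(1000, 1020))
        extra = rng.uniform(0, 50, (20, 2))
        t2 = make_points(np.vstack([t1.xy, extra]), ids=np.arange(1000, 1040))
        d1 = spatial.nearest_neighbor_distances(q, t1)
        d2 = spatial.nearest_neighbor_distances(q, t2)
        assert np.all(d2 <= d1 + 1e-12)


class TestDistanceHistogram:
    def test_small_distances_share_bin_zero(self):
        h = spatial.distance_histogram([0.5, 1.0])
        assert h.counts[0] == 2

    def test_exact_bin_edge_goes_up(self):
        # half-open [k*1.1, (k+1)*1.1) convention: 1.1 falls in bin 1
        h = spatial.distance_histogram([1.1])
        assert h.counts[0] == 0 and h.counts[1] == 1

    def test_counts_conserved(self, rng):
        for _ in range(30):
            d = rng.uniform(0, 80, size=rng.integers(1, 200))
            h = spatial.distance_histogram(d)
            assert h.counts.sum() == len(d)

    def test_empty_input_missing_median(self):
        h = spatial.distance_histogram([])
        assert h.median is None
        assert len(h.counts) == 0

    def test_median_reported(self, rng):
        d = rng.uniform(0, 50, 101)
        assert spatial.distance_histogram(d).median == np.median(d)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            spatial.distance_histogram([-1.0])


class TestDensityClusters:
    def test_constructed_fixture_matches_oracle(self, rng):
        tight = rng.uniform(0, 10, size=(6, 2))
        far = np.array([[500.0, 500.0], [560.0, 500.0]])
        pts = make_points(np.vstack([tight, far]))
        result = spatial.density_clusters(pts, eps=56.42, min_pts=5)
        assert len(result.clusters) == 1
        assert len(result.clusters[0].member_ids) == 6
        assert set(result.noise_ids.tolist()) == {6, 7}
        core, partition = dbscan_oracle(pts, 56.42, 5)
        assert cluster_partition(result, pts) == partition

    def test_below_min_pts_all_noise(self, rng):
        pts = make_points(rng.uniform(0, 5, size=(4, 2)))
        result = spatial.density_clusters(pts, min_pts=5)
        assert not result.clusters
        assert len(result.noise_ids) == 4

    def test_empty_input(self):
        result = spatial.density_clusters(make_points(np.empty((0, 2)), ids=[]))
        assert not result.clusters and len(result.noise_ids) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = make_points(rng.uniform(0, 400, size=(200, 2)))
        result = spatial.density_clusters(pts, eps=30, min_pts=4)
        core, partition = dbscan_oracle(pts, 30, 4)
        got_core = {
            cid for c in result.clusters for cid in c.member_ids
            if len([1 for j in range(len(pts))
                    if np.hypot(*(pts.xy[cid] - pts.xy[j])) <= 30]) >= 4
        }
        assert got_core == core
        assert cluster_partition(result, pts) == partition

    def test_matches_sklearn_core_points(self, rng):
        from sklearn.cluster import DBSCAN

        pts = make_points(rng.uniform(0, 300, size=(250, 2)))
        result = spatial.density_clusters(pts, eps=25, min_pts=4)
        sk = DBSCAN(eps=25, min_samples=4).fit(pts.xy)
        assert set(sk.core_sample_indices_) == {
            i for i in range(len(pts))
            if len([1 for j in range(len(pts))
                    if np.hypot(*(pts.xy[i] - pts.xy[j])) <= 25]) >= 4
        }
        # cluster count agrees (partitions may differ only on border ties)
        assert len(result.clusters) == len(set(sk.labels_) - {-1})

    def test_input_order_invariance(self, rng):
        xy = rng.uniform(0, 200, size=(120, 2))
        ids = np.arange(120)
        base = spatial.density_clusters(make_points(xy, ids), eps=25, min_pts=4)
        base_part = cluster_partition(base, None)
        for _ in range(10):
            perm = rng.permutation(120)
            shuffled = spatial.density_clusters(
                make_points(xy[perm], ids[perm]), eps=25, min_pts=4
            )
            assert cluster_partition(shuffled, None) == base_part

    def test_density_annotation(self):
        # 6 points in a ~10x10 square: hull area 100 um^2 -> 600 per 10^4 um^2
        xy = [(0, 0), (10, 0), (0, 10), (10, 10), (5, 5), (2, 7)]
        result = spatial.density_clusters(make_points(xy), eps=56.42, min_pts=5)
        c = result.clusters[0]
        assert c.hull_area_um2 == pytest.approx(100.0)
        assert c.density_per_10k_um2 == pytest.approx(600.0)
        assert c.high_density


class TestClusterFraction:
    def test_all_in_one_dense_cluster(self, rng):
        pts = make_points(rng.uniform(0, 20, size=(10, 2)))
        clusters = spatial.density_clusters(pts, eps=56.42, min_pts=5)
        assert spatial.cluster_fraction(pts, clusters) == 1.0

    def test_no_clusters_zero(self, rng):
        pts = make_points([(0, 0), (1000, 1000)])
        clusters = spatial.density_clusters(pts, min_pts=5)
        assert spatial.cluster_fraction(pts, clusters) == 0.0

    def test_empty_population_missing(self):
        empty = make_points(np.empty((0, 2)), ids=[])
        clusters = spatial.density_clusters(empty)
        assert spatial.cluster_fraction(empty, clusters) is None


class TestClusterCoOccupancy:
    def test_distant_cells_not_counted(self, rng):
        pts = make_points(rng.uniform(0, 20, size=(8, 2)))
        clusters = spatial.density_clusters(pts, eps=56.42, min_pts=5)
        other = make_points([(500, 500), (600, 600)], ids=[100, 101])
        counts = spatial.cluster_co_occupancy(clusters, pts, other, radius=25)
        assert all(v == 0 for v in counts.values())

    def test_conservation_bound(self, rng):
        pts = make_points(rng.uniform(0, 100, size=(60, 2)))
        clusters = spatial.density_clusters(pts, eps=30, min_pts=4)
        other = make_points(rng.uniform(0, 100, size=(40, 2)),
                            ids=np.arange(1000, 1040))
        counts = spatial.cluster_co_occupancy(clusters, pts, other, radius=20)
        assert sum(counts.values()) <= len(other)

    def test_invalid_radius_rejected(self, rng):
        pts = make_points(rng.uniform(0, 20, size=(8, 2)))
        clusters = spatial.density_clusters(pts)
        with pytest.raises(ValueError):
            spatial.cluster_co_occupancy(clusters, pts, pts, radius=0)


class TestCompareProximity:
    def test_planted_attraction_detected(self, rng):
        targets = make_points(rng.uniform(0, 500, size=(30, 2)),
                              ids=np.arange(1000, 1030))
        near = targets.xy[rng.integers(0, 30, 50)] + rng.normal(0, 3, (50, 2))
        far = rng.uniform(0, 500, size=(50, 2))
        query = make_points(np.vstack([near, far]))
        flags = np.array([True] * 50 + [False] * 50)
        res = spatial.compare_proximity(query, targets, flags)
        assert res.p < 0.01
        assert res.median_difference < 0

    def test_null_flags_well_calibrated(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            query = make_points(rng.uniform(0, 300, (40, 2)))
            targets = make_points(rng.uniform(0, 300, (30, 2)),
                                  ids=np.arange(1000, 1030))
            flags = rng.uniform(size=40) < 0.5
            if flags.all() or not flags.any():
                continue
            ps.append(spatial.compare_proximity(query, targets, flags).p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_split_level_missing(self, rng):
        query = make_points(rng.uniform(0, 100, (10, 2)))
        targets = make_points(rng.uniform(0, 100, (10, 2)), ids=np.arange(100, 110))
        res = spatial.compare_proximity(query, targets, np.ones(10, bool))
        assert res.missing

    def test_split_target_mode(self, rng):
        query = make_points(rng.uniform(0, 100, (20, 2)))
        targets = make_points(rng.uniform(0, 100, (30, 2)), ids=np.arange(100, 130))
        flags = np.arange(30) < 15
        res = spatial.compare_proximity(query, targets, flags, mode="split_target")
        assert 0 <= res.p <= 1


class TestRegionSummaries:
    def test_perfectly_proportional_abundances(self):
        tables = {}
        for i, n_t in enumerate([100, 200, 300, 400]):
            n_m = n_t // 2
            lineages = (["T_cell"] * n_t + ["macrophage"] * n_m
                        + ["tumor"] * (1000 - n_t - n_m))
            tables[f"R{i}"] = pd.DataFrame({"lineage": lineages})
        df, r, p = spatial.region_coinfiltration(tables)
        assert r == pytest.approx(1.0)

    def test_independent_abundances_uncorrelated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tables = {}
            for i in range(50):
                n_t = rng.integers(5, 50)
                n_m = rng.integers(5, 50)
                tables[f"R{i}"] = pd.DataFrame({
                    "lineage": ["T_cell"] * n_t + ["macrophage"] * n_m
                    + ["tumor"] * 2000
                })
            _, r, _ = spatial.region_coinfiltration(tables)
            if abs(r) < 0.3:
                hits += 1
        assert hits >= 18

    def test_two_regions_rejected(self):
        tables = {"a": pd.DataFrame({"lineage": ["T_cell"] * 5}),
                  "b": pd.DataFrame({"lineage": ["macrophage"] * 5})}
        with pytest.raises(ValueError, match="3 regions"):
            spatial.region_coinfiltration(tables)

    def test_high_low_ratio_identity(self):
        ratio = spatial.high_low_ratio([10, 10], [100, 100], ["high", "low"])
        assert ratio == 1.0

    def test_high_low_ratio_planted_double(self):
        ratio = spatial.high_low_ratio([40, 10], [100, 50], ["high", "low"])
        assert ratio == pytest.approx(2.0)

    def test_high_low_ratio_zero_low_is_missing(self):
        assert spatial.high_low_ratio([5, 0], [10, 10], ["high", "low"]) is None

    def test_high_low_ratio_needs_both_levels(self):
        with pytest.raises(ValueError):
            spatial.high_low_ratio([5], [10], ["high"])
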