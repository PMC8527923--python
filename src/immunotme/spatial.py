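"""Spatial statistics on cell centroids within one imaging region.

Nearest-neighbour distance distributions with fixed-width (1.1 μm) binning,
density-based (DBSCAN) clusters of a phenotype of interest annotated with a
cells-per-area criterion, cluster composition, and region-level
co-infiltration summaries.

All distances are centroid-to-centroid Euclidean distances in μm. Points are
always restricted to a single region: distances across regions are
meaningless.

The density criterion for a "high-density" cluster follows the published
convention of >= 5 cells per 10,000 μm². DBSCAN itself takes a radius (eps)
and a neighbour count (min_pts); by default eps is the radius of a
10,000-μm² disc (~56.42 μm) and min_pts = 5, so that a core point realizes
the stated density, and each cluster is additionally annotated with its
convex-hull density and a high_density flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.stats import gaussian_kde

from .stats import ComparisonResult, pearson, wilcoxon_rank_sum

__all__ = [
    "PointSet",
    "Cluster",
    "SpatialClusterSet",
    "DistanceHistogram",
    "nearest_neighbor_distances",
    "distance_histogram",
    "compare_proximity",
    "density_clusters",
    "cluster_fraction",
    "cluster_co_occupancy",
    "region_coinfiltration",
    "high_low_ratio",
]

BIN_WIDTH_UM = 1.1
DENSITY_CRITERION = 5.0      # cells per 10,000 um^2
DEFAULT_EPS_UM = math.sqrt(10_000 / math.pi)   # radius of a 10,000-um^2 disc
DEFAULT_MIN_PTS = 5


@dataclass
class PointSet:
    """Cell centroids of one population in one region."""

    cell_ids: np.ndarray
    xy: np.ndarray          # (n, 2) centroids in um
    label: str = ""
    region_id: str | None = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array of centroids")
        if len(self.cell_ids) != len(self.xy):
            raise ValueError("cell_ids and xy lengths differ")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("centroids must be finite")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @classmethod
    def from_cells(cls, cells: pd.DataFrame, mask=None, label: str = "",
                   region_id=None) -> "PointSet":
        sub = cells if mask is None else cells[mask]
        return cls(
            cell_ids=sub["cell_id"].to_numpy(),
            xy=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            label=label,
            region_id=region_id,
        )


@dataclass
class Cluster:
    cluster_id: int
    member_ids: np.ndarray
    hull_area_um2: float
    density_per_10k_um2: float
    high_density: bool


@dataclass
class SpatialClusterSet:
    clusters: list[Cluster]
    noise_ids: np.ndarray
    eps: float
    min_pts: int
    density_criterion: float
    labels: np.ndarray = field(repr=False, default=None)  # per input point, -1 = noise

    @property
    def high_density_member_ids(self) -> np.ndarray:
        ids = [c.member_ids for c in self.clusters if c.high_density]
        if not ids:
            return np.array([], dtype=object)
        return np.concatenate(ids)


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    median: float | None
    density_x: np.ndarray
    density_y: np.ndarray


def nearest_neighbor_distances(query: PointSet, target: PointSet) -> np.ndarray:
    """Distance from each query cell to its nearest target cell (μm).

    Self-matches (same cell_id present in both sets) are excluded, so a cell
    is never at distance 0 to itself.
    """
    if len(target) == 0:
        raise ValueError(
            f"no target cells ({target.label or 'target'}) in region; "
            "nearest-neighbour distance undefined (not zero)"
        )
    tree = cKDTree(target.xy)
    target_ids = target.cell_ids
    overlap = np.isin(query.cell_ids, target_ids)
    k = min(len(target), 2)
    dists, idx = tree.query(query.xy, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]
    out = np.empty(len(query))
    for i in range(len(query)):
        if overlap[i]:
            # skip the entry that is the query cell itself
            choices = [
                d for d, j in zip(dists[i], idx[i])
                if target_ids[j] != query.cell_ids[i]
            ]
            if not choices:
                raise ValueError(
                    "target set contains only the query cell itself; "
                    "no other-cell distance exists"
                )
            out[i] = choices[0]
        else:
            out[i] = dists[i, 0]
    return out


def distance_histogram(distances, bin_width: float = BIN_WIDTH_UM) -> DistanceHistogram:
    """Histogram of distances in half-open bins [k*w, (k+1)*w).

    Also fits a Gaussian kernel density curve with bandwidth equal to the
    bin width and reports the median. Empty input yields an empty histogram
    with a missing median.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if d.size == 0:
        return DistanceHistogram(
            bin_edges=np.array([0.0]), counts=np.array([], dtype=int),
            median=None, density_x=np.array([]), density_y=np.array([]),
        )
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin; digitize keeps every bin half-open
    which = np.floor(d / bin_width).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    x = np.linspace(0, edges[-1], max(200, n_bins * 4))
    if d.size > 1 and np.std(d) > 0:
        kde = gaussian_kde(d, bw_method=bin_width / np.std(d))
        y = kde(x)
    else:
        y = np.zeros_like(x)
    return DistanceHistogram(
        bin_edges=edges, counts=counts, median=float(np.median(d)),
        density_x=x, density_y=y,
    )


def compare_proximity(
    query: PointSet,
    target: PointSet,
    split_flags: np.ndarray,
    mode: str = "split_query",
) -> ComparisonResult:
    """Compare nearest-target distances of flagged vs unflagged cells.

    ``split_query`` (default): nearest-target distances of flag+ query cells
    vs the remaining query cells, two-sided Wilcoxon rank-sum; the effect is
    median(flag+) - median(rest), so planted attraction gives a negative
    median difference.

    ``split_target``: each query cell's distance to the nearest flag+ target
    vs to the nearest flag- target.
    """
    flags = np.asarray(split_flags, dtype=bool)
    if mode == "split_query":
        if len(flags) != len(query):
            raise ValueError("split_flags must align with the query set")
        if flags.all() or not flags.any():
            return ComparisonResult(
                statistic=np.nan, p=np.nan, n_a=int(flags.sum()),
                n_b=int((~flags).sum()), median_difference=np.nan,
                reason_missing="a split level is empty on the query side",
            )
        d = nearest_neighbor_distances(query, target)
        return wilcoxon_rank_sum(d[flags], d[~flags])
    elif mode == "split_target":
        if len(flags) != len(target):
            raise ValueError("split_flags must align with the target set")
        if flags.all() or not flags.any():
            return ComparisonResult(
                statistic=np.nan, p=np.nan, n_a=int(flags.sum()),
                n_b=int((~flags).sum()), median_difference=np.nan,
                reason_missing="a split level is empty on the target side",
            )
        pos = PointSet(target.cell_ids[flags], target.xy[flags],
                       label=f"{target.label}+", region_id=target.region_id)
        neg = PointSet(target.cell_ids[~flags], target.xy[~flags],
                       label=f"{target.label}-", region_id=target.region_id)
        d_pos = nearest_neighbor_distances(query, pos)
        d_neg = nearest_neighbor_distances(query, neg)
        return wilcoxon_rank_sum(d_pos, d_neg)
    raise ValueError("mode must be 'split_query' or 'split_target'")


def _hull_area(xy: np.ndarray) -> float:
    """Convex-hull area of a 2-D point cloud; 0 for degenerate clouds."""
    pts = np.unique(xy, axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)   # 2-D: volume is the area
    except QhullError:  # collinear
        return 0.0


def density_clusters(
    points: PointSet,
    eps: float = DEFAULT_EPS_UM,
    min_pts: int = DEFAULT_MIN_PTS,
    density_criterion: float = DENSITY_CRITERION,
) -> SpatialClusterSet:
    """Density-based (DBSCAN) clusters of one cell population.

    Core points have >= ``min_pts`` neighbours within ``eps`` (counting
    themselves); clusters are connected components of core points, plus
    border points, each border point assigned to the cluster of its
    lowest-cell-id core neighbour (a deterministic tie-break absent from the
    algorithm's definition). Each cluster is annotated with its convex-hull
    area and density (cells per 10,000 μm²); clusters whose hull is
    degenerate (fewer than 3 distinct points, or collinear) are treated as
    infinitely dense. ``high_density`` marks clusters meeting
    ``density_criterion``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return SpatialClusterSet([], np.array([], dtype=object), eps, min_pts,
                                 density_criterion, labels=labels)
    # order points by cell id so tie-breaks are input-order independent
    id_order = np.argsort(points.cell_ids, kind="stable")
    tree = cKDTree(points.xy)
    neighbors = tree.query_ball_point(points.xy, r=eps)
    core = np.array([len(nb) >= min_pts for nb in neighbors])

    # connected components over core points (flood fill)
    cluster_of_core = np.full(n, -1, dtype=int)
    n_clusters = 0
    for seed in id_order:
        if not core[seed] or cluster_of_core[seed] != -1:
            continue
        stack = [seed]
        cluster_of_core[seed] = n_clusters
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                if core[j] and cluster_of_core[j] == -1:
                    cluster_of_core[j] = n_clusters
                    stack.append(j)
        n_clusters += 1

    labels[core] = cluster_of_core[core]
    # border points: non-core with a core neighbour; lowest-cell-id core wins
    for i in np.where(~core)[0]:
        core_nbs = [j for j in neighbors[i] if core[j]]
        if core_nbs:
            best = min(core_nbs, key=lambda j: (points.cell_ids[j],))
            labels[i] = cluster_of_core[best]

    clusters = []
    for cid in range(n_clusters):
        members = np.where(labels == cid)[0]
        area = _hull_area(points.xy[members])
        density = (len(members) / area * 10_000) if area > 0 else math.inf
        clusters.append(Cluster(
            cluster_id=cid,
            member_ids=points.cell_ids[members],
            hull_area_um2=area,
            density_per_10k_um2=density,
            high_density=bool(density >= density_criterion),
        ))
    noise = points.cell_ids[labels == -1]
    return SpatialClusterSet(clusters, noise, eps, min_pts, density_criterion,
                             labels=labels)


def cluster_fraction(population: PointSet, clusters: SpatialClusterSet) -> float | None:
    """Fraction of a population's cells inside high-density clusters."""
    if len(population) == 0:
        return None
    members = set(clusters.high_density_member_ids.tolist())
    inside = sum(1 for cid in population.cell_ids if cid in members)
    return inside / len(population)


def cluster_co_occupancy(
    clusters: SpatialClusterSet,
    points: PointSet,
    other: PointSet,
    radius: float,
) -> dict[int, int]:
    """Count other-population cells within ``radius`` of each cluster.

    Each other-cell is counted at most once, for the cluster containing its
    nearest member (ties to the lowest cluster_id). ``points`` is the
    PointSet the clusters were computed on.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    counts = {c.cluster_id: 0 for c in clusters.clusters}
    if not clusters.clusters or len(other) == 0:
        return counts
    member_xy, member_cluster = [], []
    for c in sorted(clusters.clusters, key=lambda c: c.cluster_id):
        sel = np.isin(points.cell_ids, c.member_ids)
        member_xy.append(points.xy[sel])
        member_cluster.extend([c.cluster_id] * int(sel.sum()))
    member_xy = np.vstack(member_xy)
    member_cluster = np.asarray(member_cluster)
    tree = cKDTree(member_xy)
    dists, idx = tree.query(other.xy, k=1)
    for d, j in zip(dists, idx):
        if d <= radius:
            # nearest member wins; among equidistant members the lowest
            # cluster_id wins because members are stacked in cluster order
            counts[int(member_cluster[j])] += 1
    return counts


def region_coinfiltration(
    region_tables: dict,
    t_cell_lineage: str = "T_cell",
    macrophage_lineage: str = "macrophage",
) -> tuple[pd.DataFrame, float, float]:
    """Normalized T-cell and macrophage abundances per region, with Pearson r.

    Abundance is the population count over the total cells of the region.
    Regions with zero cells are excluded. Requires at least 3 usable
    regions.
    """
    rows = []
    for rid, cells in region_tables.items():
        total = len(cells)
        if total == 0:
            continue
        rows.append({
            "region_id": rid,
            "t_cells": (cells["lineage"] == t_cell_lineage).sum() / total,
            "macrophages": (cells["lineage"] == macrophage_lineage).sum() / total,
        })
    df = pd.DataFrame(rows)
    if len(df) < 3:
        raise ValueError("co-infiltration correlation requires >= 3 regions")
    r, p = pearson(df["t_cells"], df["macrophages"])
    return df, r, p


def high_low_ratio(counts, totals, labels) -> float | None:
    """Pooled normalized abundance in high- vs low-infiltration regions.

    ``counts`` and ``totals`` are per-region population counts and total
    cell counts; ``labels`` marks each region 'high' or 'low'. The ratio is
    (sum counts_high / sum totals_high) / (sum counts_low / sum totals_low).
    Missing (None) when the low-region pooled abundance is zero.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    labels = np.asarray(labels)
    if not (len(counts) == len(totals) == len(labels)):
        raise ValueError("counts, totals and labels must align")
    hi = labels == "high"
    lo = labels == "low"
    if not hi.any() or not lo.any():
        raise ValueError("need at least one high and one low region")
    num = counts[hi].sum() / totals[hi].sum()
    den = counts[lo].sum() / totals[lo].sum()
    if den == 0:
        return None
    return float(num / den)
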