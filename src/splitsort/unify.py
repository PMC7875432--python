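"""Sub-cluster unification: outlier-filtered bounded regions merged by overlap.

After each data subset is clustered independently, every (subset, label)
pair becomes a sub-cluster. For each sub-cluster the Euclidean distances of
its member feature points to the sub-cluster centroid are computed; the
distance distribution is classified as symmetric or skewed by comparing the
quartile distances to the median, and an outlier fence is applied:

* symmetric — the empirical rule, distances inside mu +/- 2*sigma
  (population sigma, i.e. Z in [-2, 2]);
* skewed — the Tukey fence [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

The per-dimension [min, max] envelope (bounded region) of the surviving
inlier points is then computed, and sub-clusters whose regions overlap in
EVERY feature dimension are merged transitively (union-find over the
pairwise overlap graph) into global clusters. Outliers are excluded only
from region estimation; they keep their sub-cluster's final label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .features import FeatureMatrix
from .partition import Partition

__all__ = [
    "DistanceStats",
    "BoundedRegion",
    "SubCluster",
    "UnificationResult",
    "build_subclusters",
    "distance_stats",
    "tukey_quartiles",
    "classify_distribution",
    "outlier_filter",
    "bounded_region",
    "regions_overlap",
    "unify",
]


@dataclass(frozen=True)
class DistanceStats:
    """Member-to-centroid distance statistics driving the outlier filter."""

    edm: np.ndarray          # member distances to centroid, input order
    mu: float
    sigma: float             # population SD (divide by n)
    z: np.ndarray            # standardized distances; all zero when sigma == 0
    q1: float
    median: float
    q3: float
    iqr: float


@dataclass(frozen=True)
class BoundedRegion:
    """Per-dimension closed [min, max] envelope; shape (m, 2)."""

    bounds: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("bounds must be (m, 2)")
        if np.any(b[:, 0] > b[:, 1]):
            raise ValueError("region min must not exceed max")
        object.__setattr__(self, "bounds", b)

    @property
    def m(self) -> int:
        return self.bounds.shape[0]


@dataclass(frozen=True)
class SubCluster:
    """One cluster from one data subset, with its filter and bounded region."""

    subset_index: int
    local_label: int
    member_rows: np.ndarray      # global row indices
    centroid: np.ndarray
    stats: DistanceStats
    dist_class: str              # symmetric | skewed
    of_min: float
    of_max: float
    inlier_mask: np.ndarray
    region: BoundedRegion

    @property
    def n_members(self) -> int:
        return len(self.member_rows)


@dataclass(frozen=True)
class UnificationResult:
    """Global clustering after merging overlapping sub-clusters."""

    subcluster_to_global: np.ndarray   # global id per sub-cluster
    labels: np.ndarray                 # one label per spike, -1 = in no sub-cluster
    n_global: int


def tukey_quartiles(sorted_values: np.ndarray) -> tuple[float, float, float]:
    """Median-exclusive (Tukey) quartiles of an ascending-sorted vector.

    Q1/Q3 are the medians of the lower/upper halves; for odd n the overall
    median belongs to neither half. A single value is its own three quartiles.
    """
    x = np.asarray(sorted_values, dtype=float)
    n = len(x)
    med = float(np.median(x))
    if n == 1:
        return med, med, med
    half = n // 2
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return q1, med, q3


def distance_stats(member_features: np.ndarray) -> DistanceStats:
    """Centroid-distance statistics for one sub-cluster's member points.

    Each m-dimensional feature row is a single point; its Euclidean distance
    to the centroid (column mean) forms the EDM vector. mu and sigma are the
    EDM mean and population SD; Z scores are (ED - mu)/sigma, all zero when
    sigma is 0. Quartiles use the median-exclusive convention on the sorted
    EDM.
    """
    X = np.atleast_2d(np.asarray(member_features, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("sub-cluster must have at least one member")
    centroid = X.mean(axis=0)
    edm = np.linalg.norm(X - centroid, axis=1)
    mu = float(edm.mean())
    sigma = float(edm.std())  # population: divide by n
    z = (edm - mu) / sigma if sigma > 0 else np.zeros_like(edm)
    q1, med, q3 = tukey_quartiles(np.sort(edm))
    return DistanceStats(edm=edm, mu=mu, sigma=sigma, z=z,
                         q1=q1, median=med, q3=q3, iqr=q3 - q1)


def classify_distribution(q1: float, median: float, q3: float,
                          tol_frac: float = 0.2) -> str:
    """Symmetric iff the quartiles sit (near-)equidistant from the median.

    Exact equality almost never holds for continuous data, so the distances
    are compared with tolerance ``tol_frac * IQR`` (0 recovers the strict
    rule); zero IQR counts as symmetric.
    """
    if not (q1 <= median <= q3):
        raise ValueError("need q1 <= median <= q3")
    iqr = q3 - q1
    if iqr == 0:
        return "symmetric"
    asym = abs((q3 - median) - (median - q1))
    return "symmetric" if asym <= tol_frac * iqr else "skewed"


def outlier_filter(stats: DistanceStats,
                   tol_frac: float = 0.2) -> tuple[float, float, np.ndarray]:
    """Outlier fence over the EDM and the resulting inlier mask.

    Symmetric distance distribution -> empirical rule [mu - 2s, mu + 2s];
    skewed -> [Q1 - 1.5*IQR, Q3 + 1.5*IQR]. If the fence would reject every
    member, all are retained (with a warning) so a bounded region exists.
    """
    dist_class = classify_distribution(stats.q1, stats.median, stats.q3, tol_frac)
    if dist_class == "symmetric":
        of_min = stats.mu - 2.0 * stats.sigma
        of_max = stats.mu + 2.0 * stats.sigma
    else:
        of_min = stats.q1 - 1.5 * stats.iqr
        of_max = stats.q3 + 1.5 * stats.iqr
    mask = (stats.edm >= of_min) & (stats.edm <= of_max)
    if not mask.any():
        warnings.warn("outlier fence rejected every member; retaining all")
        mask = np.ones_like(mask)
    return of_min, of_max, mask


def bounded_region(member_features: np.ndarray,
                   inlier_mask: np.ndarray | None = None) -> BoundedRegion:
    """Per-dimension [min, max] envelope over the inlier member points."""
    X = np.atleast_2d(np.asarray(member_features, dtype=float))
    if inlier_mask is not None:
        mask = np.asarray(inlier_mask, dtype=bool)
        if not mask.any():
            raise ValueError("bounded region needs at least one inlier")
        X = X[mask]
    return BoundedRegion(bounds=np.stack([X.min(axis=0), X.max(axis=0)], axis=1))


def _make_subcluster(subset_index: int, local_label: int, member_rows: np.ndarray,
                     X: np.ndarray, tol_frac: float = 0.2) -> SubCluster:
    feats = X[member_rows]
    stats = distance_stats(feats)
    dist_class = classify_distribution(stats.q1, stats.median, stats.q3, tol_frac)
    of_min, of_max, mask = outlier_filter(stats, tol_frac)
    return SubCluster(
        subset_index=subset_index, local_label=int(local_label),
        member_rows=np.asarray(member_rows, dtype=int),
        centroid=feats.mean(axis=0), stats=stats, dist_class=dist_class,
        of_min=of_min, of_max=of_max, inlier_mask=mask,
        region=bounded_region(feats, mask),
    )


def build_subclusters(partition: Partition, per_subset_labels: Sequence[np.ndarray],
                      features: FeatureMatrix | np.ndarray,
                      tol_frac: float = 0.2) -> list[SubCluster]:
    """One SubCluster per (subset, non-noise local label), in subset order.

    Noise rows (label -1) contribute no sub-cluster. Raises if no subset
    yields any sub-cluster at all.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if len(per_subset_labels) != partition.N:
        raise ValueError("need one label vector per subset")
    out: list[SubCluster] = []
    for si, ((start, end), labels) in enumerate(zip(partition.bounds, per_subset_labels)):
        labels = np.asarray(labels, dtype=int)
        if len(labels) != end - start:
            raise ValueError(f"subset {si}: {len(labels)} labels for {end - start} rows")
        for lab in np.unique(labels):
            if lab == -1:
                continue
            rows = start + np.nonzero(labels == lab)[0]
            out.append(_make_subcluster(si, lab, rows, X, tol_frac))
    if not out:
        raise ValueError("no sub-clusters: every subset labeled all rows as noise")
    return out


def regions_overlap(a: BoundedRegion, b: BoundedRegion) -> bool:
    """True iff the closed boxes intersect in every dimension (touching counts)."""
    if a.m != b.m:
        raise ValueError(f"dimension mismatch: {a.m} vs {b.m}")
    lo = np.maximum(a.bounds[:, 0], b.bounds[:, 0])
    hi = np.minimum(a.bounds[:, 1], b.bounds[:, 1])
    return bool(np.all(lo <= hi))


def unify(subclusters: Sequence[SubCluster], n_total: int) -> UnificationResult:
    """Merge sub-clusters whose bounded regions overlap in all dimensions.

    Connected components of the pairwise overlap graph become global
    clusters; global ids are dense and ordered by each component's smallest
    member row, so the final labeling is independent of sub-cluster order.
    Rows belonging to no sub-cluster (noise) are labeled -1.
    """
    if not subclusters:
        raise ValueError("no sub-clusters to unify")
    k = len(subclusters)
    rows_ij = []
    for i in range(k):
        for j in range(i + 1, k):
            if regions_overlap(subclusters[i].region, subclusters[j].region):
                rows_ij.append((i, j))
    if rows_ij:
        ii, jj = np.array(rows_ij).T
    else:
        ii = jj = np.array([], dtype=int)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(k, k))
    n_comp, comp = connected_components(graph, directed=False)
    # order global ids by the smallest member row in each component
    first_row = np.full(n_comp, np.iinfo(np.int64).max, dtype=np.int64)
    for sc, c in zip(subclusters, comp):
        first_row[c] = min(first_row[c], int(sc.member_rows.min()))
    order = np.argsort(first_row, kind="stable")
    rank = np.empty(n_comp, dtype=int)
    rank[order] = np.arange(n_comp)
    global_ids = rank[comp]
    labels = np.full(n_total, -1, dtype=int)
    for sc, g in zip(subclusters, global_ids):
        labels[sc.member_rows] = g
    return UnificationResult(subcluster_to_global=global_ids, labels=labels,
                             n_global=int(n_comp))
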