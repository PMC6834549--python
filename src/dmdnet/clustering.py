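"""Unsupervised hierarchical clustering of binned mode masks.

Binned modes are thresholded at a z-score ``z_t`` to form binary spatial
masks; pairwise mask distance is ``1 - Pearson correlation`` and masks are
merged by average-linkage (UPGMA) agglomerative clustering.  Flat clusters
are cut either at a cophenetic-distance threshold ``t`` or into a fixed
number of clusters.  Cluster averages, per-cluster frequency statistics,
cross-run matching and reference-map labeling complete the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .binning import BinnedMode

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "ClusterSet",
    "threshold_masks",
    "mask_distances",
    "cluster_modes",
    "cluster_summary",
    "match_clusters",
    "correlate_reference",
]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering knobs: mask threshold, cut criterion, filters.

    ``z_t`` is the z-score at which binned modes are binarized into masks
    (default 2.5).  If ``n_clusters`` is set, the tree is cut into exactly
    that many flat clusters; otherwise it is cut at cophenetic distance
    ``t``.  Clusters smaller than ``min_cluster_size`` are withheld from
    reports but kept in the label vector.
    """

    z_t: float = 2.5
    t: float = 0.955
    c_min: int = 25
    min_cluster_size: int = 5
    n_clusters: int | None = None
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if self.z_t <= 0:
            raise ValueError("z_t must be positive")
        if not 0 < self.t <= 2:
            raise ValueError("t must lie in (0, 2]")
        if self.c_min < 0:
            raise ValueError("c_min must be >= 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ClusterSet:
    """Flat-cluster labels plus the linkage tree they were cut from."""

    labels: np.ndarray
    linkage_matrix: np.ndarray
    params: ClusterParams
    masks: np.ndarray
    mode_windows: np.ndarray | None = None
    cluster_ids: np.ndarray = field(init=False)
    sizes: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.cluster_ids = np.unique(self.labels)
        self.sizes = {int(c): int((self.labels == c).sum()) for c in self.cluster_ids}

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def reported_clusters(self) -> list[int]:
        """Cluster ids meeting the minimum-size requirement, largest first."""
        ok = [c for c, s in self.sizes.items() if s >= self.params.min_cluster_size]
        return sorted(ok, key=lambda c: (-self.sizes[c], c))

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def threshold_masks(binned: list[BinnedMode] | np.ndarray, z_t: float = 2.5) -> np.ndarray:
    """Binary masks: bin is set where the mode's z-score >= z_t."""
    if len(binned) == 0:
        raise ValueError("no binned modes to threshold")
    if isinstance(binned, np.ndarray):
        z = np.atleast_2d(binned)
    else:
        z = np.array([b.zscores for b in binned])
    return z >= z_t


def mask_distances(masks: np.ndarray) -> np.ndarray:
    """Condensed pairwise distance 1 - Pearson(mask_i, mask_j).

    A constant mask has undefined correlation; its distance to every other
    mask is set to the maximum correlation distance (1) with a warning.
    """
    masks = np.asarray(masks, dtype=float)
    n = masks.shape[0]
    if n < 2:
        raise ValueError("need >= 2 masks to cluster")
    sd = masks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant mask(s); distances to them set to 1", int(constant.sum())
        )
    centered = masks - masks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return squareform(dist, checks=False)


def cluster_modes(
    masks: np.ndarray,
    params: ClusterParams,
    mode_windows: np.ndarray | None = None,
) -> ClusterSet:
    """Agglomerate masks (average linkage) and cut flat clusters.

    ``mode_windows`` optionally records the source window of each mask so
    that cluster dynamics can be reconstructed later.  Deterministic:
    SciPy's linkage resolves ties by a fixed merge order.
    """
    masks = np.asarray(masks)
    condensed = mask_distances(masks)
    Z = linkage(condensed, method=params.linkage_method)
    if params.n_clusters is not None:
        labels = fcluster(Z, t=params.n_clusters, criterion="maxclust")
    else:
        labels = fcluster(Z, t=params.t, criterion="distance")
    return ClusterSet(
        labels=np.asarray(labels, dtype=int),
        linkage_matrix=Z,
        params=params,
        masks=masks,
        mode_windows=None if mode_windows is None else np.asarray(mode_windows, dtype=int),
    )


def cluster_summary(
    cluster_set: ClusterSet,
    binned: list[BinnedMode],
    full_magnitudes: np.ndarray | None = None,
) -> dict[int, dict]:
    """Per-cluster average mode and frequency statistics (Hz).

    Returns, for every cluster id, the mean binned magnitude over members,
    optionally the full-resolution average, and the mean and population
    standard deviation of member mode frequencies.
    """
    if len(binned) != len(cluster_set.labels):
        raise ValueError("binned modes and labels are inconsistent")
    values = np.array([b.values for b in binned])
    freqs = np.array([b.freq_hz for b in binned])
    out: dict[int, dict] = {}
    for c in cluster_set.cluster_ids:
        idx = cluster_set.members(int(c))
        entry = {
            "size": len(idx),
            "average": values[idx].mean(axis=0),
            "freq_mean_hz": float(np.nanmean(freqs[idx])) if len(idx) else np.nan,
            "freq_std_hz": float(np.nanstd(freqs[idx])) if len(idx) else np.nan,
        }
        if full_magnitudes is not None:
            entry["average_full"] = full_magnitudes[idx].mean(axis=0)
        out[int(c)] = entry
    return out


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_clusters(
    average_sets: list[dict[int, np.ndarray]],
    method: str = "greedy",
    top_k: int | None = None,
) -> list[dict]:
    """One-to-one matching of cluster averages across independent runs.

    The first set anchors the matching; every other set is matched to it
    one-to-one, either greedily by descending pairwise correlation
    (default) or optimally (Hungarian assignment on negative correlation).
    Returns one record per matched tuple, sorted by descending minimum
    within-tuple correlation; ``top_k`` truncates the list (e.g. the six
    most consistent clusters across scans).
    """
    if len(average_sets) < 2:
        raise ValueError("need >= 2 cluster sets to match")
    anchor_ids = sorted(average_sets[0])
    tuples: list[list[int]] = [[cid] for cid in anchor_ids]
    for other in average_sets[1:]:
        other_ids = sorted(other)
        corr = np.array(
            [
                [_corr(average_sets[0][a], other[b]) for b in other_ids]
                for a in anchor_ids
            ]
        )
        if method == "hungarian":
            rows, cols = linear_sum_assignment(-corr)
            assign = dict(zip(rows.tolist(), cols.tolist()))
        elif method == "greedy":
            assign = {}
            used_r: set[int] = set()
            used_c: set[int] = set()
            order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
            for ri, ci in order:
                if ri in used_r or ci in used_c:
                    continue
                assign[int(ri)] = int(ci)
                used_r.add(int(ri))
                used_c.add(int(ci))
                if len(assign) == min(corr.shape):
                    break
        else:
            raise ValueError(f"unknown matching method {method!r}")
        for ti, tup in enumerate(tuples):
            tup.append(other_ids[assign[ti]] if ti in assign else -1)

    records = []
    for tup in tuples:
        if -1 in tup:
            continue
        avgs = [average_sets[si][cid] for si, cid in enumerate(tup)]
        pair_corrs = [
            _corr(avgs[i], avgs[j])
            for i in range(len(avgs))
            for j in range(i + 1, len(avgs))
        ]
        records.append(
            {"clusters": tuple(tup), "min_corr": min(pair_corrs), "corrs": pair_corrs}
        )
    records.sort(key=lambda r: -r["min_corr"])
    return records[:top_k] if top_k is not None else records


def correlate_reference(
    mode_map: np.ndarray,
    references: dict[str, np.ndarray],
    z_threshold: float | None = None,
) -> dict[str, float]:
    """Pearson correlation of a (cluster-average) map with labeled references.

    With ``z_threshold`` set, both the map and each reference are z-scored
    and binarized at that threshold before correlating (mask overlap,
    z = 2 in the standard comparison); otherwise raw values are correlated.
    """
    mode_map = np.asarray(mode_map, dtype=float).ravel()

    def prep(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).ravel()
        if v.shape != mode_map.shape:
            raise ValueError("reference map shape does not match the mode map")
        if z_threshold is None:
            return v
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        return (z >= z_threshold).astype(float)

    target = prep(mode_map)
    return {name: _corr(target, prep(ref)) for name, ref in references.items()}
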