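"""Cluster dynamics: activation rasters, occupancy, transfer, transitions.

A cluster's time course follows directly from windowing: it is active in
a window iff one of its member modes was extracted there.  From the binary
cluster x window raster follow the occupancy matrix ``O`` (windows where
two clusters co-occur), the lagged transfer matrix ``T`` (probability that
cluster j is active a fixed lag after cluster i), per-timepoint traces
(union of the covering windows, which smooths dynamics over the window
length), maximum-likelihood Markov transition estimates for the synthetic
three-state benchmark, and across-scan occupancy reproducibility.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationRaster",
    "OccupancyMatrix",
    "TransferMatrix",
    "build_raster",
    "occupancy",
    "transfer",
    "timepoint_traces",
    "traces_to_labels",
    "estimate_transitions",
    "reproducibility",
]


@dataclass
class ActivationRaster:
    """Binary clusters x windows activity with the windowing geometry."""

    active: np.ndarray
    cluster_ids: np.ndarray
    window_starts: np.ndarray
    T: int
    dT: int
    dt: float

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.ndim != 2:
            raise ValueError("raster must be 2-D (clusters x windows)")
        if self.active.shape[1] != len(self.window_starts):
            raise ValueError("raster width must equal the number of windows")

    @property
    def n_clusters(self) -> int:
        return self.active.shape[0]

    @property
    def n_windows(self) -> int:
        return self.active.shape[1]


@dataclass
class OccupancyMatrix:
    """Symmetric window co-occurrence counts; diagonal = total activity."""

    O: np.ndarray
    cluster_ids: np.ndarray


@dataclass
class TransferMatrix:
    """Lagged conditional activation probabilities (not row-stochastic)."""

    T_mat: np.ndarray
    cluster_ids: np.ndarray
    lag_seconds: float
    lag_windows: int
    undefined: np.ndarray  # rows with no valid source windows


def build_raster(cluster_set, mode_set_or_n_windows, cluster_ids=None) -> ActivationRaster:
    """Binary activation per cluster per window from mode membership.

    ``cluster_set`` must carry ``mode_windows`` (the source window of each
    clustered mode).  The second argument is the ModeSet the modes came
    from (for the windowing geometry).
    """
    if cluster_set.mode_windows is None:
        raise ValueError("cluster_set has no mode_windows provenance")
    ms = mode_set_or_n_windows
    window_starts = np.asarray(ms.window_starts)
    T, dT, dt = ms.spec.T, ms.spec.dT, ms.dt
    n_windows = len(window_starts)

    if cluster_ids is None:
        cluster_ids = cluster_set.cluster_ids
    cluster_ids = np.asarray(cluster_ids)
    active = np.zeros((len(cluster_ids), n_windows), dtype=bool)
    for row, cid in enumerate(cluster_ids):
        member_windows = cluster_set.mode_windows[cluster_set.labels == cid]
        active[row, member_windows] = True
    return ActivationRaster(active, cluster_ids, window_starts, T, dT, dt)


def occupancy(raster: ActivationRaster) -> OccupancyMatrix:
    """O_ij = number of windows where clusters i and j are both active."""
    A = raster.active.astype(np.int64)
    return OccupancyMatrix(O=A @ A.T, cluster_ids=raster.cluster_ids)


def transfer(raster: ActivationRaster, lag_seconds: float = 30.0) -> TransferMatrix:
    """T_ij = P(cluster j active at w + lag | cluster i active at w).

    The lag in seconds is rounded to the nearest integer number of window
    steps (``lag_windows = round(lag_seconds / (dT * dt))``).  Conditioning
    is on cluster i being active, regardless of what else is active.  Rows
    whose cluster is never active in a window with a valid lagged partner
    are undefined (NaN) and flagged.
    """
    lag_windows = int(round(lag_seconds / (raster.dT * raster.dt)))
    A = raster.active
    n_w = raster.n_windows
    if lag_windows < 0 or lag_windows >= n_w:
        raise ValueError(
            f"lag of {lag_windows} window steps is outside the scan "
            f"({n_w} windows)"
        )
    src = A[:, : n_w - lag_windows] if lag_windows else A
    dst = A[:, lag_windows:] if lag_windows else A
    denom = src.sum(axis=1).astype(float)
    num = src.astype(np.int64) @ dst.T.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        T_mat = num / denom[:, None]
    undefined = denom == 0
    if undefined.any():
        logger.warning("%d cluster(s) have undefined transfer rows", undefined.sum())
        T_mat[undefined, :] = np.nan
    return TransferMatrix(T_mat, raster.cluster_ids, lag_seconds, lag_windows, undefined)


def timepoint_traces(raster: ActivationRaster, n_frames: int | None = None) -> np.ndarray:
    """Per-timepoint activity: t is active iff any covering window is.

    A window covers the half-open frame interval [start, start + T); the
    union over active windows smooths the trace over the window length.
    """
    if n_frames is None:
        n_frames = int(raster.window_starts[-1]) + raster.T
    traces = np.zeros((raster.n_clusters, n_frames), dtype=bool)
    for c in range(raster.n_clusters):
        for w in np.flatnonzero(raster.active[c]):
            start = int(raster.window_starts[w])
            traces[c, start : min(start + raster.T, n_frames)] = True
    return traces


def traces_to_labels(cat_trace: np.ndarray, chicken_trace: np.ndarray) -> np.ndarray:
    """Reduce two binary traces to the 3-state scheme of the benchmark.

    0 = cat only, 1 = chicken only, 2 = both; timepoints where neither is
    active get label -1 (excluded from transition estimation).
    """
    cat = np.asarray(cat_trace, dtype=bool)
    chk = np.asarray(chicken_trace, dtype=bool)
    labels = np.full(cat.shape, -1, dtype=int)
    labels[cat & ~chk] = 0
    labels[~cat & chk] = 1
    labels[cat & chk] = 2
    return labels


def estimate_transitions(labels: np.ndarray, n_states: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood per-step transition probabilities from labels.

    Counts transitions over consecutive timepoint pairs where both labels
    are valid (in ``[0, n_states)``); rows for states never departed from
    are NaN (missing, not zero).  Returns (P_hat, counts).
    """
    labels = np.asarray(labels, dtype=int)
    a, b = labels[:-1], labels[1:]
    valid = (a >= 0) & (a < n_states) & (b >= 0) & (b < n_states)
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(counts, (a[valid], b[valid]), 1)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P_hat = counts / totals[:, None]
    P_hat[totals == 0, :] = np.nan
    return P_hat, counts


def reproducibility(occupancies: np.ndarray) -> pd.DataFrame:
    """Across-run rank correlation of per-subject cluster occupancies.

    ``occupancies`` has shape (n_clusters, n_subjects, n_runs): for each
    cluster, how many of its member modes each subject contributed in each
    run.  For every cluster, Spearman's rho and p are computed between all
    run pairs; the reported statistic is the median rho across pairs with
    the p-value of the pair attaining it (lower-middle pair for an even
    pair count).  Requires >= 3 subjects and >= 2 runs.
    """
    occ = np.asarray(occupancies, dtype=float)
    if occ.ndim != 3:
        raise ValueError("occupancies must be (clusters, subjects, runs)")
    n_clusters, n_subjects, n_runs = occ.shape
    if n_subjects < 3 or n_runs < 2:
        raise ValueError("need >= 3 subjects and >= 2 runs")
    rows = []
    for c in range(n_clusters):
        pair_stats = []
        for i, j in itertools.combinations(range(n_runs), 2):
            rho, p = stats.spearmanr(occ[c, :, i], occ[c, :, j])
            pair_stats.append((float(rho), float(p), i, j))
        rhos = np.array([s[0] for s in pair_stats])
        order = np.argsort(rhos, kind="stable")
        median_idx = order[(len(order) - 1) // 2]  # lower-middle for even counts
        rho_med, p_med, ri, rj = pair_stats[median_idx]
        rows.append(
            {
                "cluster": c,
                "median_rho": rho_med,
                "p_value": p_med,
                "median_pair": (ri, rj),
                "n_pairs": len(pair_stats),
            }
        )
    return pd.DataFrame(rows)
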