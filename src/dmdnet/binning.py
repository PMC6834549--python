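"""Coarse spatial binning of mode magnitudes and a continuity heuristic.

Modes are reduced to a fixed 2-D bin grid (default 40 bins per axis per
location group) before clustering: averaging within bins suppresses pixel
noise while preserving large-scale structure.  A cheap continuity score
``c`` -- the number of high-z bins that have a high-z neighbor -- filters
out modes with no coherent spatial structure before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinGrid",
    "BinnedMode",
    "build_grid",
    "bin_mode",
    "bin_modes",
    "continuity_score",
    "filter_modes",
]


@dataclass
class BinGrid:
    """Mapping from locations to occupied bins of a per-group 2-D grid.

    ``bin_of_location`` maps every location to an index into the occupied
    bins; ``bin_coords`` gives each occupied bin's (group, iy, ix) grid
    cell, and ``counts`` its population.
    """

    bin_of_location: np.ndarray
    bin_coords: np.ndarray
    counts: np.ndarray
    bins_per_axis: int
    n_groups: int

    def __post_init__(self) -> None:
        self._adjacency_cache: dict[int, np.ndarray] = {}

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_locations(self) -> int:
        return len(self.bin_of_location)

    def neighbor_pairs(self, connectivity: int = 8) -> np.ndarray:
        """Boolean adjacency between occupied bins (same group, grid-adjacent).

        Cached per connectivity; the grid is immutable after construction.
        """
        if connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if connectivity in self._adjacency_cache:
            return self._adjacency_cache[connectivity]
        g = self.bin_coords
        same_group = g[:, 0][:, None] == g[:, 0][None, :]
        dy = np.abs(g[:, 1][:, None] - g[:, 1][None, :])
        dx = np.abs(g[:, 2][:, None] - g[:, 2][None, :])
        if connectivity == 8:
            adj = (dy <= 1) & (dx <= 1)
        else:
            adj = dy + dx <= 1
        adj &= same_group
        np.fill_diagonal(adj, False)
        self._adjacency_cache[connectivity] = adj
        return adj


@dataclass
class BinnedMode:
    """Per-bin mean magnitude of one mode, with z-scores across bins."""

    values: np.ndarray
    zscores: np.ndarray
    grid: BinGrid
    window_index: int = -1
    freq_hz: float = np.nan
    source_index: int = -1

    def continuity(self, z_cut: float = 2.0, connectivity: int = 8) -> int:
        return continuity_score(self, z_cut=z_cut, connectivity=connectivity)


def build_grid(
    coords: np.ndarray,
    groups: np.ndarray | None = None,
    bins_per_axis: int = 40,
    projection: tuple[int, int] | None = None,
) -> BinGrid:
    """Partition locations into a per-group 2-D bin grid.

    Per group, uniform bin edges span the [min, max] of the projected
    coordinates in each of the two axes; empty bins are dropped.  3-D
    coordinates are projected onto the plane given by ``projection``
    (default axes (1, 2), i.e. the sagittal plane for x/y/z brain
    coordinates); 2-D coordinates are used as-is.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] not in (2, 3):
        raise ValueError("coords must be (n, 2) or (n, 3)")
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    if bins_per_axis < 1:
        raise ValueError("bins_per_axis must be >= 1")
    n = coords.shape[0]
    if coords.shape[1] == 3:
        proj = projection if projection is not None else (1, 2)
        coords = coords[:, list(proj)]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups, dtype=int)
    if groups.shape != (n,):
        raise ValueError("groups must be a label per location")

    group_ids = np.unique(groups)
    cell = np.empty((n, 3), dtype=int)  # (group, iy, ix) per location
    for gi, g in enumerate(group_ids):
        sel = groups == g
        if not sel.any():
            continue
        sub = coords[sel]
        idx = np.empty((sel.sum(), 2), dtype=int)
        for axis in range(2):
            lo, hi = sub[:, axis].min(), sub[:, axis].max()
            span = hi - lo
            if span == 0:
                idx[:, axis] = 0
            else:
                idx[:, axis] = np.minimum(
                    ((sub[:, axis] - lo) / span * bins_per_axis).astype(int),
                    bins_per_axis - 1,
                )
        cell[sel, 0] = gi
        cell[sel, 1:] = idx

    occupied, bin_of_loc, counts = np.unique(
        cell, axis=0, return_inverse=True, return_counts=True
    )
    return BinGrid(
        bin_of_location=bin_of_loc.astype(int),
        bin_coords=occupied,
        counts=counts,
        bins_per_axis=bins_per_axis,
        n_groups=len(group_ids),
    )


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def bin_mode(
    magnitude: np.ndarray,
    grid: BinGrid,
    *,
    window_index: int = -1,
    freq_hz: float = np.nan,
    source_index: int = -1,
) -> BinnedMode:
    """Average a mode's magnitude within each occupied bin and z-score it."""
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.shape != (grid.n_locations,):
        raise ValueError(
            f"mode length {magnitude.shape} does not match grid locations "
            f"({grid.n_locations})"
        )
    sums = np.bincount(grid.bin_of_location, weights=magnitude, minlength=grid.n_bins)
    values = sums / grid.counts
    return BinnedMode(
        values=values,
        zscores=_zscore(values),
        grid=grid,
        window_index=window_index,
        freq_hz=freq_hz,
        source_index=source_index,
    )


def bin_modes(mode_set, grid: BinGrid) -> list[BinnedMode]:
    """Bin every mode of a ModeSet (or a raw magnitude array)."""
    if hasattr(mode_set, "modes"):
        return [
            bin_mode(
                m.magnitude,
                grid,
                window_index=m.window_index,
                freq_hz=m.freq_hz,
                source_index=i,
            )
            for i, m in enumerate(mode_set.modes)
        ]
    mags = np.atleast_2d(np.asarray(mode_set, dtype=float))
    return [bin_mode(row, grid, source_index=i) for i, row in enumerate(mags)]


def continuity_score(
    binned: BinnedMode, z_cut: float = 2.0, connectivity: int = 8
) -> int:
    """Count high-z bins (z >= z_cut) that have a high-z grid neighbor.

    Neighbors are grid-adjacent occupied bins within the same group
    (8-connectivity by default).  Ties at exactly ``z_cut`` count as high.
    """
    high = binned.zscores >= z_cut
    if high.sum() < 2:
        return 0
    adj = binned.grid.neighbor_pairs(connectivity)
    has_high_neighbor = (adj[high][:, high]).any(axis=1)
    return int(has_high_neighbor.sum())


def filter_modes(
    binned: list[BinnedMode],
    c_min: int,
    *,
    z_cut: float = 2.0,
    connectivity: int = 8,
) -> list[BinnedMode]:
    """Keep modes with continuity >= c_min, preserving order."""
    return [
        b for b in binned if continuity_score(b, z_cut, connectivity) >= c_min
    ]
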