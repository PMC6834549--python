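"""Comparison procedures: windowed spatial ICA and supervised reconstruction.

Windowed spatial ICA applies FastICA to the same sliding windows as the
DMD pipeline, estimating ``r`` statistically independent spatial source
maps per window (``X^T = A S^T``); sources carry no temporal eigenvalue.

The supervised top-k reconstruction scores how well a set of windowed
modes can reproduce a known reference pattern: take absolute values,
order modes by |correlation| with the reference, and average the first k
modes for the k that maximizes the average's correlation.  Because it
peeks at the reference, it upper-bounds what any unsupervised clustering
of the same mode set could return, giving a fair head-to-head comparison
of the DMD and ICA mode sets themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .dmd import DataMatrix, ModeSet, WindowSpec, run_windowed_dmd, window_indices

logger = logging.getLogger(__name__)

__all__ = [
    "ICAMode",
    "ICAModeSet",
    "ReconstructionResult",
    "windowed_ica",
    "supervised_reconstruction",
    "compare_methods",
]


@dataclass
class ICAMode:
    """One spatial ICA source from one window (no temporal eigenvalue)."""

    values: np.ndarray
    window_index: int
    window_start: int
    scan_id: str = ""
    converged: bool = True

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class ICAModeSet:
    """Windowed ICA sources pooled over a scan (mirrors ModeSet)."""

    modes: list[ICAMode]
    window_starts: np.ndarray
    spec: WindowSpec
    dt: float
    scan_id: str = ""
    failed_windows: list[int] | None = None

    def __len__(self) -> int:
        return len(self.modes)

    def magnitudes(self) -> np.ndarray:
        return np.array([m.magnitude for m in self.modes])

    def window_index(self) -> np.ndarray:
        return np.array([m.window_index for m in self.modes], dtype=int)


@dataclass
class ReconstructionResult:
    """Best top-k averaged mode against one reference."""

    averaged_mode: np.ndarray
    k: int
    correlation: float
    method: str
    correlations_by_k: np.ndarray | None = None


def windowed_ica(
    data: DataMatrix,
    spec: WindowSpec,
    seed: int = 0,
    *,
    max_retries: int = 3,
    max_iter: int = 200,
) -> ICAModeSet:
    """FastICA spatial sources in every sliding window.

    Uses the same windowing as :func:`run_windowed_dmd` with ``spec.r``
    sources per window.  Each window gets a seed derived from ``seed`` so
    the whole run is reproducible; a window that fails to converge is
    retried with fresh derived seeds up to ``max_retries`` times and then
    flagged (its last estimate is kept, marked unconverged).
    """
    spec.validate_for(data)
    starts = window_indices(data.n_frames, spec.T, spec.dT)
    base = np.random.SeedSequence(seed)
    window_seeds = [
        s.generate_state(max_retries + 1) % (2**31) for s in base.spawn(len(starts))
    ]
    modes: list[ICAMode] = []
    failed: list[int] = []
    for w_idx, start in enumerate(starts):
        window = data.values[:, start : start + spec.T]
        sources = None
        converged = False
        for attempt in range(max_retries + 1):
            ica = FastICA(
                n_components=spec.r,
                random_state=int(window_seeds[w_idx][attempt]),
                max_iter=max_iter,
                whiten="unit-variance",
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                sources = ica.fit_transform(window)
            converged = not any(
                issubclass(c.category, ConvergenceWarning) for c in caught
            )
            if converged:
                break
        if not converged:
            failed.append(w_idx)
            logger.warning("ICA did not converge in window %d; flagged", w_idx)
        for j in range(sources.shape[1]):
            modes.append(
                ICAMode(
                    values=sources[:, j],
                    window_index=w_idx,
                    window_start=int(start),
                    scan_id=data.scan_id,
                    converged=converged,
                )
            )
    return ICAModeSet(modes, starts, spec, data.dt, data.scan_id, failed)


def supervised_reconstruction(
    mode_set: ModeSet | ICAModeSet | np.ndarray,
    reference: np.ndarray,
    method: str = "",
) -> ReconstructionResult:
    """Best average of the top-k |modes| most correlated with a reference.

    Exhaustively scans k = 1..N; on ties the smallest k wins.  The
    reference must have nonzero variance.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.std() == 0:
        raise ValueError("reference map has zero variance")
    if isinstance(mode_set, np.ndarray):
        mags = np.abs(np.atleast_2d(mode_set))
    else:
        mags = mode_set.magnitudes()
        method = method or (
            "dmd" if isinstance(mode_set, ModeSet) else "ica"
        )
    if mags.shape[0] == 0:
        raise ValueError("empty mode set")

    ref_c = reference - reference.mean()
    ref_n = ref_c / np.linalg.norm(ref_c)

    def corr_rows(rows: np.ndarray) -> np.ndarray:
        centered = rows - rows.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        return (centered / safe[:, None]) @ ref_n

    order = np.argsort(-np.abs(corr_rows(mags)), kind="stable")
    cum = np.cumsum(mags[order], axis=0) / np.arange(1, len(order) + 1)[:, None]
    corrs_by_k = corr_rows(cum)
    best = int(np.argmax(corrs_by_k))  # first maximum -> smallest k on ties
    return ReconstructionResult(
        averaged_mode=cum[best],
        k=best + 1,
        correlation=float(corrs_by_k[best]),
        method=method,
        correlations_by_k=corrs_by_k,
    )


def compare_methods(
    data: DataMatrix,
    spec: WindowSpec,
    references: dict[str, np.ndarray],
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed DMD vs windowed ICA under identical windowing.

    Runs both mode extractors on the same windows and applies the
    supervised reconstruction against each reference; one row per
    (method, reference) with the best correlation and its k.
    """
    dmd_set = run_windowed_dmd(data, spec)
    ica_set = windowed_ica(data, spec, seed=seed)
    rows = []
    for method, mode_set in [("dmd", dmd_set), ("ica", ica_set)]:
        for name, ref in references.items():
            rec = supervised_reconstruction(mode_set, ref, method=method)
            rows.append(
                {
                    "method": method,
                    "reference": name,
                    "correlation": rec.correlation,
                    "k": rec.k,
                }
            )
    return pd.DataFrame(rows)
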