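"""Exact dynamic mode decomposition (DMD) on short sliding windows.

DMD approximates the dynamics of a data matrix ``X`` by the best-fit linear
map ``A`` with ``X' = A X``, where ``X'`` is ``X`` advanced by one frame.
Rather than forming the (space x space) operator directly, the algorithm
projects onto the leading ``r`` singular vectors of ``X`` and
eigendecomposes the reduced operator; each eigenvector lifts back to a
complex spatial mode whose eigenvalue encodes an oscillation frequency and
an exponential growth/decay rate.  Applied within short sliding windows,
this yields time-resolved spatial modes: the basis of the group/subject
mode-clustering pipeline implemented by the rest of this package.

The reduced operator is rescaled by ``diag(S)**(+-1/2)`` before the
eigendecomposition so that modes are weighted by how strongly they are
present in the data (the convention of the neural-recordings DMD
literature).  Oscillations in real data appear as complex-conjugate
eigenvalue pairs whose modes share the same elementwise magnitude; only the
magnitude ``|phi|`` is used downstream for spatial comparisons.

A real *standing* oscillation (a fixed spatial pattern pulsing in place)
spans a single spatial dimension, which a one-step linear map cannot
oscillate.  For such data :func:`exact_dmd` accepts ``n_delays`` to
shift-stack the window (Hankel/delay embedding), which makes a pure
sinusoid exactly rank-2 and recovers its frequency exactly.  The default
(``n_delays=1``) is the plain algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DataMatrix",
    "WindowSpec",
    "DMDFactors",
    "DMDMode",
    "ModeSet",
    "window_indices",
    "exact_dmd",
    "eigen_to_rates",
    "fit_amplitudes",
    "dedupe_conjugates",
    "run_windowed_dmd",
]


@dataclass
class DataMatrix:
    """A space x time real signal matrix with its frame interval.

    Parameters
    ----------
    values
        Array of shape ``(n_locations, n_frames)``.
    dt
        Seconds per frame; must be positive.
    coords
        Optional per-location spatial coordinates, shape ``(n_locations, d)``.
    groups
        Optional integer group label per location (e.g. hemisphere x
        lateral/medial for cortical data); used by the binning stage.
    scan_id
        Free-form label propagated into every derived artifact.
    """

    values: np.ndarray
    dt: float
    coords: np.ndarray | None = None
    groups: np.ndarray | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (locations x frames)")
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise ValueError(f"need >=1 location and >=2 frames, got {n}x{m}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(
                f"non-finite entries at (location, frame) {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive and finite, got {self.dt}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape[0] != n:
                raise ValueError("coords must have one row per location")

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length ``T``, step ``dT``, rank ``r``."""

    T: int = 32
    dT: int = 4
    r: int = 8

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("window length T must be >= 2")
        if self.dT < 1:
            raise ValueError("window step dT must be >= 1")
        if self.r < 1:
            raise ValueError("rank r must be >= 1")

    def validate_for(self, data: DataMatrix) -> None:
        if self.T > data.n_frames:
            raise ValueError(
                f"window length T={self.T} exceeds scan length {data.n_frames}"
            )
        if self.r > min(data.n_locations, self.T - 1):
            raise ValueError(
                f"rank r={self.r} exceeds min(n_locations, T-1)="
                f"{min(data.n_locations, self.T - 1)}"
            )


@dataclass
class DMDFactors:
    """Intermediate factors of one exact-DMD solve (for inspection/testing)."""

    U_r: np.ndarray
    S_r: np.ndarray
    V_r: np.ndarray
    A_tilde: np.ndarray
    A_hat: np.ndarray
    eigvals: np.ndarray
    W_hat: np.ndarray


@dataclass
class DMDMode:
    """One spatial DMD mode with its temporal eigenvalue and derived rates.

    ``freq_per_step`` is in cycles per frame; ``freq_hz = freq_per_step / dt``.
    ``growth`` is the continuous-time growth/decay constant in 1/s.  Spatial
    comparisons downstream use ``magnitude = |phi|``.
    """

    phi: np.ndarray
    eigval: complex
    growth: float
    freq_hz: float
    freq_per_step: float
    amplitude: complex
    window_index: int
    window_start: int
    scan_id: str = ""
    magnitude: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi)
        self.magnitude = np.abs(self.phi)


@dataclass
class ModeSet:
    """Modes pooled over all windows of one scan."""

    modes: list[DMDMode]
    window_starts: np.ndarray
    spec: WindowSpec
    dt: float
    scan_id: str = ""

    def __len__(self) -> int:
        return len(self.modes)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def magnitudes(self) -> np.ndarray:
        """Stack ``|phi|`` of every mode into an (n_modes, n_locations) array."""
        return np.array([m.magnitude for m in self.modes])

    def window_index(self) -> np.ndarray:
        return np.array([m.window_index for m in self.modes], dtype=int)

    def freq_hz(self) -> np.ndarray:
        return np.array([m.freq_hz for m in self.modes])

    def freq_per_step(self) -> np.ndarray:
        return np.array([m.freq_per_step for m in self.modes])


def window_indices(m: int, T: int, dT: int) -> np.ndarray:
    """Start frames of square sliding windows over ``m`` frames.

    Windows are half-open intervals ``[start, start + T)``; the count is
    ``floor((m - T) / dT) + 1``.  With the reference settings (1200 frames,
    T=32, dT=4) this yields 293 windows.
    """
    if T > m:
        raise ValueError(f"window length T={T} exceeds number of frames m={m}")
    if dT < 1:
        raise ValueError("dT must be >= 1")
    if T < 2:
        raise ValueError("T must be >= 2")
    n_win = (m - T) // dT + 1
    return np.arange(n_win) * dT


def eigen_to_rates(eigval: complex, dt: float) -> tuple[float, float]:
    """Convert a DMD eigenvalue to (growth 1/s, frequency Hz).

    Uses the principal branch of the logarithm::

        growth = Re(ln lambda) / dt,   freq = Im(ln lambda) / (2 pi dt)

    so the returned frequency lies in ``(-1/(2 dt), 1/(2 dt)]`` (the Nyquist
    interval).  A zero eigenvalue has no defined frequency and raises.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eigval == 0:
        raise ValueError("eigenvalue 0 (mode fully decayed); rates undefined")
    log_ev = np.log(complex(eigval))
    return float(log_ev.real / dt), float(log_ev.imag / (2.0 * np.pi * dt))


def fit_amplitudes(phi: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Least-squares mode amplitudes ``b`` with ``phi @ b ~= x0``.

    Amplitudes are fit as initial conditions at the first frame of the
    window.  A rank-deficient mode matrix falls back to the minimum-norm
    solution with a logged warning.
    """
    phi = np.atleast_2d(np.asarray(phi))
    b, _res, rank, _sv = np.linalg.lstsq(phi, np.asarray(x0, dtype=complex))
    if rank < phi.shape[1]:
        logger.warning(
            "mode matrix rank-deficient (%d < %d); minimum-norm amplitudes",
            rank,
            phi.shape[1],
        )
    return b


def _delay_embed(window: np.ndarray, n_delays: int) -> np.ndarray:
    """Shift-stack ``n_delays`` copies of the window (Hankel embedding)."""
    n, T = window.shape
    cols = T - n_delays + 1
    return np.vstack([window[:, i : i + cols] for i in range(n_delays)])


def exact_dmd(
    window: np.ndarray,
    r: int,
    dt: float = 1.0,
    *,
    n_delays: int = 1,
    window_index: int = 0,
    window_start: int = 0,
    scan_id: str = "",
    rank_tol: float = 1e-12,
) -> tuple[DMDFactors, list[DMDMode]]:
    """Exact DMD of one data window.

    Splits the window into ``X`` (frames 0..T-2) and the one-step-advanced
    ``X'`` (frames 1..T-1), takes the rank-``r`` SVD of ``X``, forms the
    reduced operator ``A~ = U* X' V S^-1``, rescales it to
    ``A^ = S^-1/2 A~ S^1/2``, eigendecomposes, and lifts eigenvectors to
    spatial modes ``Phi = X' V S^-1/2 W``.

    Singular values below ``rank_tol`` relative to the largest are treated
    as zero; if fewer than ``r`` remain, the rank is reduced with a logged
    warning (never silently padded).

    With ``n_delays > 1`` the window is shift-stacked first (needed for
    standing oscillations, which are spatially rank-1); returned modes keep
    only the zero-delay block, so their length matches the input space.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be 2-D")
    n_space = window.shape[0]
    if n_delays < 1:
        raise ValueError("n_delays must be >= 1")
    if n_delays > 1:
        window = _delay_embed(window, n_delays)
    T = window.shape[1]
    if T < 3:
        raise ValueError("window must have at least 3 frames (after embedding)")

    X = window[:, :-1]
    Xp = window[:, 1:]

    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    n_keep = int(np.sum(s > rank_tol * s[0])) if s[0] > 0 else 0
    if n_keep == 0:
        raise ValueError("window is numerically zero; DMD undefined")
    r_eff = min(r, n_keep)
    if r_eff < r:
        logger.warning(
            "window %d: effective rank %d < requested rank %d; reducing",
            window_index,
            r_eff,
            r,
        )

    U_r = U[:, :r_eff]
    S_r = s[:r_eff]
    V_r = Vh[:r_eff].conj().T

    A_tilde = U_r.conj().T @ Xp @ V_r / S_r[np.newaxis, :]
    sqrt_s = np.sqrt(S_r)
    A_hat = (A_tilde * sqrt_s[np.newaxis, :]) / sqrt_s[:, np.newaxis]
    eigvals, W_hat = np.linalg.eig(A_hat)

    Phi = Xp @ V_r @ np.diag(1.0 / sqrt_s) @ W_hat
    factors = DMDFactors(U_r, S_r, V_r, A_tilde, A_hat, eigvals, W_hat)

    b = fit_amplitudes(Phi, window[:, 0])
    modes: list[DMDMode] = []
    for j in range(r_eff):
        ev = complex(eigvals[j])
        if ev == 0:
            logger.warning("window %d: zero eigenvalue; dropping mode", window_index)
            continue
        growth, freq_hz = eigen_to_rates(ev, dt)
        modes.append(
            DMDMode(
                phi=Phi[:n_space, j],
                eigval=ev,
                growth=growth,
                freq_hz=freq_hz,
                freq_per_step=freq_hz * dt,
                amplitude=complex(b[j]),
                window_index=window_index,
                window_start=window_start,
                scan_id=scan_id,
            )
        )
    return factors, modes


def dedupe_conjugates(modes: list[DMDMode], tol: float = 1e-8) -> list[DMDMode]:
    """Collapse conjugate eigenvalue pairs to one mode each.

    For real input data, oscillatory modes come in conjugate pairs with
    identical spatial magnitudes; the member with nonnegative per-step
    frequency is kept.  Real-eigenvalue modes pass through unchanged.
    Pairing matches ``lambda_j`` to the nearest ``conj(lambda_k)`` within
    ``tol`` (relative).
    """
    keep: list[DMDMode] = []
    used = [False] * len(modes)
    for i, mi in enumerate(modes):
        if used[i]:
            continue
        used[i] = True
        if abs(mi.eigval.imag) <= tol * max(1.0, abs(mi.eigval)):
            keep.append(mi)
            continue
        partner = None
        for j in range(i + 1, len(modes)):
            if used[j]:
                continue
            mj = modes[j]
            if abs(mj.eigval - np.conj(mi.eigval)) <= tol * max(1.0, abs(mi.eigval)):
                partner = j
                break
        if partner is not None:
            used[partner] = True
            keep.append(mi if mi.freq_per_step >= 0 else modes[partner])
        else:
            # unpaired complex eigenvalue (can happen after rank reduction)
            keep.append(mi)
    return keep


def run_windowed_dmd(
    data: DataMatrix,
    spec: WindowSpec,
    *,
    n_delays: int = 1,
    dedupe: bool = True,
    demean: bool = False,
) -> ModeSet:
    """Apply exact DMD to every sliding window of a scan.

    ``demean`` subtracts each window's per-location temporal mean before the
    decomposition (off by default; the standard pipeline runs on raw data).
    Deterministic: repeated runs on identical input are bit-identical.
    """
    spec.validate_for(data)
    starts = window_indices(data.n_frames, spec.T, spec.dT)
    all_modes: list[DMDMode] = []
    for w_idx, start in enumerate(starts):
        window = data.values[:, start : start + spec.T]
        if demean:
            window = window - window.mean(axis=1, keepdims=True)
        try:
            _, modes = exact_dmd(
                window,
                spec.r,
                data.dt,
                n_delays=n_delays,
                window_index=w_idx,
                window_start=int(start),
                scan_id=data.scan_id,
            )
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(f"DMD failed in window {w_idx} (start {start}): {exc}") from exc
        if dedupe:
            modes = dedupe_conjugates(modes)
        all_modes.extend(modes)
    return ModeSet(all_modes, starts, spec, data.dt, data.scan_id)
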