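"""Synthetic Markov-switched benchmark: two overlapping pulsing spatial modes.

The benchmark emulates the structure of resting-state network dynamics at
desk scale: two spatially overlapping 2-D patterns (a "cat" and a "chicken"
silhouette, each in two variants) pulse sinusoidally at fixed per-timestep
frequencies and phases, switched on and off by a three-state Markov chain
(cat only, chicken only, both), in uniform background noise::

    X(t_k) = a_c sin(2 pi f_c k + phi_c) C  +  a_k sin(2 pi f_k k + phi_k) K  +  N

with amplitudes (a_c, a_k) in {(1,0), (0,1), (1,1)} read from the chain's
state at step k, and N uniform on [0, noise_amp) drawn fresh per pixel and
frame.  Defaults: 75x50-pixel patterns, f_c = 0.045 and f_k = 0.071 cycles
per timestep, phi_c = 1.6 and phi_k = 0.7 rad, noise amplitude 5, and 1200
timesteps (the length of a standard resting-state scan).

Every operation is deterministic given its seed; the ground-truth state
sequence is carried alongside the data so downstream inference can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmd import DataMatrix

__all__ = [
    "ShapeModes",
    "MarkovSpec",
    "SimulationResult",
    "generate_shape_modes",
    "sample_state_sequence",
    "synthesize",
    "simulate_benchmark",
    "batch_simulations",
    "DEFAULT_FREQ_CAT",
    "DEFAULT_FREQ_CHICKEN",
    "DEFAULT_PHASE_CAT",
    "DEFAULT_PHASE_CHICKEN",
    "DEFAULT_NOISE_AMP",
    "DEFAULT_N_STEPS",
    "DEFAULT_DT",
    "SHAPE_PEAK_INTENSITY",
]

DEFAULT_FREQ_CAT = 0.045  # cycles per timestep
DEFAULT_FREQ_CHICKEN = 0.071
DEFAULT_PHASE_CAT = 1.6  # radians
DEFAULT_PHASE_CHICKEN = 0.7
DEFAULT_NOISE_AMP = 5.0
DEFAULT_N_STEPS = 1200
DEFAULT_DT = 0.73  # seconds per frame, rs-fMRI-like

# Peak pattern intensity.  The noise amplitude (5) is fixed by convention,
# so this scale sets the signal-to-noise regime: at peak 10 the one-sided
# uniform noise (std ~1.44) is a substantial fraction of the per-pixel
# signal -- noisy single frames, but recoverable from short windows.
SHAPE_PEAK_INTENSITY = 10.0


@dataclass(frozen=True)
class ShapeModes:
    """Two pairs of overlapping nonnegative 2-D patterns (height x width)."""

    cat_a: np.ndarray
    cat_b: np.ndarray
    chicken_a: np.ndarray
    chicken_b: np.ndarray

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.all_patterns().values()}
        if len(shapes) != 1:
            raise ValueError("all four patterns must share identical dimensions")
        for name, p in self.all_patterns().items():
            if (p < 0).any():
                raise ValueError(f"pattern {name} has negative intensity")
        for cname in ("cat_a", "cat_b"):
            for kname in ("chicken_a", "chicken_b"):
                c = getattr(self, cname)
                k = getattr(self, kname)
                if not ((c > 0) & (k > 0)).any():
                    raise ValueError(f"{cname} and {kname} do not overlap")
                if not ((c > 0) ^ (k > 0)).any():
                    raise ValueError(f"{cname} and {kname} are spatially identical")

    def all_patterns(self) -> dict[str, np.ndarray]:
        return {
            "cat_a": self.cat_a,
            "cat_b": self.cat_b,
            "chicken_a": self.chicken_a,
            "chicken_b": self.chicken_b,
        }

    def cat(self, choice: str) -> np.ndarray:
        return {"A": self.cat_a, "B": self.cat_b}[choice.upper()]

    def chicken(self, choice: str) -> np.ndarray:
        return {"A": self.chicken_a, "B": self.chicken_b}[choice.upper()]

    @property
    def height(self) -> int:
        return self.cat_a.shape[0]

    @property
    def width(self) -> int:
        return self.cat_a.shape[1]


@dataclass(frozen=True)
class MarkovSpec:
    """Three-state amplitude chain: (cat only, chicken only, both).

    ``transition_probs`` holds per-timestep probabilities; each row must sum
    to one.  The default favors strong self-transitions (0.98, mean dwell
    ~50 steps, so states persist across several 32-frame windows) with
    direct cat<->chicken swaps rarer than passages through "both".
    """

    states: tuple[tuple[float, float], ...] = ((1.0, 0.0), (0.0, 1.0), (1.0, 1.0))
    transition_probs: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.980, 0.004, 0.016],
                [0.004, 0.980, 0.016],
                [0.010, 0.010, 0.980],
            ]
        )
    )
    initial_state: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_probs, dtype=float)
        object.__setattr__(self, "transition_probs", P)
        n = len(self.states)
        if P.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}, got {P.shape}")
        if (P < 0).any() or (P > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each transition-matrix row must sum to 1 (within 1e-12)")
        if not 0 <= self.initial_state < n:
            raise ValueError("initial_state out of range")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution via eigen-analysis of the transition matrix."""
        w, v = np.linalg.eig(self.transition_probs.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


@dataclass
class SimulationResult:
    """Synthetic data plus its full ground truth."""

    data: DataMatrix
    state_sequence: np.ndarray
    shapes: ShapeModes
    cat_choice: str
    chicken_choice: str
    markov: MarkovSpec
    params: dict

    @property
    def cat_image(self) -> np.ndarray:
        return self.shapes.cat(self.cat_choice)

    @property
    def chicken_image(self) -> np.ndarray:
        return self.shapes.chicken(self.chicken_choice)

    def amplitudes(self) -> np.ndarray:
        """(n_steps, 2) array of (a_c, a_k) read from the state sequence."""
        table = np.asarray(self.markov.states, dtype=float)
        return table[self.state_sequence]


def _soft_ellipse(yy, xx, cy, cx, ry, rx):
    """Smooth elliptical bump: 1 at the center falling to 0 at the rim."""
    d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    return np.sqrt(np.clip(1.0 - d2, 0.0, None))


def generate_shape_modes(
    width: int = 75, height: int = 50, seed: int = 0
) -> ShapeModes:
    """Build two pairs of partially overlapping silhouette patterns.

    The paper's original cat/chicken bitmaps are not distributed; any two
    pairs of partially overlapping nonnegative patterns play the same role
    in the benchmark.  Each pattern here is a union of smooth elliptical
    bumps (body + head + an appendage), the "cat" on the left and the
    "chicken" on the right of the frame with a controlled overlap band in
    the middle.  The A/B variants differ by a small seeded jitter of the
    component geometry.  Deterministic given the seed.
    """
    if width < 8 or height < 8:
        raise ValueError("width and height must be >= 8 to place two overlapping shapes")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    w, h = float(width), float(height)

    def build(kind: str, jitter: np.ndarray) -> np.ndarray:
        jy, jx = jitter * 0.02 * h, jitter * 0.02 * w
        if kind == "cat":
            body = _soft_ellipse(yy, xx, 0.52 * h + jy[0], 0.30 * w + jx[0], 0.30 * h, 0.23 * w)
            head = _soft_ellipse(yy, xx, 0.28 * h + jy[1], 0.44 * w + jx[1], 0.15 * h, 0.11 * w)
            ear = _soft_ellipse(yy, xx, 0.14 * h + jy[2], 0.40 * w + jx[2], 0.09 * h, 0.04 * w)
            img = np.maximum(np.maximum(body, head), ear)
        else:
            body = _soft_ellipse(yy, xx, 0.56 * h + jy[0], 0.66 * w + jx[0], 0.26 * h, 0.19 * w)
            head = _soft_ellipse(yy, xx, 0.26 * h + jy[1], 0.58 * w + jx[1], 0.13 * h, 0.09 * w)
            beak = _soft_ellipse(yy, xx, 0.26 * h + jy[2], 0.49 * w + jx[2], 0.04 * h, 0.06 * w)
            img = np.maximum(np.maximum(body, head), beak)
        return SHAPE_PEAK_INTENSITY * img

    patterns = {}
    for name, kind in [
        ("cat_a", "cat"),
        ("cat_b", "cat"),
        ("chicken_a", "chicken"),
        ("chicken_b", "chicken"),
    ]:
        patterns[name] = build(kind, rng.uniform(-1.0, 1.0, size=3))
    return ShapeModes(**patterns)  # invariants (overlap etc.) checked here


def sample_state_sequence(spec: MarkovSpec, n_steps: int, seed: int) -> np.ndarray:
    """Draw a state-index sequence of length ``n_steps`` from the chain.

    The first element is ``spec.initial_state``; each subsequent step is
    drawn from the corresponding row of the transition matrix.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    P = spec.transition_probs
    cum = np.cumsum(P, axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps - 1)
    seq = np.empty(n_steps, dtype=np.int64)
    seq[0] = spec.initial_state
    s = spec.initial_state
    for k in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[k - 1], side="right"))
        s = min(s, spec.n_states - 1)  # guard against u landing on 1.0 exactly
        seq[k] = s
    return seq


def synthesize(
    shapes: ShapeModes,
    cat_choice: str = "A",
    chicken_choice: str = "A",
    states: np.ndarray | None = None,
    *,
    markov: MarkovSpec | None = None,
    f_c: float = DEFAULT_FREQ_CAT,
    f_k: float = DEFAULT_FREQ_CHICKEN,
    phi_c: float = DEFAULT_PHASE_CAT,
    phi_k: float = DEFAULT_PHASE_CHICKEN,
    noise_amp: float = DEFAULT_NOISE_AMP,
    centered_noise: bool = False,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    scan_id: str = "",
) -> SimulationResult:
    """Render the pulsing-mode data matrix for a given state sequence.

    ``states`` indexes ``markov.states`` (amplitude pairs) per timestep.
    Noise is uniform on ``[0, noise_amp)`` per pixel per frame (one-sided;
    ``centered_noise=True`` shifts it to zero mean).  The returned data
    matrix is pixels (row-major flattened) x timesteps, with per-pixel
    (row, col) coordinates attached for the binning stage.
    """
    markov = markov if markov is not None else MarkovSpec()
    if states is None:
        raise ValueError("states must be provided (see sample_state_sequence)")
    states = np.asarray(states, dtype=int)
    if states.min() < 0 or states.max() >= markov.n_states:
        raise ValueError(
            f"state indices must lie in [0, {markov.n_states}); got range "
            f"[{states.min()}, {states.max()}]"
        )
    if not (0 < f_c < 0.5 and 0 < f_k < 0.5):
        raise ValueError("frequencies must lie in (0, 0.5) cycles per timestep")

    C = shapes.cat(cat_choice).ravel()
    K = shapes.chicken(chicken_choice).ravel()
    n_steps = len(states)
    k = np.arange(n_steps)
    amp = np.asarray(markov.states, dtype=float)[states]  # (n_steps, 2)
    sig_c = amp[:, 0] * np.sin(2.0 * np.pi * f_c * k + phi_c)
    sig_k = amp[:, 1] * np.sin(2.0 * np.pi * f_k * k + phi_k)

    values = np.outer(C, sig_c) + np.outer(K, sig_k)
    if noise_amp > 0:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0.0, noise_amp, size=values.shape)
        if centered_noise:
            noise -= noise_amp / 2.0
        values += noise

    h, w = shapes.height, shapes.width
    rows, cols = np.divmod(np.arange(h * w), w)
    coords = np.column_stack([rows, cols]).astype(float)

    data = DataMatrix(values=values, dt=dt, coords=coords, scan_id=scan_id)
    params = {
        "f_c": f_c,
        "f_k": f_k,
        "phi_c": phi_c,
        "phi_k": phi_k,
        "noise_amp": noise_amp,
        "centered_noise": centered_noise,
        "dt": dt,
        "seed": seed,
        "width": w,
        "height": h,
        "cat_choice": cat_choice,
        "chicken_choice": chicken_choice,
    }
    return SimulationResult(
        data=data,
        state_sequence=states,
        shapes=shapes,
        cat_choice=cat_choice,
        chicken_choice=chicken_choice,
        markov=markov,
        params=params,
    )


def simulate_benchmark(
    seed: int = 0,
    *,
    width: int = 75,
    height: int = 50,
    n_steps: int = DEFAULT_N_STEPS,
    markov: MarkovSpec | None = None,
    cat_choice: str = "A",
    chicken_choice: str = "A",
    noise_amp: float = DEFAULT_NOISE_AMP,
    dt: float = DEFAULT_DT,
    scan_id: str = "",
) -> SimulationResult:
    """One default benchmark run: shapes + chain + rendering from one seed.

    Derives independent sub-seeds for the shape geometry, the state
    sequence, and the noise so that a single integer reproduces the run.
    """
    markov = markov if markov is not None else MarkovSpec()
    ss = np.random.SeedSequence(seed).spawn(3)
    shape_seed, chain_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    shapes = generate_shape_modes(width, height, shape_seed)
    states = sample_state_sequence(markov, n_steps, chain_seed)
    return synthesize(
        shapes,
        cat_choice,
        chicken_choice,
        states,
        markov=markov,
        noise_amp=noise_amp,
        dt=dt,
        seed=noise_seed,
        scan_id=scan_id or f"sim-{seed}",
    )


def batch_simulations(seed: int = 0, **kwargs) -> list[SimulationResult]:
    """The four variant combinations (cat A/B x chicken A/B), one run each."""
    runs = []
    for i, (c, k) in enumerate([("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")]):
        runs.append(
            simulate_benchmark(
                seed + i, cat_choice=c, chicken_choice=k,
                scan_id=f"sim-{seed + i}-cat{c}-chicken{k}", **kwargs,
            )
        )
    return runs
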