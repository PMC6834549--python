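import logging

import numpy as np
import pytest

import dmdnet as dn

logging.getLogger("dmdnet").setLevel(logging.ERROR)


def pearson(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return float(np.corrcoef(a, b)[0, 1])


def lifted_linear_trajectory(eigvals_blocks, n_space, n_frames, seed=0):
    """Trajectory of x_{k+1} = A x_k with known spectrum, lifted to n_space.

    ``eigvals_blocks`` lists real eigenvalues and (r, theta) pairs for
    2x2 rotation-scaling blocks; the state is embedded with a random
    orthonormal map so the data is genuinely high-dimensional.  Serves as
    the independent oracle for DMD spectrum recovery.
    """
    from scipy.linalg import block_diag

    blocks = []
    true_eigs = []
    for item in eigvals_blocks:
        if np.isscalar(item):
            blocks.append(np.array([[float(item)]]))
            true_eigs.append(complex(item))
        else:
            r, theta = item
            c, s = r * np.cos(theta), r * np.sin(theta)
            blocks.append(np.array([[c, -s], [s, c]]))
            true_eigs.extend([r * np.exp(1j * theta), r * np.exp(-1j * theta)])
    A = block_diag(*blocks)
    d = A.shape[0]
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n_space, d)))
    x = rng.standard_normal(d)
    traj = np.empty((d, n_frames))
    for k in range(n_frames):
        traj[:, k] = x
        x = A @ x
    return Q @ traj, np.array(true_eigs), A


@pytest.fixture(scope="session")
def default_sim():
    """One default benchmark run (75x50 pixels, 1200 steps, noise 5)."""
    return dn.simulate_benchmark(seed=0)


@pytest.fixture(scope="session")
def default_modeset(default_sim):
    return dn.run_windowed_dmd(default_sim.data, dn.WindowSpec())


@pytest.fixture(scope="session")
def small_shapes():
    return dn.generate_shape_modes(width=24, height=16, seed=3)


@pytest.fixture(scope="session")
def synthetic_report():
    """Full benchmark pipeline run scored against ground truth (seed 0)."""
    return dn.analyze_synthetic_run(seed=0)
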