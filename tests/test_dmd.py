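"""Exact DMD: windowing arithmetic, spectra, rates, conjugate handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmdnet as dn
from dmdnet.dmd import exact_dmd

from conftest import lifted_linear_trajectory


class TestWindowIndices:
    @pytest.mark.parametrize(
        "m,T,dT,count,last",
        [
            (1200, 32, 4, 293, 1168),
            (32, 32, 4, 1, 0),
            (100, 32, 4, 18, 68),
        ],
    )
    def test_counts_and_last_start(self, m, T, dT, count, last):
        starts = dn.window_indices(m, T, dT)
        assert len(starts) == count
        assert starts[0] == 0 and starts[-1] == last

    def test_window_longer_than_scan_raises(self):
        with pytest.raises(ValueError):
            dn.window_indices(10, 32, 4)

    @settings(deadline=None, derandomize=True)
    @given(
        m=st.integers(2, 500), T=st.integers(2, 500), dT=st.integers(1, 50)
    )
    def test_windows_fit_and_cover(self, m, T, dT):
        if T > m:
            with pytest.raises(ValueError):
                dn.window_indices(m, T, dT)
            return
        starts = dn.window_indices(m, T, dT)
        assert (starts + T <= m).all()
        assert len(starts) == (m - T) // dT + 1
        assert (np.diff(starts) == dT).all() or len(starts) == 1


class TestExactDMD:
    def test_known_linear_spectrum_recovered(self):
        """DMD eigenvalues match the constructed operator's spectrum."""
        data, true_eigs, _ = lifted_linear_trajectory(
            [(0.9, 0.3), 0.8], n_space=40, n_frames=30
        )
        _, modes = exact_dmd(data, r=3)
        got = np.sort_complex(np.array([m.eigval for m in modes]))
        np.testing.assert_allclose(got, np.sort_complex(true_eigs), atol=1e-8)

    def test_constant_window_identity_dynamics(self):
        window = np.outer(np.arange(1.0, 6.0), np.ones(10))
        _, modes = exact_dmd(window, r=1)
        assert len(modes) == 1
        assert abs(modes[0].eigval - 1.0) < 1e-10

    def test_rank_reduced_with_warning(self, caplog):
        window = np.outer(np.arange(1.0, 6.0), np.ones(10))
        with caplog.at_level("WARNING", logger="dmdnet.dmd"):
            _, modes = exact_dmd(window, r=4)
        assert len(modes) == 1  # effective rank 1, never padded
        assert any("reducing" in r.message for r in caplog.records)

    def test_noise_free_standing_mode_needs_delay_embedding(self, small_shapes):
        """A pulsing image is rank-1 in space; shift-stacking recovers f."""
        cat_only = dn.MarkovSpec(
            states=((1.0, 0.0),), transition_probs=np.array([[1.0]])
        )
        sim = dn.synthesize(
            small_shapes,
            states=np.zeros(32, dtype=int),
            markov=cat_only,
            f_c=0.045,
            noise_amp=0.0,
        )
        window = sim.data.values
        # plain DMD: rank collapses to 1, no oscillation representable
        _, plain = exact_dmd(window, r=2)
        assert len(plain) == 1 and abs(plain[0].eigval.imag) < 1e-10
        # delay-embedded DMD: exact conjugate pair at the true frequency
        _, modes = exact_dmd(window, r=2, n_delays=2)
        freqs = sorted(m.freq_per_step for m in modes)
        np.testing.assert_allclose(freqs, [-0.045, 0.045], atol=1e-9)

    def test_conjugate_pairs_have_equal_magnitude(self):
        data, _, _ = lifted_linear_trajectory(
            [(0.95, 0.2), (0.85, 0.5)], n_space=30, n_frames=25, seed=3
        )
        _, modes = exact_dmd(data, r=4)
        eigs = np.array([m.eigval for m in modes])
        for i, m in enumerate(modes):
            if abs(m.eigval.imag) < 1e-12:
                continue
            j = int(np.argmin(np.abs(eigs - np.conj(m.eigval))))
            np.testing.assert_allclose(
                m.magnitude, modes[j].magnitude, atol=1e-8
            )

    def test_truncation_optimality(self):
        """Rank-r SVD residual equals the discarded singular energy."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 9))
        U, s, Vh = np.linalg.svd(X, full_matrices=False)
        for r in (1, 3, 5):
            approx = U[:, :r] @ np.diag(s[:r]) @ Vh[:r]
            np.testing.assert_allclose(
                np.linalg.norm(X - approx, "fro"),
                np.sqrt((s[r:] ** 2).sum()),
                rtol=1e-10,
            )

    def test_factor_invariants(self):
        data, _, _ = lifted_linear_trajectory(
            [(0.9, 0.3), 0.8], n_space=25, n_frames=20, seed=5
        )
        factors, _ = exact_dmd(data, r=3)
        # orthonormal left singular vectors
        np.testing.assert_allclose(
            factors.U_r.T @ factors.U_r, np.eye(3), atol=1e-8
        )
        assert (np.diff(factors.S_r) <= 0).all()
        # eigen-relation of the scaled reduced operator
        np.testing.assert_allclose(
            factors.A_hat @ factors.W_hat,
            factors.W_hat @ np.diag(factors.eigvals),
            atol=1e-6 * np.abs(factors.eigvals).max(),
        )


class TestEigenToRates:
    @pytest.mark.parametrize(
        "eigval,dt,growth,freq",
        [
            (1.0, 0.72, 0.0, 0.0),
            (0.9, 1.0, np.log(0.9), 0.0),
        ],
    )
    def test_closed_forms(self, eigval, dt, growth, freq):
        g, f = dn.eigen_to_rates(eigval, dt)
        assert g == pytest.approx(growth, abs=1e-12)
        assert f == pytest.approx(freq, abs=1e-12)

    def test_per_step_frequency_to_hertz(self):
        """0.045 cycles/step at dt = 0.73 s is about 0.06 Hz."""
        _, f = dn.eigen_to_rates(np.exp(1j * 2 * np.pi * 0.045), dt=0.73)
        assert f == pytest.approx(0.045 / 0.73, abs=1e-12)
        assert round(f, 2) == 0.06

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            dn.eigen_to_rates(0.0, 0.72)

    @settings(deadline=None, derandomize=True)
    @given(
        growth=st.floats(-1.0, 1.0),
        freq=st.floats(-0.6, 0.6),
        dt=st.floats(0.1, 2.0),
    )
    def test_roundtrip_identity_below_nyquist(self, growth, freq, dt):
        if abs(freq) >= 1.0 / (2 * dt) - 1e-9:
            return  # aliased: principal branch cannot recover
        ev = np.exp((growth + 1j * 2 * np.pi * freq) * dt)
        g, f = dn.eigen_to_rates(ev, dt)
        assert g == pytest.approx(growth, abs=1e-9)
        assert f == pytest.approx(freq, abs=1e-9)


class TestAmplitudes:
    def test_single_mode_equal_to_x0(self):
        x0 = np.array([1.0, 2.0, 3.0])
        b = dn.fit_amplitudes(x0[:, None], x0)
        np.testing.assert_allclose(b, [1.0], atol=1e-12)

    def test_zero_initial_condition(self):
        phi = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        b = dn.fit_amplitudes(phi, np.zeros(3))
        np.testing.assert_allclose(b, 0.0, atol=1e-12)

    def test_forward_reconstruction_matches_every_snapshot(self):
        data, _, _ = lifted_linear_trajectory(
            [(0.95, 0.25), 0.9], n_space=30, n_frames=24, seed=7
        )
        _, modes = exact_dmd(data, r=3)
        Phi = np.column_stack([m.phi for m in modes])
        b = np.array([m.amplitude for m in modes])
        lam = np.array([m.eigval for m in modes])
        for k in range(data.shape[1] - 1):
            recon = (Phi * (lam**k)) @ b
            np.testing.assert_allclose(
                recon.real, data[:, k], atol=1e-6 * np.abs(data).max()
            )


class TestDedupeConjugates:
    def _mode(self, eigval, n=4):
        g, f = dn.eigen_to_rates(eigval, 1.0)
        return dn.DMDMode(
            phi=np.ones(n, dtype=complex),
            eigval=eigval,
            growth=g,
            freq_hz=f,
            freq_per_step=f,
            amplitude=1.0 + 0j,
            window_index=0,
            window_start=0,
        )

    def test_pair_keeps_nonnegative_frequency(self):
        pair = [self._mode(0.9 * np.exp(-0.3j)), self._mode(0.9 * np.exp(0.3j))]
        kept = dn.dedupe_conjugates(pair)
        assert len(kept) == 1 and kept[0].freq_per_step >= 0

    def test_real_mode_passes_through(self):
        kept = dn.dedupe_conjugates([self._mode(0.8 + 0j)])
        assert len(kept) == 1 and kept[0].eigval == 0.8 + 0j

    def test_three_pairs_two_reals_give_five(self):
        modes = []
        for theta in (0.2, 0.5, 1.1):
            modes.append(self._mode(0.9 * np.exp(1j * theta)))
            modes.append(self._mode(0.9 * np.exp(-1j * theta)))
        modes.append(self._mode(0.7 + 0j))
        modes.append(self._mode(-0.5 + 0j))
        kept = dn.dedupe_conjugates(modes)
        assert len(kept) == 5
        assert all(m.freq_per_step >= 0 or abs(m.eigval.imag) < 1e-12 for m in kept)


class TestWindowedRun:
    def test_default_benchmark_geometry(self, default_modeset):
        ms = default_modeset
        assert ms.n_windows == 293
        assert len(ms) <= 293 * 8
        per_window = np.bincount(ms.window_index(), minlength=293)
        assert per_window.max() <= 8

    def test_pre_dedup_mode_cap(self, default_sim):
        short = dn.DataMatrix(
            default_sim.data.values[:, :120],
            default_sim.data.dt,
            coords=default_sim.data.coords,
        )
        ms = dn.run_windowed_dmd(short, dn.WindowSpec(), dedupe=False)
        per_window = np.bincount(ms.window_index(), minlength=ms.n_windows)
        assert (per_window <= 8).all()

    def test_single_window_when_T_equals_m(self):
        rng = np.random.default_rng(0)
        data = dn.DataMatrix(rng.standard_normal((20, 16)), dt=1.0)
        ms = dn.run_windowed_dmd(data, dn.WindowSpec(T=16, dT=1, r=3))
        assert ms.n_windows == 1

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((15, 40))
        a = dn.run_windowed_dmd(dn.DataMatrix(values, 1.0), dn.WindowSpec(T=10, dT=5, r=3))
        b = dn.run_windowed_dmd(dn.DataMatrix(values, 1.0), dn.WindowSpec(T=10, dT=5, r=3))
        for ma, mb in zip(a.modes, b.modes):
            np.testing.assert_array_equal(ma.phi, mb.phi)
            assert ma.eigval == mb.eigval

    def test_mode_rate_consistency(self, default_modeset):
        """growth/freq of every mode agree with its eigenvalue via the log map."""
        dt = default_modeset.dt
        for m in default_modeset.modes[::97]:
            g, f = dn.eigen_to_rates(m.eigval, dt)
            assert m.growth == pytest.approx(g, abs=1e-10)
            assert m.freq_hz == pytest.approx(f, abs=1e-10)
            assert m.freq_per_step == pytest.approx(f * dt, abs=1e-10)
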