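"""Occupancy, transfer, timepoint traces, transition estimation, reproducibility."""

import numpy as np
import pytest

import dmdnet as dn
from dmdnet import dynamics


def raster_from_rows(rows, n_windows=10, T=32, dT=4, dt=0.72):
    active = np.zeros((len(rows), n_windows), dtype=bool)
    for i, wins in enumerate(rows):
        active[i, list(wins)] = True
    return dynamics.ActivationRaster(
        active=active,
        cluster_ids=np.arange(len(rows)),
        window_starts=np.arange(n_windows) * dT,
        T=T,
        dT=dT,
        dt=dt,
    )


class TestBuildRaster:
    def _cluster_set(self, labels, windows):
        return dn.ClusterSet(
            labels=np.asarray(labels),
            linkage_matrix=np.empty((0, 4)),
            params=dn.ClusterParams(),
            masks=np.ones((len(labels), 4), dtype=bool),
            mode_windows=np.asarray(windows),
        )

    def _mode_set_stub(self, n_windows):
        class Stub:
            window_starts = np.arange(n_windows) * 4
            spec = dn.WindowSpec()
            dt = 0.72

        return Stub()

    def test_member_windows_marked(self):
        cs = self._cluster_set([1, 1, 2], [0, 5, 3])
        raster = dynamics.build_raster(cs, self._mode_set_stub(8))
        np.testing.assert_array_equal(
            np.flatnonzero(raster.active[0]), [0, 5]
        )
        np.testing.assert_array_equal(np.flatnonzero(raster.active[1]), [3])

    def test_requested_empty_cluster_gives_zero_row(self):
        cs = self._cluster_set([1, 1], [0, 1])
        raster = dynamics.build_raster(
            cs, self._mode_set_stub(5), cluster_ids=[1, 99]
        )
        assert raster.active[1].sum() == 0

    def test_raster_support_matches_membership_bruteforce(self, synthetic_report):
        res = synthetic_report.result
        cs, raster = res.cluster_set, res.raster
        for row, cid in enumerate(raster.cluster_ids):
            expected = set(cs.mode_windows[cs.labels == cid].tolist())
            assert set(np.flatnonzero(raster.active[row]).tolist()) == expected

    def test_missing_provenance_rejected(self):
        cs = dn.ClusterSet(
            labels=np.array([1]),
            linkage_matrix=np.empty((0, 4)),
            params=dn.ClusterParams(),
            masks=np.ones((1, 4), dtype=bool),
        )
        with pytest.raises(ValueError):
            dynamics.build_raster(cs, self._mode_set_stub(3))


class TestOccupancy:
    def test_intersection_counts(self):
        raster = raster_from_rows([{1, 2, 3}, {2, 3, 4}])
        O = dynamics.occupancy(raster).O
        assert O[0, 0] == 3 and O[1, 1] == 3 and O[0, 1] == 2

    def test_disjoint_rows(self):
        O = dynamics.occupancy(raster_from_rows([{0, 1}, {5, 6}])).O
        assert O[0, 1] == 0

    def test_identical_rows(self):
        O = dynamics.occupancy(raster_from_rows([{2, 4}, {2, 4}])).O
        assert O[0, 1] == O[0, 0] == O[1, 1] == 2

    def test_symmetry_and_diagonal_dominance_random(self):
        rng = np.random.default_rng(0)
        raster = raster_from_rows(
            [set(np.flatnonzero(rng.random(30) < 0.4)) for _ in range(6)],
            n_windows=30,
        )
        O = dynamics.occupancy(raster).O
        np.testing.assert_array_equal(O, O.T)
        for i in range(6):
            assert (O[i] <= O[i, i]).all()


class TestTransfer:
    def test_always_active_gives_ones(self):
        raster = raster_from_rows([set(range(10)), set(range(10))])
        T = dynamics.transfer(raster, lag_seconds=raster.dT * raster.dt * 3)
        np.testing.assert_allclose(T.T_mat, 1.0)
        assert T.lag_windows == 3

    def test_row_without_valid_sources_flagged(self):
        raster = raster_from_rows([{9}, {0, 1}])
        T = dynamics.transfer(raster, lag_seconds=raster.dT * raster.dt * 2)
        assert T.undefined[0] and not T.undefined[1]
        assert np.isnan(T.T_mat[0]).all()

    def test_counting_oracle_lag_one(self):
        rows = [{0, 2, 3, 6}, {1, 3, 4, 7}]
        raster = raster_from_rows(rows, n_windows=8)
        T = dynamics.transfer(raster, lag_seconds=raster.dT * raster.dt)
        for i in range(2):
            src = [w for w in rows[i] if w + 1 < 8]
            for j in range(2):
                hits = sum(1 for w in src if (w + 1) in rows[j])
                assert T.T_mat[i, j] == pytest.approx(hits / len(src))

    def test_zero_lag_equals_normalized_occupancy(self):
        rng = np.random.default_rng(1)
        raster = raster_from_rows(
            [set(np.flatnonzero(rng.random(20) < 0.5)) for _ in range(4)],
            n_windows=20,
        )
        T = dynamics.transfer(raster, lag_seconds=0.0)
        O = dynamics.occupancy(raster).O
        expected = O / np.diag(O)[:, None]
        np.testing.assert_allclose(T.T_mat, expected)

    def test_lag_beyond_scan_rejected(self):
        raster = raster_from_rows([{0}], n_windows=3)
        with pytest.raises(ValueError):
            dynamics.transfer(raster, lag_seconds=raster.dT * raster.dt * 5)


class TestTimepointTraces:
    def test_single_window_interval(self):
        raster = raster_from_rows([{0}], n_windows=4)
        traces = dynamics.timepoint_traces(raster, n_frames=50)
        np.testing.assert_array_equal(np.flatnonzero(traces[0]), np.arange(32))

    def test_no_active_windows(self):
        raster = raster_from_rows([set()], n_windows=4)
        assert dynamics.timepoint_traces(raster, 40).sum() == 0

    def test_overlapping_windows_union(self):
        raster = raster_from_rows([{0, 1}], n_windows=4)  # starts 0 and 4, T=32
        traces = dynamics.timepoint_traces(raster, n_frames=60)
        np.testing.assert_array_equal(np.flatnonzero(traces[0]), np.arange(36))

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(2)
        wins = set(np.flatnonzero(rng.random(12) < 0.4))
        raster = raster_from_rows([wins], n_windows=12)
        traces = dynamics.timepoint_traces(raster, n_frames=100)
        expected = np.zeros(100, dtype=bool)
        for w in wins:
            expected[w * 4 : w * 4 + 32] = True
        np.testing.assert_array_equal(traces[0], expected)


class TestTransitionEstimation:
    def test_constant_sequence_self_transition_one(self):
        P, _ = dynamics.estimate_transitions(np.zeros(50, dtype=int))
        assert P[0, 0] == 1.0
        assert np.isnan(P[1]).all() and np.isnan(P[2]).all()

    def test_hand_counted_sequence(self):
        labels = np.array([0, 0, 1, 1, 2, 0, 0, 1, 2, 2])
        P, counts = dynamics.estimate_transitions(labels)
        expected_counts = np.array([[2, 2, 0], [0, 1, 2], [1, 0, 1]])
        np.testing.assert_array_equal(counts, expected_counts)
        np.testing.assert_allclose(P[0], [0.5, 0.5, 0.0])

    def test_invalid_labels_excluded(self):
        labels = np.array([0, -1, 1, 1])
        _, counts = dynamics.estimate_transitions(labels)
        assert counts.sum() == 1  # only the 1->1 pair is fully labeled

    def test_recovers_chain_within_three_se(self):
        """ML estimation on raw chain samples is consistent."""
        spec = dn.MarkovSpec()
        seq = dn.sample_state_sequence(spec, 10**5, seed=3)
        P_hat, counts = dynamics.estimate_transitions(seq)
        N = counts.sum(axis=1)
        se = np.sqrt(spec.transition_probs * (1 - spec.transition_probs) / N[:, None])
        assert (np.abs(P_hat - spec.transition_probs) <= 3 * np.maximum(se, 1e-12)).all()

    def test_traces_to_labels_mapping(self):
        cat = np.array([1, 1, 0, 0, 1], dtype=bool)
        chk = np.array([0, 1, 1, 0, 1], dtype=bool)
        np.testing.assert_array_equal(
            dynamics.traces_to_labels(cat, chk), [0, 2, 1, -1, 2]
        )


class TestReproducibility:
    def test_identical_occupancies_perfect_rank_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 50, size=(2, 20))
        occ = np.repeat(base[:, :, None], 3, axis=2)
        table = dynamics.reproducibility(occ)
        assert (table["median_rho"] == 1.0).all()

    def test_reversed_ranks_anticorrelated(self):
        base = np.arange(10.0)
        occ = np.stack([base, base[::-1]], axis=-1)[None, :, :]
        table = dynamics.reproducibility(occ)
        assert table.loc[0, "median_rho"] == pytest.approx(-1.0)

    def test_shared_propensity_detected_at_population_scale(self):
        """Subjects with a stable per-subject activity level correlate across runs."""
        rng = np.random.default_rng(4)
        n_subjects, n_runs = 120, 4
        propensity = rng.uniform(5, 40, size=n_subjects)
        occ = propensity[None, :, None] + rng.normal(
            0, 6, size=(3, n_subjects, n_runs)
        )
        table = dynamics.reproducibility(occ)
        assert (table["median_rho"] > 0.5).all()
        assert (table["p_value"] < 0.05).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            dynamics.reproducibility(np.ones((1, 2, 2)))
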