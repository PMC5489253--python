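import numpy as np
import pytest

from mousebrainsim import (
    BoldSeries,
    commute_distance,
    count_seizure_cycles,
    fcd_matrix,
    functional_connectivity,
    functional_hubs,
    hub_volume,
    make_connectome,
    make_onset_series,
    make_switching_bold,
    segment_epochs,
    seizure_onset_latency,
    spectral_embedding,
)
from mousebrainsim.analysis import AnalysisError


def random_connected_affinity(rng, n):
    """Random symmetric nonnegative affinity guaranteed connected."""
    W = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    for i in range(n - 1):  # ring keeps it connected
        W[i, i + 1] = W[i + 1, i] = W[i, i + 1] + 0.2
    W[0, n - 1] = W[n - 1, 0] = W[0, n - 1] + 0.2
    return W


class TestFunctionalConnectivity:
    def test_identical_signals_fully_correlated(self):
        x = np.vstack([np.sin(np.linspace(0, 10, 50))] * 2)
        fc = functional_connectivity(x)
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_sign_flip_anticorrelated(self):
        s = np.sin(np.linspace(0, 10, 50))
        fc = functional_connectivity(np.vstack([s, -s]))
        assert fc.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        fc = functional_connectivity(np.array([[1.0, 2, 3, 4], [1, 2, 4, 3]]))
        assert fc.values[0, 1] == pytest.approx(0.8)

    def test_zero_variance_region_named(self):
        bold = BoldSeries(
            values=np.array([[1.0, 2, 3], [5, 5, 5]]),
            dt_s=2.0,
            region_labels=["good", "flat"],
        )
        with pytest.raises(AnalysisError, match="flat"):
            functional_connectivity(bold)

    def test_too_few_samples_rejected(self):
        with pytest.raises(AnalysisError, match="3 time points"):
            functional_connectivity(np.ones((2, 2)))


class TestFCD:
    def test_default_window_count_for_20_minutes(self, rng):
        bold = BoldSeries(values=rng.standard_normal((4, 600)), dt_s=2.0)
        fcd = fcd_matrix(bold)
        assert fcd.n_windows == 256

    def test_stationary_structured_signals_give_high_fcd(self, rng):
        # a fixed two-group correlation structure held for the whole series:
        # window FCs vary around one pattern, so inter-window correlation is
        # high (a single stable epoch)
        f = rng.standard_normal(600)
        sign = np.array([1.0, 1, 1, -1, -1, -1])
        values = 0.9 * sign[:, None] * f[None, :] + 0.45 * rng.standard_normal((6, 600))
        fcd = fcd_matrix(BoldSeries(values=values, dt_s=2.0))
        off = fcd.values[np.triu_indices(fcd.n_windows, 1)]
        assert off.mean() > 0.8

    def test_switching_states_give_block_structure(self):
        bold, truth = make_switching_bold(seed=4)
        fcd = fcd_matrix(bold)
        w = fcd.n_windows
        third = w // 3
        within_a = fcd.values[:third, :third]
        within_b = fcd.values[-third:, -third:]
        across = fcd.values[:third, -third:]
        assert within_a.mean() > 0.8 and within_b.mean() > 0.8
        assert across.mean() < 0.2

    def test_overlap_must_be_smaller_than_window(self, rng):
        bold = BoldSeries(values=rng.standard_normal((3, 600)), dt_s=2.0)
        with pytest.raises(AnalysisError, match="overlap"):
            fcd_matrix(bold, window_s=180.0, overlap_s=180.0)

    def test_unit_diagonal_symmetry_and_range(self, rng):
        bold = BoldSeries(values=rng.standard_normal((4, 400)), dt_s=2.0)
        fcd = fcd_matrix(bold, window_s=60.0, overlap_s=56.0)
        v = fcd.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= -1.0 and v.max() <= 1.0


class TestCommuteDistance:
    def test_two_node_unit_edge(self):
        c = commute_distance(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert c[0, 1] == pytest.approx(2.0)

    def test_unit_triangle_all_pairs_four(self):
        W = np.ones((3, 3)) - np.eye(3)
        c = commute_distance(W)
        off = c[np.triu_indices(3, 1)]
        assert np.allclose(off, 4.0)

    def test_self_distance_zero(self, rng):
        W = random_connected_affinity(rng, 6)
        assert np.all(np.diag(commute_distance(W)) == 0)

    def test_disconnected_graph_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(AnalysisError, match="components"):
            commute_distance(W)


class TestSpectralEmbedding:
    def test_embedding_reproduces_commute_distance(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            W = random_connected_affinity(rng, n)
            c = commute_distance(W)
            z = spectral_embedding(W).coordinates
            d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
            assert np.allclose(d2, c, atol=1e-8)

    def test_node_permutation_permutes_rows(self, rng):
        W = random_connected_affinity(rng, 7)
        perm = rng.permutation(7)
        z = spectral_embedding(W).coordinates
        zp = spectral_embedding(W[np.ix_(perm, perm)]).coordinates
        d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
        d2p = ((zp[:, None, :] - zp[None, :, :]) ** 2).sum(-1)
        assert np.allclose(d2p, d2[np.ix_(perm, perm)], atol=1e-8)

    def test_disconnected_affinity_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(AnalysisError, match="components"):
            spectral_embedding(W)


class TestSegmentEpochs:
    def test_two_perfect_blocks_split_at_block_edge(self):
        n = 40
        W = np.zeros((n, n))
        W[:20, :20] = 0.9
        W[20:, 20:] = 0.9
        W[19, 20] = W[20, 19] = 0.3  # faint link keeps the graph connected
        np.fill_diagonal(W, 1.0)
        centers = np.arange(n, dtype=float)
        epochs = segment_epochs(spectral_embedding(W), centers, seed=0)
        assert len(epochs) == 2
        assert epochs.epochs[0].end_s == 19.0
        assert epochs.epochs[1].start_s == 20.0

    def test_uniform_fcd_is_single_epoch(self):
        W = np.full((30, 30), 0.95)
        np.fill_diagonal(W, 1.0)
        epochs = segment_epochs(spectral_embedding(W), np.arange(30.0), seed=0)
        assert len(epochs) == 1
        assert epochs.epochs[0].start_s == 0.0
        assert epochs.epochs[0].end_s == 29.0

    def test_planted_three_state_schedule_recovered(self):
        bold, truth = make_switching_bold(
            schedule=((0, 400.0), (1, 400.0), (2, 400.0)), seed=9
        )
        fcd = fcd_matrix(bold)
        epochs = segment_epochs(spectral_embedding(fcd), fcd.window_centers_s, seed=0)
        assert len(epochs) == 3

    def test_short_runs_are_absorbed(self):
        from mousebrainsim.analysis import _smooth_runs

        labels = np.array([0] * 10 + [1] * 2 + [0] * 10)
        assert np.all(_smooth_runs(labels, 3) == 0)


class TestFunctionalHubs:
    def test_densely_correlated_region_is_top_hub(self, rng):
        n = 8
        fc = np.full((n, n), 0.1)
        fc[0, :] = fc[:, 0] = 0.9
        np.fill_diagonal(fc, 1.0)
        report = functional_hubs(fc)
        lead = report.eigenvectors[:, 0]
        assert np.argmax(np.abs(lead)) == 0
        assert report.hub_masks[0, 0]

    def test_leading_vector_matches_power_iteration(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            A = rng.random((n, n))
            fc = 0.5 * (A + A.T) + n * np.eye(n)  # diagonally shifted -> PSD-ish
            report = functional_hubs(fc, n_vectors=1)
            v = rng.random(n)
            for _ in range(3000):
                v = fc @ v
                v /= np.linalg.norm(v)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(np.abs(v), np.abs(report.eigenvectors[:, 0]), atol=1e-6)

    def test_identity_fc_flagged_degenerate(self):
        report = functional_hubs(np.eye(5))
        assert report.degenerate
        assert report.eigenvectors.shape[1] == 5  # all tied vectors reported

    def test_frac_one_keeps_only_argmax(self, rng):
        A = rng.random((6, 6))
        fc = 0.5 * (A + A.T)
        np.fill_diagonal(fc, 1.0)
        report = functional_hubs(fc, frac=1.0)
        assert report.hub_masks[:, 0].sum() == 1

    def test_eigenvalues_sorted_descending(self, rng):
        A = rng.random((7, 7))
        fc = 0.5 * (A + A.T)
        report = functional_hubs(fc)
        assert np.all(np.diff(report.eigenvalues) <= 0)

    def test_hub_volume_painting(self):
        conn = make_connectome(4, seed=0, with_volume=True)
        fc = np.full((4, 4), 0.5)
        np.fill_diagonal(fc, 1.0)
        report = functional_hubs(fc, n_vectors=1)
        vol = hub_volume(conn, report)
        assert vol.shape == conn.volume.shape
        assert np.all(vol[conn.volume == -1] == -1)
        idx = conn.volume[conn.volume >= 0]
        assert np.allclose(
            vol[conn.volume >= 0], np.abs(report.eigenvectors[idx, 0])
        )


class TestSeizureOnsetLatency:
    def test_group_mean_and_difference(self):
        sim = make_onset_series([500.0, 1000.0, 2000.0], duration_ms=5000.0, seed=1)
        report = seizure_onset_latency(
            sim,
            {"EZ": ["N00"], "distal": ["N01", "N02"]},
            ez_labels=["N00"],
        )
        assert report.table.loc["EZ", "latency_s"] == pytest.approx(0.0)
        assert report.table.loc["distal", "latency_s"] == pytest.approx(1.0, abs=0.002)

    def test_onsets_recovered_within_one_sample(self):
        onsets = [250.0, 1250.0, 3333.0]
        sim = make_onset_series(onsets, duration_ms=6000.0, seed=2)
        report = seizure_onset_latency(sim, {"all": list(sim.region_labels)}, ["N00"])
        for lab, true in zip(sim.region_labels, onsets):
            assert abs(report.node_onsets_ms[lab] - true) <= sim.dt_effective

    def test_node_never_seizing_flagged_absent(self):
        sim = make_onset_series([400.0, None], duration_ms=3000.0, seed=3)
        report = seizure_onset_latency(
            sim, {"grp": ["N00", "N01"]}, ez_labels=["N00"]
        )
        assert report.node_onsets_ms["N01"] is None
        assert report.table.loc["grp", "n_absent"] == 1
        # the absent node is excluded from the group mean
        assert report.table.loc["grp", "onset_s"] == pytest.approx(0.4, abs=0.002)

    def test_silent_ez_is_error(self):
        sim = make_onset_series([None, 500.0], duration_ms=3000.0, seed=4)
        with pytest.raises(AnalysisError, match="epileptogenic"):
            seizure_onset_latency(sim, {"g": ["N01"]}, ez_labels=["N00"])

    def test_latency_invariant_to_time_shift(self):
        sim = make_onset_series([500.0, 1500.0], duration_ms=4000.0, seed=5)
        shifted = make_onset_series([1500.0, 2500.0], duration_ms=5000.0, seed=5)
        groups = {"a": ["N00"], "b": ["N01"]}
        r1 = seizure_onset_latency(sim, groups, ["N00"])
        r2 = seizure_onset_latency(shifted, groups, ["N00"])
        assert r1.table["latency_s"].values == pytest.approx(
            r2.table["latency_s"].values, abs=0.002
        )


class TestSeizureCycleCounter:
    def test_counts_complete_cycles(self):
        dt = 1.0
        t = np.arange(0, 20_000.0, dt)
        x = np.full_like(t, -1.6)
        for start in (3000, 9000, 15_000):
            x[start : start + 2000] = 0.5
        assert count_seizure_cycles(x, dt) == 3

    def test_flat_equilibrium_has_no_cycles(self):
        x = np.full(10_000, -1.4)
        assert count_seizure_cycles(x, 1.0) == 0

    def test_incomplete_final_onset_not_counted(self):
        x = np.full(10_000, -1.6)
        x[8000:] = 0.5  # rises but never comes back down
        assert count_seizure_cycles(x, 1.0) == 0
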