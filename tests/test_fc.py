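import numpy as np
import pytest

from cascadenet.fc import (
    DegenerateInputError, dfc_edge, dfc_windowed, edge_timeseries,
    event_correlation_distributions, functional_hubs, partition_events,
    pca_modes, rss, sort_dfc_by_rss, static_fc, switching_index,
)
from .conftest import make_bold


def brute_force_corr_cols(X):
    """Independent oracle: pairwise Pearson of columns by explicit loops."""
    T = X.shape[1]
    M = np.empty((T, T))
    for i in range(T):
        for j in range(T):
            a, b = X[:, i], X[:, j]
            M[i, j] = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
    return M


class TestEdgeSeries:
    def test_edge_mean_equals_pearson_identity(self, correlated_bold):
        E = edge_timeseries(correlated_bold)
        fc = static_fc(correlated_bold)
        for (n, m), row in zip(E.edge_index, E.E):
            assert abs(row.mean() - fc[n, m]) < 1e-10

    def test_duplicated_and_mirrored_regions(self):
        x = np.array([1.0, -2.0, 3.0, 0.5, -1.5])
        B = make_bold(np.vstack([x, x, -x]))
        E = edge_timeseries(B)
        means = {e: row.mean() for e, row in zip(E.edge_index, E.E)}
        assert means[(0, 1)] == pytest.approx(1.0, abs=1e-12)
        assert means[(0, 2)] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_region_rejected(self):
        B = make_bold([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(DegenerateInputError, match="region 0"):
            edge_timeseries(B)

    def test_row_count(self, correlated_bold):
        E = edge_timeseries(correlated_bold)
        n = correlated_bold.n_regions
        assert E.E.shape[0] == n * (n - 1) // 2


class TestStaticFC:
    def test_printed_toy(self):
        B = make_bold([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        np.testing.assert_allclose(static_fc(B), [[1, 1], [1, 1]], atol=1e-12)

    def test_white_noise_off_diagonal_near_zero(self, rng):
        T = 4000
        B = make_bold(rng.normal(size=(4, T)))
        fc = static_fc(B)
        off = fc[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(T))

    def test_matches_edge_time_average(self, correlated_bold):
        E = edge_timeseries(correlated_bold)
        fc = static_fc(correlated_bold)
        for (n, m), row in zip(E.edge_index, E.E):
            assert fc[n, m] == pytest.approx(row.mean(), abs=1e-12)


class TestDfc:
    def test_edge_variant_against_brute_force(self, rng):
        X = rng.normal(size=(10, 20))  # 5 regions -> 10 edges, 20 frames
        from cascadenet.fc import EdgeSeries
        E = EdgeSeries(E=X, edge_index=[(0, 0)] * 10, TR=2.0, n_regions=5)
        M = dfc_edge(E).M
        np.testing.assert_allclose(M, brute_force_corr_cols(X), atol=1e-12)

    def test_duplicated_frame_and_diagonal(self, rng):
        X = rng.normal(size=(6, 5))
        X[:, 3] = X[:, 1]
        from cascadenet.fc import EdgeSeries
        E = EdgeSeries(E=X, edge_index=[], TR=2.0, n_regions=4)
        M = dfc_edge(E).M
        assert M[1, 3] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M, M.T, atol=1e-14)
        assert np.all((M >= -1 - 1e-12) & (M <= 1 + 1e-12))

    def test_windowed_against_brute_force(self, rng):
        B = make_bold(rng.normal(size=(4, 70)), TR=2.0)
        M = dfc_windowed(B, window=20.0, step=4.0)
        wlen, wstep = 10, 2
        starts = list(range(0, 70 - wlen + 1, wstep))
        vecs = []
        for s in starts:
            fc = np.corrcoef(B.B[:, s:s + wlen])
            iu, ju = np.triu_indices(4, k=1)
            vecs.append(fc[iu, ju])
        expect = np.corrcoef(np.array(vecs))
        np.testing.assert_allclose(M.M, expect, atol=1e-10)
        assert M.M.shape == (len(starts),) * 2

    def test_periodic_signal_gives_all_ones_and_zero_switching(self, rng):
        period = 2  # frames; equal to the window step at TR=2, step=4s... use step=period*TR
        base = rng.normal(size=(3, period))
        B = make_bold(np.tile(base, (1, 40)), TR=2.0)
        M = dfc_windowed(B, window=16.0, step=period * 2.0)
        np.testing.assert_allclose(M.M, 1.0, atol=1e-10)
        assert switching_index(M) == pytest.approx(0.0, abs=1e-20)


class TestSwitchingIndex:
    def test_hand_computed_variance(self):
        from cascadenet.fc import DFCMatrix
        M = np.eye(4)
        iu, ju = np.triu_indices(4, k=1)
        M[iu, ju] = M[ju, iu] = [0, 1, 0, 1, 0, 1]
        d = DFCMatrix(M=M, variant="windowed")
        assert switching_index(d) == pytest.approx(0.25)
        dT = DFCMatrix(M=M.T, variant="windowed")
        assert switching_index(dT) == switching_index(d)

    def test_degenerate_sizes(self):
        from cascadenet.fc import DFCMatrix
        assert switching_index(DFCMatrix(M=np.ones((1, 1)), variant="windowed")) == 0.0
        assert switching_index(DFCMatrix(M=np.ones((5, 5)), variant="windowed")) == 0.0


class TestRssAndEvents:
    def test_rss_hand_values(self):
        from cascadenet.fc import EdgeSeries
        E = EdgeSeries(E=np.array([[0.0, 3.0], [0.0, 0.0]]), edge_index=[],
                       TR=2.0, n_regions=2)
        np.testing.assert_allclose(rss(E), [0.0, 3.0])

    def test_rss_homogeneity(self, rng):
        from cascadenet.fc import EdgeSeries
        X = rng.normal(size=(6, 9))
        E1 = EdgeSeries(E=X, edge_index=[], TR=2.0, n_regions=4)
        E2 = EdgeSeries(E=-2.5 * X, edge_index=[], TR=2.0, n_regions=4)
        np.testing.assert_allclose(rss(E2), 2.5 * rss(E1), atol=1e-12)

    def test_partition_order_statistics(self):
        part = partition_events(np.arange(100.0), percentile=98.0)
        assert part.event_frames.size == 2
        assert part.event_frames.tolist() == [98, 99]
        assert part.event_frames.size + part.nonevent_frames.size == 100

    def test_constant_rss_yields_no_events(self):
        part = partition_events(np.full(50, 7.0))
        assert part.event_frames.size == 0

    def test_event_correlation_grouping(self, rng):
        from cascadenet.fc import EdgeSeries
        X = rng.normal(size=(10, 50))
        E = EdgeSeries(E=X, edge_index=[], TR=2.0, n_regions=5)
        part = partition_events(rss(E), percentile=90.0)
        k = part.event_frames.size
        out = event_correlation_distributions(E, part)
        assert out["within_events"]["n"] == k * (k - 1) // 2
        assert out["events_nonevents"]["n"] == k * (50 - k)

    def test_identical_frames_degenerate_at_one(self):
        from cascadenet.fc import EdgeSeries
        X = np.tile(np.array([[1.0], [2.0], [-1.0]]), (1, 12))
        E = EdgeSeries(E=X, edge_index=[], TR=2.0, n_regions=3)
        part = partition_events(rss(E), percentile=50.0)
        out = event_correlation_distributions(E, part)
        sample = out["within_nonevents"]["sample"]
        assert np.allclose(sample, 1.0)


class TestHubsAndPca:
    def test_rank_one_recovery(self, rng):
        z = rng.normal(size=6)
        A = np.outer(z, z)
        iu, ju = np.triu_indices(6, k=1)
        lead, val, ratio = functional_hubs(A[iu, ju], 6)
        cos = abs(np.dot(lead, z)) / np.linalg.norm(z)
        assert cos > 0.99
        assert val > 0 and 0 < ratio <= 1

    def test_identity_frame_flagged_degenerate(self):
        lead, _, _ = functional_hubs(np.zeros(15), 6)
        assert lead is None

    def test_power_iteration_oracle(self, rng):
        z = rng.normal(size=6)
        A = np.outer(z, z) + 0.1 * np.eye(6)
        iu, ju = np.triu_indices(6, k=1)
        lead, _, _ = functional_hubs(A[iu, ju], 6)
        # brute-force power iteration on the reshaped matrix
        M = np.eye(6)
        M[iu, ju] = M[ju, iu] = A[iu, ju]
        v = np.ones(6)
        for _ in range(500):
            v = M @ v
            v /= np.linalg.norm(v)
        assert abs(abs(v @ lead) - 1) < 1e-6

    def test_pca_ratios_and_rank_one(self, rng):
        X = rng.normal(size=(5, 40))
        _, ratios = pca_modes(X, mode="global")
        assert ratios.sum() == pytest.approx(1.0)
        z = rng.normal(size=5)
        X1 = np.outer(z, rng.normal(size=40))
        _, r1 = pca_modes(X1, mode="global")
        assert r1[0] == pytest.approx(1.0)

    def test_pca_covariance_oracle(self, rng):
        X = rng.normal(size=(5, 60))
        comps, ratios = pca_modes(X, mode="global")
        C = np.cov(X, bias=False)
        vals, vecs = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1]
        np.testing.assert_allclose(ratios, vals[order] / vals.sum(), atol=1e-10)
        for k in range(3):
            cos = abs(np.dot(comps[k], vecs[:, order[k]]))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_windowed_mode_shapes(self, rng):
        X = rng.normal(size=(4, 1000))
        loadings, ratios = pca_modes(X, mode="windowed", window_s=0.1, rate_hz=1000.0)
        assert loadings.shape == (10, 4)
        assert np.all((ratios > 0) & (ratios <= 1))


class TestSortByRss:
    def test_identity_and_inverse(self, rng):
        from cascadenet.fc import DFCMatrix
        A = rng.normal(size=(6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        M = DFCMatrix(M=A, variant="edge")
        sortedM, perm = sort_dfc_by_rss(M, np.arange(6.0))
        np.testing.assert_array_equal(sortedM.M, A)
        r = rng.random(6)
        sortedM, perm = sort_dfc_by_rss(M, r)
        inv = np.argsort(perm)
        np.testing.assert_array_equal(sortedM.M[np.ix_(inv, inv)], A)
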