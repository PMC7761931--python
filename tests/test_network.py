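"""Weighted graph metrics against brute-force oracles, and feature assembly."""

import numpy as np
import pytest

from srcnet import (
    ConnectivityMatrix,
    assemble_features,
    char_path_length,
    get_band,
    global_clustering,
    local_clustering,
)


def brute_local_cc(w):
    """Independent oracle: triangle enumeration of the geometric-mean weighted CC."""
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    n = len(w)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    cc = np.zeros(n)
    for u in range(n):
        k = int((w[u] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for v in range(n):
            for x in range(n):
                if v != u and x != u and v != x:
                    s += (wn[u, v] * wn[u, x] * wn[v, x]) ** (1.0 / 3.0)
        cc[u] = s / (k * (k - 1))
    return cc


def brute_path_lengths(w):
    """Independent oracle: Floyd-Warshall exhaustive relaxation on lengths 1/w."""
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def complete_graph(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return w


class TestClustering:
    def test_complete_unit_graph(self):
        assert np.allclose(local_clustering(complete_graph(4)), 1.0)
        assert global_clustering(complete_graph(4)) == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert np.allclose(local_clustering(w), 0.0)
        assert global_clustering(w) == 0.0

    def test_weighted_triangle_closed_form(self):
        w = np.array([[0, 0.8, 0.5], [0.8, 0, 0.2], [0.5, 0.2, 0]])
        expected = (1.0 * 0.625 * 0.25) ** (1 / 3)  # weights rescaled by max 0.8
        cc = local_clustering(w)
        assert np.allclose(cc, expected, atol=1e-12)
        assert global_clustering(w) == pytest.approx(expected)
        assert expected == pytest.approx(0.5386, abs=5e-4)

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            cc = local_clustering(np.zeros((4, 4)))
        assert np.all(cc == 0)

    def test_weight_scaling_invariance(self, rng):
        w = rng.uniform(0.1, 1.0, (7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        np.testing.assert_allclose(local_clustering(w), local_clustering(5.0 * w), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        w = rng.uniform(0, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            local_clustering(w)[perm], local_clustering(w[np.ix_(perm, perm)]), atol=1e-12
        )

    def test_values_in_unit_interval(self, rng):
        for _ in range(10):
            w = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) > 0.3)
            w = (w + w.T) / 2
            cc = local_clustering(w) if w.max() > 0 else np.zeros(8)
            assert np.all((cc >= 0) & (cc <= 1 + 1e-12))


class TestPathLength:
    def test_complete_unit_graph(self):
        assert char_path_length(complete_graph(5)) == pytest.approx(1.0)

    def test_three_node_chain(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert char_path_length(w) == pytest.approx(4 / 3)  # distances {1,1,2}

    def test_chain_scales_inverse_weight(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 0.5
        assert char_path_length(w) == pytest.approx(8 / 3)

    def test_sum_mode(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        assert char_path_length(w, mode="sum") == pytest.approx(4.0)

    def test_disconnected_warns_mean_over_reachable(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0  # nodes 2, 3 isolated
        with pytest.warns(UserWarning):
            assert char_path_length(w) == pytest.approx(1.0)

    def test_path_scaling_inverse_of_weights(self, rng):
        w = rng.uniform(0.2, 1.0, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        assert char_path_length(2.0 * w) == pytest.approx(char_path_length(w) / 2.0)


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self, rng):
        """Pipeline metrics equal exhaustive triangle/path enumeration on random graphs."""
        for trial in range(25):
            w = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) > 0.25)
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            if w.max() == 0:
                continue
            np.testing.assert_allclose(local_clustering(w), brute_local_cc(w), atol=1e-10)
            d = brute_path_lengths(w)
            iu = np.triu_indices(8, k=1)
            finite = np.isfinite(d[iu])
            if finite.all():
                assert char_path_length(w) == pytest.approx(float(d[iu].mean()), abs=1e-10)

    def test_matches_networkx_convention(self, rng):
        nx = pytest.importorskip("networkx")
        w = rng.uniform(0.1, 1.0, (7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = nx.from_numpy_array(w)
        nx_cc = np.array([nx.clustering(g, weight="weight")[i] for i in range(7)])
        np.testing.assert_allclose(local_clustering(w), nx_cc, atol=1e-10)


def make_matrix(n, band_name, rng):
    w = rng.uniform(0.05, 1.0, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(values=w, band=get_band(band_name))


class TestAssembleFeatures:
    def test_length_formula(self, rng):
        mats = [make_matrix(10, b, rng) for b in ("alpha", "beta")]
        fv = assemble_features(mats)
        assert len(fv) == 10 * 2 + 2 * 2

    def test_full_scale_dimensionality(self, rng):
        # 148 nodes x 11 bands -> 1650 features, from the index alone
        bands = [b.name for b in __import__("srcnet").band_table()]
        mats = [make_matrix(148, b, rng) for b in bands[:1]]
        fv = assemble_features(mats)
        assert len(fv) == 150  # one band: 148 + 2
        assert 148 * 11 + 2 * 11 == 1650

    def test_index_order(self, rng):
        mats = [make_matrix(3, b, rng) for b in ("alpha", "beta")]
        fv = assemble_features(mats)
        kinds = [k for _, k, _ in fv.index]
        assert kinds == ["local_cc"] * 3 + ["global_cc", "path_length"] + \
            ["local_cc"] * 3 + ["global_cc", "path_length"]
        assert fv.names()[0].startswith("alpha__local_cc__")

    def test_single_node_rejected(self, rng):
        w = np.ones((1, 1))
        mat = ConnectivityMatrix(values=w, band=get_band("alpha"))
        with pytest.raises(ValueError):
            assemble_features([mat])

    def test_inconsistent_node_sets(self, rng):
        with pytest.raises(ValueError):
            assemble_features([make_matrix(4, "alpha", rng), make_matrix(5, "beta", rng)])

    def test_values_match_direct_metric_calls(self, rng):
        mat = make_matrix(5, "alpha", rng)
        fv = assemble_features([mat])
        np.testing.assert_allclose(fv.values[:5], local_clustering(mat))
        assert fv.values[5] == pytest.approx(global_clustering(mat))
        assert fv.values[6] == pytest.approx(char_path_length(mat))
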