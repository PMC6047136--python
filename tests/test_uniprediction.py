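import math

import numpy as np
import pytest

from netlinkpred import (
    ConvergenceError,
    NEIGHBORHOOD_METHODS,
    UnipartiteGraph,
    geodesic_score,
    hitting_time,
    katz_score,
    local_path_score,
    neighborhood_score,
    rwr_unipartite,
)
from conftest import random_unipartite


def brute_neighborhood(g, method, x, y):
    """Set-based reference implementation of the nine neighborhood indices."""
    A = g.binary()
    nbrs = [set(np.nonzero(A[i])[0]) for i in range(g.n_nodes)]
    C = nbrs[x] & nbrs[y]
    kx, ky = len(nbrs[x]), len(nbrs[y])

    def ratio(num, den):
        return num / den if den else 0.0

    if method == "common_neighbors":
        return float(len(C))
    if method == "jaccard":
        return ratio(len(C), len(nbrs[x] | nbrs[y]))
    if method == "cosine":
        return ratio(len(C), math.sqrt(kx * ky))
    if method == "hpi":
        return ratio(len(C), min(kx, ky))
    if method == "hdi":
        return ratio(len(C), max(kx, ky))
    if method == "adamic_adar":
        return sum(1.0 / math.log(len(nbrs[z])) for z in C if len(nbrs[z]) > 1)
    if method == "pref_attach":
        return float(kx * ky)
    if method == "resource_alloc":
        return sum(1.0 / len(nbrs[z]) for z in C if len(nbrs[z]) > 0)
    return ratio(len(C), kx * ky)  # lhn


class TestNeighborhood:
    def test_cycle_pair_values(self, cycle4):
        i, j = 0, 2  # opposite corners a, c
        expected = {"common_neighbors": 2, "jaccard": 1.0, "resource_alloc": 1.0,
                    "pref_attach": 4, "lhn": 0.5, "hpi": 1.0}
        for method, val in expected.items():
            S = neighborhood_score(cycle4, method).values
            assert S[i, j] == pytest.approx(val), method

    def test_path_pair_values(self, path3):
        for method, val in {"common_neighbors": 1, "cosine": 1.0, "hdi": 1.0}.items():
            assert neighborhood_score(path3, method).values[0, 2] == pytest.approx(val)

    @pytest.mark.parametrize("method", NEIGHBORHOOD_METHODS)
    def test_symmetry_and_finiteness(self, method):
        rng = np.random.default_rng(17)
        for _ in range(5):
            g = random_unipartite(rng, n_max=15)
            S = neighborhood_score(g, method).values
            assert np.allclose(S, S.T)
            assert np.isfinite(S).all()

    @pytest.mark.parametrize("method", NEIGHBORHOOD_METHODS)
    def test_matches_set_based_brute_force(self, method):
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = random_unipartite(rng, n_max=12)
            S = neighborhood_score(g, method).values
            for x in range(g.n_nodes):
                for y in range(g.n_nodes):
                    if x == y:
                        continue
                    assert S[x, y] == pytest.approx(
                        brute_neighborhood(g, method, x, y)
                    ), (method, x, y)

    def test_isolated_nodes_score_zero_not_nan(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1
        g = UnipartiteGraph(adj, ["a", "b", "iso"])
        for method in NEIGHBORHOOD_METHODS:
            S = neighborhood_score(g, method).values
            assert np.isfinite(S).all()
            if method != "pref_attach":
                assert S[0, 2] == 0.0


class TestLocalPath:
    def test_path_graph(self, path3):
        S = local_path_score(path3, epsilon=0.01).values
        assert S[0, 2] == pytest.approx(1.0)  # one 2-path, zero 3-paths

    def test_cycle_adjacent_pair(self, cycle4):
        eps = 0.05
        S = local_path_score(cycle4, epsilon=eps).values
        # A2(a,b)=0; A3(a,b)=4 length-3 walks (a-b-a-b, a-d-a-b, a-b-c-b, a-d-c-b)
        assert S[0, 1] == pytest.approx(4 * eps)

    def test_epsilon_zero_is_common_neighbors(self):
        rng = np.random.default_rng(2)
        g = random_unipartite(rng, n_max=15)
        S0 = local_path_score(g, epsilon=0.0).values
        CN = neighborhood_score(g, "common_neighbors").values
        off = ~np.eye(g.n_nodes, dtype=bool)
        np.testing.assert_allclose(S0[off], CN[off])


class TestKatz:
    def test_single_edge_closed_form(self):
        g = UnipartiteGraph(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        S = katz_score(g, beta=0.1).values
        assert S[0, 1] == pytest.approx(0.1 / (1 - 0.01))

    def test_matches_truncated_series(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g = random_unipartite(rng, n_max=12)
            A = g.binary()
            rho = max(np.abs(np.linalg.eigvalsh(A)))
            if rho == 0:
                continue
            beta = 0.5 / rho
            S = katz_score(g, beta=beta).values
            series = np.zeros_like(A)
            Ak = np.eye(A.shape[0])
            for _l in range(1, 60):
                Ak = Ak @ A
                series += beta**_l * Ak
            np.testing.assert_allclose(S, series, atol=1e-8)

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(9)
        g = random_unipartite(rng, n_max=10)
        rho = max(np.abs(np.linalg.eigvalsh(g.binary())))
        S1 = katz_score(g, beta=0.2 / rho).values
        S2 = katz_score(g, beta=0.4 / rho).values
        assert (S2 - S1 >= -1e-12).all()

    def test_divergent_beta_reports_bound(self, cycle4):
        with pytest.raises(ValueError, match="spectral radius"):
            katz_score(cycle4, beta=0.6)


class TestGeodesic:
    def test_inverse_distance(self, path3):
        S = geodesic_score(path3).values
        assert S[0, 2] == pytest.approx(0.5)
        assert S[0, 1] == pytest.approx(1.0)

    def test_disconnected_scores_zero(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        g = UnipartiteGraph(adj, list("abcd"))
        assert geodesic_score(g).values[0, 2] == 0.0

    def test_weighted_distances(self):
        adj = np.array([[0, 2.0, 0], [2.0, 0, 3.0], [0, 3.0, 0]])
        g = UnipartiteGraph(adj, list("abc"), weighted=True)
        assert geodesic_score(g).values[0, 2] == pytest.approx(1 / 5.0)


class TestHittingTime:
    def test_path3_exact(self, path3):
        H = hitting_time(path3).values
        assert H[0, 1] == pytest.approx(1.0)
        assert H[1, 2] == pytest.approx(3.0)
        assert H[0, 2] == pytest.approx(4.0)

    def test_path_additivity(self, path3):
        H = hitting_time(path3).values
        assert H[0, 2] == pytest.approx(H[0, 1] + H[1, 2])

    def test_single_edge_forced_move(self):
        g = UnipartiteGraph(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        H = hitting_time(g).values
        assert H[0, 1] == 1.0 and H[1, 0] == 1.0

    def test_cross_component_is_infinite(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1
        g = UnipartiteGraph(adj, ["a", "b", "iso"])
        H = hitting_time(g).values
        assert np.isinf(H[0, 2]) and np.isinf(H[2, 0])

    def test_matches_monte_carlo(self, cycle4):
        H = hitting_time(cycle4).values
        A = cycle4.binary()
        nbrs = np.array([np.nonzero(A[i])[0] for i in range(4)])  # 2 nbrs each
        rng = np.random.default_rng(12)
        n_walks = 100_000
        pos = np.zeros(n_walks, dtype=int)  # start at node 0
        steps = np.zeros(n_walks)
        active = np.ones(n_walks, dtype=bool)
        target = 2
        for _ in range(10_000):
            if not active.any():
                break
            choice = rng.integers(2, size=active.sum())
            pos[active] = nbrs[pos[active], choice]
            steps[active] += 1
            active &= pos != target
        mean, se = steps.mean(), steps.std(ddof=1) / np.sqrt(n_walks)
        assert abs(H[0, target] - mean) < 3 * se


class TestRWR:
    def test_two_state_fixed_point(self):
        g = UnipartiteGraph(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        P = rwr_unipartite(g, c=0.5).values
        np.testing.assert_allclose(P[:, 0], [2 / 3, 1 / 3], atol=1e-8)

    def test_high_restart_concentrates_at_start(self, cycle4):
        P = rwr_unipartite(cycle4, c=0.999).values
        assert (np.diag(P) > 0.99).all()

    def test_columns_are_probability_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            g = random_unipartite(rng, n_max=20)
            P = rwr_unipartite(g, c=0.3).values
            assert (P >= -1e-12).all()
            np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-8)

    def test_fixed_point_residual(self, cycle4):
        c = 0.3
        P = rwr_unipartite(cycle4, c=c, tol=1e-12).values
        A = cycle4.binary()
        W = A / A.sum(axis=1, keepdims=True)
        resid = np.abs(P - (1 - c) * W.T @ P - c * np.eye(4)).sum(axis=0)
        assert (resid < 1e-9).all()

    def test_nonconvergence_reports_residual(self, cycle4):
        with pytest.raises(ConvergenceError, match="residual"):
            rwr_unipartite(cycle4, c=0.01, tol=1e-15, max_iter=2)

    def test_invalid_restart_probability(self, cycle4):
        with pytest.raises(ValueError):
            rwr_unipartite(cycle4, c=1.5)
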