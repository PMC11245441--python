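"""Bundle-level score matrices, network reconstruction and evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mlbundle as mb
from mlbundle.bundlenet import BundleNetwork
from mlbundle.spectral import AffinityPair

from conftest import random_regimes


def wrap_affinity(A):
    return AffinityPair(correlation=A, affinity=A)


def random_affinity(rng, n):
    A = rng.uniform(size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


def regimes_and_layer(rng, n, k, r):
    counts = rng.integers(1, 6, size=r).tolist()
    regimes = random_regimes(rng, n, counts)
    return regimes, mb.form_bundles(regimes, k)


def H_bruteforce(A, layer):
    N = layer.n_bundles
    H = np.zeros((N, N))
    for x in range(N):
        for y in range(N):
            total = 0.0
            for i in layer.bundles[x]:
                for j in layer.bundles[y]:
                    total += A[i, j]
            H[x, y] = total / (len(layer.bundles[x]) * len(layer.bundles[y]))
    return H


def L_bruteforce(regimes, layer, k, r):
    """Direct set-arithmetic evaluation of the co-cluster score."""
    N = layer.n_bundles
    bundles = [set(map(int, b)) for b in layer.bundles]
    L = np.zeros((N, N))
    for x in range(N):
        for y in range(N):
            if x == y:
                continue
            total = 0.0
            for regime in regimes[:k]:
                clusters = [set(map(int, c)) for c in regime.clusters()]
                for xi in clusters:
                    if bundles[x] <= xi and bundles[y] <= xi:
                        total += (len(bundles[x]) + len(bundles[y])) / len(xi)
            for regime in regimes[k:r]:
                clusters = [set(map(int, c)) for c in regime.clusters()]
                for xi in clusters:
                    nx_, ny_ = len(bundles[x] & xi), len(bundles[y] & xi)
                    if nx_ and ny_:
                        total += (nx_ + ny_) / len(xi)
            L[x, y] = total
    return L


class TestBundleAffinity:
    def test_mean_of_constant_cross_block(self):
        rng = np.random.default_rng(0)
        regimes = [mb.ClusteringRegime(1, 2, np.array([0, 0, 1, 1, 1]))]
        layer = mb.form_bundles(regimes, 1)
        A = np.full((5, 5), 0.5)
        np.fill_diagonal(A, 0.0)
        H = mb.bundle_affinity_matrix(wrap_affinity(A), layer)
        x, y = layer.labels[3], layer.labels[0]
        assert H[x, y] == pytest.approx(0.5)  # mean of six 0.5 entries

    def test_singleton_bundles_copy_affinity(self):
        regimes = [mb.ClusteringRegime(1, 2, np.array([0, 1]))]
        layer = mb.form_bundles(regimes, 1)
        A = np.array([[0.0, 0.7], [0.7, 0.0]])
        H = mb.bundle_affinity_matrix(wrap_affinity(A), layer)
        assert H[0, 1] == pytest.approx(0.7)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(5, 31))
            regimes, layer = regimes_and_layer(rng, n, k=2, r=2)
            A = random_affinity(rng, n)
            H = mb.bundle_affinity_matrix(wrap_affinity(A), layer)
            np.testing.assert_allclose(
                H, H_bruteforce(A, layer), atol=1e-12
            )

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n = 20
        regimes, layer = regimes_and_layer(rng, n, k=2, r=2)
        A = random_affinity(rng, n)
        H = mb.bundle_affinity_matrix(wrap_affinity(A), layer)
        perm = rng.permutation(n)
        regimes_p = [
            mb.ClusteringRegime(r.rank, r.n_clusters, r.labels[perm])
            for r in regimes
        ]
        layer_p = mb.form_bundles(regimes_p, 2)
        H_p = mb.bundle_affinity_matrix(
            wrap_affinity(A[np.ix_(perm, perm)]), layer_p
        )
        # canonical bundle ordering can differ; compare as dictionaries
        # keyed by member sets
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)

        def key(bundle, mapping=None):
            ids = bundle if mapping is None else mapping[bundle]
            return frozenset(map(int, ids))

        lut = {key(b): i for i, b in enumerate(layer.bundles)}
        for bx, x in enumerate(layer_p.bundles):
            for by, y in enumerate(layer_p.bundles):
                ox, oy = lut[key(perm[x])], lut[key(perm[y])]
                assert H_p[bx, by] == pytest.approx(H[ox, oy], abs=1e-12)


class TestCoClusterMatrix:
    def test_worked_six_node_example(self):
        # regime 1: everything together; regime 2 splits in half (the
        # layer-2 bundles); regime 3 pairs features across the split
        regimes = [
            mb.ClusteringRegime(1, 1, np.array([0, 0, 0, 0, 0, 0])),
            mb.ClusteringRegime(2, 2, np.array([0, 0, 0, 1, 1, 1])),
            mb.ClusteringRegime(3, 3, np.array([0, 0, 1, 1, 2, 2])),
        ]
        layer = mb.form_bundles(regimes, 2)
        L = mb.bundle_cocluster_matrix(regimes, layer, k=2, r=3)
        # (3+3)/6 at regime 1 + 0 at regime 2 + (1+1)/2 from the straddling
        # pair at regime 3
        assert L[0, 1] == pytest.approx(2.0)
        assert L[0, 0] == 0.0 and L[1, 1] == 0.0

    def test_horizon_equal_to_layer_drops_second_sum(self):
        regimes = [
            mb.ClusteringRegime(1, 1, np.zeros(6, dtype=int)),
            mb.ClusteringRegime(2, 2, np.array([0, 0, 0, 1, 1, 1])),
        ]
        layer = mb.form_bundles(regimes, 2)
        L = mb.bundle_cocluster_matrix(regimes, layer, k=2, r=2)
        assert L[0, 1] == pytest.approx(6 / 6)  # regime-1 term only

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 31))
            k = int(rng.integers(1, 4))
            r = int(rng.integers(k, 6))
            regimes, layer = regimes_and_layer(rng, n, k=k, r=r)
            L = mb.bundle_cocluster_matrix(regimes, layer, k=k, r=r)
            np.testing.assert_allclose(
                L, L_bruteforce(regimes, layer, k, r), atol=1e-12
            )

    def test_bad_horizon_rejected(self):
        regimes = [mb.ClusteringRegime(1, 1, np.zeros(4, dtype=int))]
        layer = mb.form_bundles(regimes, 1)
        with pytest.raises(ValueError):
            mb.bundle_cocluster_matrix(regimes, layer, k=1, r=2)


class TestCombineScores:
    def test_proportional_matrices_preserve_network(self):
        rng = np.random.default_rng(4)
        H = random_affinity(rng, 6)
        LH = mb.combine_scores(H, 3.0 * H)
        net_h = mb.score_matrix_to_network(H, "H")
        net_lh = mb.score_matrix_to_network(LH, "LH")
        assert net_h.edges == net_lh.edges

    def test_constant_matrices_stay_flat(self):
        M = np.full((4, 4), 0.3)
        np.fill_diagonal(M, 0.0)
        out = mb.combine_scores(M, M)
        off = out[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_combined_ranking_matches_independent_normalization(self):
        rng = np.random.default_rng(5)
        H, L = random_affinity(rng, 4), random_affinity(rng, 4)

        def norm(M):
            mask = ~np.eye(4, dtype=bool)
            v = M[mask]
            out = np.zeros_like(M)
            out[mask] = (M[mask] - v.min()) / (v.max() - v.min())
            return out

        expected = norm(H) + norm(L)
        got = mb.combine_scores(H, L)
        iu = np.triu_indices(4, 1)
        assert np.argsort(expected[iu]).tolist() == np.argsort(got[iu]).tolist()


class TestScoreToNetwork:
    def test_hand_trace_connected_after_step_one(self):
        # rows' maxima: 0<->1 mutual at .9; rows 2 and 3 both point at 1
        M = np.array(
            [
                [0.0, 0.9, 0.1, 0.1],
                [0.9, 0.0, 0.3, 0.2],
                [0.1, 0.3, 0.0, 0.05],
                [0.1, 0.2, 0.05, 0.0],
            ]
        )
        net = mb.score_matrix_to_network(M)
        assert net.edges == {(0, 1), (1, 2), (1, 3)}

    def test_hand_trace_step_two_merges_components(self):
        # two mutually-max pairs with weak cross entries; step 2 adds only
        # the largest cross entry
        M = np.array(
            [
                [0.0, 0.9, 0.10, 0.05],
                [0.9, 0.0, 0.06, 0.04],
                [0.10, 0.06, 0.0, 0.8],
                [0.05, 0.04, 0.8, 0.0],
            ]
        )
        net = mb.score_matrix_to_network(M)
        assert net.edges == {(0, 1), (2, 3), (0, 2)}

    def test_single_node(self):
        net = mb.score_matrix_to_network(np.zeros((1, 1)))
        assert net.n_edges == 0 and net.n_nodes == 1

    @given(st.integers(0, 2**31 - 1))
    def test_always_one_component_and_step1_bound(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 12))
        M = random_affinity(rng, N)
        net = mb.score_matrix_to_network(M)
        g = net.to_networkx()
        assert nx.number_connected_components(g) == 1
        # step-1 edges alone (row maxima) never cycle
        masked = M.copy()
        np.fill_diagonal(masked, -np.inf)
        step1 = {
            (min(i, int(np.argmax(masked[i]))), max(i, int(np.argmax(masked[i]))))
            for i in range(N)
        }
        assert len(step1) <= N - 1


class TestTargetAndScoring:
    def test_target_shares_projection_rule(self, small_dataset):
        _, net, _, model = small_dataset
        layer = model.bundle_layer(3)
        target = mb.target_bundle_network(layer, net)
        adj = mb.project_group_adjacency(layer, net)
        expected = {
            (min(x, y), max(x, y))
            for x, nbrs in adj.items() for y in nbrs
        }
        assert set(target.edges) == expected

    def test_jaccard_examples(self):
        def bn(edges, n=4):
            return BundleNetwork(n, frozenset(edges), "H")

        assert mb.jaccard_index(bn({(0, 1)}), bn({(0, 1)})) == 1.0
        assert mb.jaccard_index(bn({(0, 1)}), bn({(2, 3)})) == 0.0
        assert mb.jaccard_index(
            bn({(0, 1), (1, 2)}), bn({(0, 1), (2, 3)})
        ) == pytest.approx(1 / 3)
        assert mb.jaccard_index(bn(set()), bn(set())) == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_jaccard_symmetry_and_classification_identities(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        pool = [(i, j) for i in range(n) for j in range(i + 1, n)]
        pick = lambda: frozenset(
            pool[i] for i in rng.choice(len(pool),
                                        size=rng.integers(0, 8),
                                        replace=False)
        )
        a = BundleNetwork(n, pick(), "H")
        b = BundleNetwork(n, pick(), "target")
        assert mb.jaccard_index(a, b) == mb.jaccard_index(b, a)
        assert (mb.jaccard_index(a, b) == 1.0) == (a.edges == b.edges)
        tp, fn, fp = mb.classify_edges(a, b)
        assert len(tp) + len(fp) == a.n_edges
        assert len(tp) + len(fn) == b.n_edges
        assert not (tp & fn) and not (tp & fp) and not (fn & fp)
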