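"""Markov clustering and the covariance-ratio modularity test."""

import networkx as nx
import numpy as np
import pytest

from coevo.modularity import (
    MarkovClustering,
    covariance_ratio,
    mcl,
    phylo_transform,
)
from coevo.phylo import vcv
from coevo.synthetic import generate_network_fixture, simulate_tree


def _clique(g, names, weight=1.0):
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            g.add_edge(a, b, weight=weight)


class TestMCL:
    def test_disjoint_triangles(self):
        g = nx.Graph()
        _clique(g, ["a1", "a2", "a3"])
        _clique(g, ["b1", "b2", "b3"])
        labels = mcl(g, rescale_weights=None)
        assert len({labels[n] for n in ("a1", "a2", "a3")}) == 1
        assert len({labels[n] for n in ("b1", "b2", "b3")}) == 1
        assert labels["a1"] != labels["b1"]

    def test_single_edge_single_module(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        labels = mcl(g, rescale_weights=None)
        assert labels["A"] == labels["B"]

    def test_weak_bridge_between_cliques_splits(self):
        g = nx.Graph()
        _clique(g, ["a%d" % i for i in range(5)], weight=1.0)
        _clique(g, ["b%d" % i for i in range(5)], weight=1.0)
        g.add_edge("a0", "b0", weight=0.01)
        labels = mcl(g, inflation=2.0, rescale_weights=None)
        mods_a = {labels["a%d" % i] for i in range(5)}
        mods_b = {labels["b%d" % i] for i in range(5)}
        assert len(mods_a) == 1 and len(mods_b) == 1
        assert mods_a != mods_b

    def test_deterministic(self):
        g, _truth = generate_network_fixture(3, 8, 0.9, 0.05, seed=4)
        a = MarkovClustering().fit(g).labels_
        b = MarkovClustering().fit(g).labels_
        assert a == b

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            mcl(nx.Graph())


class TestPhyloTransform:
    def test_star_tree_reduces_to_scaled_centering(self, tree_from_string):
        t = tree_from_string("(A:4,B:4,C:4,D:4);")
        C = vcv(t)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        Xt = phylo_transform(X, C)
        # rows are rotated, but the column covariance must match centered X / t
        got = Xt.T @ Xt
        centered = X - X.mean(axis=0)
        np.testing.assert_allclose(got, centered.T @ centered / 4.0,
                                   atol=1e-10)

    def test_constant_trait_maps_to_zero(self, star4):
        X = np.full((4, 1), 7.0)
        Xt = phylo_transform(X, vcv(star4))
        np.testing.assert_allclose(Xt, 0.0, atol=1e-12)

    def test_recovers_rate_matrix_under_bm(self, rng):
        from coevo.synthetic import simulate_pair

        t = simulate_tree(16, root_age=2.0, seed=6)
        C = vcv(t)
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        acc = np.zeros((2, 2))
        n_rep = 300
        for _ in range(n_rep):
            X = simulate_pair(C, R, rng=rng).T
            Xt = phylo_transform(X, C)
            acc += Xt.T @ Xt / Xt.shape[0]
        np.testing.assert_allclose(acc / n_rep, R, atol=0.1)

    def test_singular_covariance_errors(self):
        C = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            phylo_transform(np.eye(3), C)


class TestCovarianceRatio:
    def test_orthogonal_blocks_give_zero(self):
        # module columns drawn from disjoint orthonormal directions: the
        # cross-block sample covariance vanishes exactly
        n = 8
        rng = np.random.default_rng(1)
        M = np.column_stack([np.ones(n), rng.normal(size=(n, 5))])
        Q = np.linalg.qr(M)[0]
        u = Q[:, 1:]  # orthonormal and orthogonal to 1 => mean-zero columns
        block_a = np.column_stack([u[:, 0], u[:, 0] + u[:, 1]])
        block_b = np.column_stack([u[:, 2], u[:, 2] - u[:, 3]])
        X = np.column_stack([block_a, block_b])
        res = covariance_ratio(X, [0, 0, 1, 1], n_perm=19, seed=0, min_size=2)
        assert res.cr == pytest.approx(0.0, abs=1e-10)

    def test_invariances(self, rng):
        X = rng.normal(size=(18, 8))
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        base = covariance_ratio(X, labels, n_perm=9, seed=1, min_size=2).cr
        # reorder traits within modules
        perm = [2, 0, 3, 1, 7, 5, 6, 4]
        again = covariance_ratio(X[:, perm], [labels[i] for i in perm],
                                 n_perm=9, seed=1, min_size=2).cr
        assert again == pytest.approx(base, abs=1e-12)
        # global rescaling
        scaled = covariance_ratio(5.0 * X, labels, n_perm=9, seed=1,
                                  min_size=2).cr
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_min_size_filter_enforced(self, rng):
        X = rng.normal(size=(10, 6))
        with pytest.raises(ValueError, match="at least 2 modules"):
            covariance_ratio(X, [0, 0, 0, 1, 1, 1], n_perm=9, min_size=15)

    def test_planted_modularity_detected(self, rng):
        block = np.full((15, 15), 0.9)
        np.fill_diagonal(block, 1.0)
        S = np.block([[block, np.zeros((15, 15))],
                      [np.zeros((15, 15)), block]])
        L = np.linalg.cholesky(S)
        X = rng.normal(size=(18, 30)) @ L.T
        res = covariance_ratio(X, [0] * 15 + [1] * 15, n_perm=199, seed=0)
        assert res.cr < 1.0
        assert res.p_value <= 0.05


def test_mcl_recovers_planted_blocks_exactly():
    g, truth = generate_network_fixture(3, 10, p_within=0.9, p_between=0.0,
                                        seed=11)
    labels = mcl(g)
    # same partition as planted (up to relabeling)
    by_mod = {}
    for gene, mod in labels.items():
        by_mod.setdefault(mod, set()).add(gene)
    planted = {}
    for gene, mod in truth.items():
        planted.setdefault(mod, set()).add(gene)
    assert sorted(map(sorted, by_mod.values())) == sorted(map(sorted, planted.values()))
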