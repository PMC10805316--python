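"""Feature representations: adjacency, RWR kernel, SVD, node2vec, PCA mixing."""

import numpy as np
import pytest

from zoonet.multinet import (
    OrthologGroupTable,
    SpeciesNetwork,
    build_multispecies_network,
)
from zoonet.represent import (
    FeatureMatrix,
    adjacency_features,
    node2vec_features,
    pca_species_projection,
    rwr_features,
    svd_features,
)


def two_node_msn(weight=0.5):
    net = SpeciesNetwork("hu", ("a", "b"), {("a", "b"): weight})
    return build_multispecies_network([net], OrthologGroupTable())


def random_msn(rng, n=8, p=0.4):
    genes = tuple(f"g{i}" for i in range(n))
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(genes[i], genes[j])] = float(rng.uniform(0.2, 1.0))
    # guarantee connectivity of each node to avoid all-sink rows
    for i in range(n - 1):
        edges.setdefault((genes[i], genes[i + 1]), 1.0)
    net = SpeciesNetwork("hu", genes, edges)
    return build_multispecies_network([net], OrthologGroupTable())


class TestAdjacencyFeatures:
    def test_undirected_edge_symmetric(self):
        fm = adjacency_features(two_node_msn(0.5))
        assert np.allclose(fm.values, [[0, 0.5], [0.5, 0]])

    def test_directed_cross_edge_populates_one_entry(self):
        hu = SpeciesNetwork("hu", ("h1", "h2"), {("h1", "h2"): 1.0})
        mu = SpeciesNetwork("mu", ("m1", "m2"), {("m1", "m2"): 1.0})
        groups = OrthologGroupTable({"G": frozenset({("hu", "h1"), ("mu", "m1")})})
        msn = build_multispecies_network([hu, mu], groups, scheme="degree")
        fm = adjacency_features(msn)
        i, j = msn.index_of(("hu", "h1")), msn.index_of(("mu", "m1"))
        assert fm.values[i, j] == pytest.approx(1.0)  # deg 1 / 1 partner
        assert fm.values[j, i] == pytest.approx(1.0)  # reverse directed edge

    def test_species_restriction_recovers_species_adjacency(self):
        hu = SpeciesNetwork("hu", ("h1", "h2", "h3"),
                            {("h1", "h2"): 0.3, ("h2", "h3"): 0.9})
        mu = SpeciesNetwork("mu", ("m1", "m2"), {("m1", "m2"): 1.0})
        groups = OrthologGroupTable({"G": frozenset({("hu", "h1"), ("mu", "m1")})})
        msn = build_multispecies_network([hu, mu], groups, scheme="uniform")
        fm = adjacency_features(msn)
        hu_idx = [i for i, (s, _) in enumerate(fm.gene_index) if s == "hu"]
        block = fm.values[np.ix_(hu_idx, hu_idx)]
        expected = np.array([[0, 0.3, 0], [0.3, 0, 0.9], [0, 0.9, 0]])
        assert np.array_equal(block, expected)


def rwr_power_iteration(P, alpha, tol=1e-14):
    """Independent oracle: iterate F <- alpha I + (1-alpha) F P."""
    n = P.shape[0]
    F = np.eye(n)
    for _ in range(10_000):
        F_next = alpha * np.eye(n) + (1 - alpha) * F @ P
        if np.abs(F_next - F).max() < tol:
            return F_next
        F = F_next
    return F


class TestRWRFeatures:
    def test_two_node_closed_form(self):
        fm = rwr_features(two_node_msn(), alpha=0.5)
        assert np.allclose(fm.values, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)

    def test_alpha_one_gives_identity(self):
        fm = rwr_features(two_node_msn(), alpha=1.0)
        assert np.allclose(fm.values, np.eye(2))

    def test_rows_sum_to_one(self):
        fm = rwr_features(random_msn(np.random.default_rng(0)), alpha=0.3)
        assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-8)

    @pytest.mark.parametrize("seed,n,alpha", [(0, 6, 0.3), (1, 10, 0.85), (2, 4, 0.5)])
    def test_matches_power_iteration_oracle(self, seed, n, alpha):
        msn = random_msn(np.random.default_rng(seed), n=n)
        A = msn.adjacency().toarray()
        P = A / A.sum(axis=1, keepdims=True)
        expected = rwr_power_iteration(P, alpha)
        fm = rwr_features(msn, alpha=alpha)
        assert np.abs(fm.values - expected).max() < 1e-8

    def test_sink_node_gets_teleport_row(self):
        net = SpeciesNetwork("hu", ("a", "b", "c"), {("a", "b"): 1.0})
        msn = build_multispecies_network([net], OrthologGroupTable())
        fm = rwr_features(msn, alpha=0.5)
        assert fm.params["n_teleport_rows"] == 1
        assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            rwr_features(two_node_msn(), alpha=alpha)


class TestSVDFeatures:
    def fm(self, values):
        genes = [("hu", f"g{i}") for i in range(values.shape[0])]
        return FeatureMatrix(genes, values.astype(float), "adjmat")

    def test_rank_one_exact_reconstruction(self):
        u = np.array([[1.0], [2.0], [3.0]])
        v = np.array([[2.0, 1.0]])
        fm = svd_features(self.fm(u @ v), d=1)
        # U1*S1 spans the input's column space; reconstruction is exact
        X = u @ v
        proj = fm.values @ np.linalg.lstsq(fm.values, X, rcond=None)[0]
        assert np.abs(proj - X).max() < 1e-9

    @staticmethod
    def reconstruction_error(factors, X):
        """Residual of projecting X onto the factor column space."""
        proj = factors @ np.linalg.lstsq(factors, X, rcond=None)[0]
        return float(np.linalg.norm(proj - X))

    def test_full_rank_zero_reconstruction_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 5))
        fm = svd_features(self.fm(X), d=5)
        assert self.reconstruction_error(fm.values, X) < 1e-9

    def test_reconstruction_error_nonincreasing_in_d(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 6))
        errors = [
            self.reconstruction_error(svd_features(self.fm(X), d=d).values, X)
            for d in range(1, 7)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))
        # matches dense brute-force SVD (Eckart-Young optimal residual)
        _, s, _ = np.linalg.svd(X)
        for d, err in enumerate(errors, start=1):
            assert err == pytest.approx(float(np.sqrt((s[d:] ** 2).sum())), abs=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        a = svd_features(self.fm(X), d=3).values
        b = svd_features(self.fm(X.copy()), d=3).values
        assert np.array_equal(a, b)
        for k in range(3):
            col_u = a[:, k]
            assert col_u[np.argmax(np.abs(col_u))] > 0

    def test_d_too_large_rejected(self):
        with pytest.raises(ValueError):
            svd_features(self.fm(np.eye(3)), d=4)


def clique_bridge_msn(n_per_clique=10):
    genes = tuple(f"g{i}" for i in range(2 * n_per_clique))
    edges = {}
    for block in (range(n_per_clique), range(n_per_clique, 2 * n_per_clique)):
        block = list(block)
        for i in block:
            for j in block:
                if i < j:
                    edges[(genes[i], genes[j])] = 1.0
    edges[(genes[n_per_clique - 1], genes[n_per_clique])] = 1.0  # bridge
    net = SpeciesNetwork("hu", genes, edges)
    return build_multispecies_network([net], OrthologGroupTable())


def mean_cosine(X, idx_a, idx_b):
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    sims = Xn[idx_a] @ Xn[idx_b].T
    if idx_a == idx_b:
        iu = np.triu_indices(len(idx_a), k=1)
        return float(sims[iu].mean())
    return float(sims.mean())


class TestNode2vecFeatures:
    def test_same_seed_bitwise_identical(self):
        msn = clique_bridge_msn(5)
        a = node2vec_features(msn, d=8, num_walks=3, walk_length=10, window=3, seed=42)
        b = node2vec_features(msn, d=8, num_walks=3, walk_length=10, window=3, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self):
        msn = clique_bridge_msn(5)
        a = node2vec_features(msn, d=8, num_walks=3, walk_length=10, window=3, seed=1)
        b = node2vec_features(msn, d=8, num_walks=3, walk_length=10, window=3, seed=2)
        assert not np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("kwargs", [{"d": 0}, {"p": 0.0}, {"q": -1.0}])
    def test_invalid_hyperparameters_rejected(self, kwargs):
        msn = clique_bridge_msn(3)
        with pytest.raises(ValueError):
            node2vec_features(msn, **{"d": 4, **kwargs})

    def test_cliques_more_similar_within_than_across(self):
        msn = clique_bridge_msn(10)
        fm = node2vec_features(msn, d=16, num_walks=10, walk_length=20,
                               window=5, epochs=3, seed=0)
        a, b = list(range(10)), list(range(10, 20))
        within = 0.5 * (mean_cosine(fm.values, a, a) + mean_cosine(fm.values, b, b))
        across = mean_cosine(fm.values, a, b)
        assert within > across

    def test_disconnected_components_separate(self):
        genes = tuple(f"g{i}" for i in range(12))
        edges = {}
        for block in (range(6), range(6, 12)):
            block = list(block)
            for i in block:
                for j in block:
                    if i < j:
                        edges[(genes[i], genes[j])] = 1.0
        net = SpeciesNetwork("hu", genes, edges)
        msn = build_multispecies_network([net], OrthologGroupTable())
        fm = node2vec_features(msn, d=16, num_walks=10, walk_length=20,
                               window=5, epochs=3, seed=0)
        a, b = list(range(6)), list(range(6, 12))
        within = 0.5 * (mean_cosine(fm.values, a, a) + mean_cosine(fm.values, b, b))
        across = mean_cosine(fm.values, a, b)
        assert within - across > 0


class TestPCASpeciesProjection:
    def test_identical_point_clouds_score_near_one(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(40, 6))
        genes = [("hu", f"g{i}") for i in range(40)] + [("mu", f"g{i}") for i in range(40)]
        fm = FeatureMatrix(genes, np.vstack([cloud, cloud]), "n2v")
        # ortholog pairing uncorrelated with position
        perm = rng.permutation(40)
        groups = OrthologGroupTable(
            {f"G{i}": frozenset({("hu", f"g{i}"), ("mu", f"g{perm[i]}")})
             for i in range(40)}
        )
        mix = pca_species_projection(fm, groups, seed=1)
        assert 0.6 < mix.score < 1.5

    def test_coincident_ortholog_pairs_score_zero(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(size=(30, 5))
        genes = [("hu", f"g{i}") for i in range(30)] + [("mu", f"g{i}") for i in range(30)]
        fm = FeatureMatrix(genes, np.vstack([cloud, cloud]), "n2v")
        groups = OrthologGroupTable(
            {f"G{i}": frozenset({("hu", f"g{i}"), ("mu", f"g{i}")}) for i in range(30)}
        )
        mix = pca_species_projection(fm, groups, seed=1)
        assert mix.score == pytest.approx(0.0, abs=1e-12)

    def test_no_cross_species_pairs_flagged_undefined(self):
        genes = [("hu", "a"), ("hu", "b"), ("mu", "c")]
        fm = FeatureMatrix(genes, np.eye(3), "adjmat")
        mix = pca_species_projection(fm, OrthologGroupTable(), n_components=2)
        assert mix.score is None and mix.n_ortholog_pairs == 0

    def test_too_few_columns_rejected(self):
        fm = FeatureMatrix([("hu", "a"), ("hu", "b")], np.ones((2, 1)), "svd")
        with pytest.raises(ValueError):
            pca_species_projection(fm, None, n_components=2)
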