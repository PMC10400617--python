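"""Sparse PLS, association networks, centrality, and node selection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from radiomet import METABOLITE, RADIOMICS, OmicsBlock
from radiomet.integration import (
    AssociationMatrix,
    association_matrix,
    build_network,
    delta_centrality,
    detect_communities,
    eigenvector_centrality,
    fit_spls,
    select_discriminative_nodes,
)
from radiomet.preprocess import zscore_normalize

from conftest import make_block


def _assoc(matrix, row_prefix="rf", col_prefix="C"):
    m = np.asarray(matrix, dtype=float)
    return AssociationMatrix(pd.DataFrame(
        m,
        index=[f"{row_prefix}{i}" for i in range(1, m.shape[0] + 1)],
        columns=[f"{col_prefix}{j}" for j in range(1, m.shape[1] + 1)],
    ))


class TestFitSpls:
    def test_self_integration_single_feature(self, rng):
        v = zscore_normalize(make_block(rng.normal(size=(8, 1))))
        x = OmicsBlock(v.data.copy(), RADIOMICS)
        y = OmicsBlock(v.data.copy().rename(columns={v.feature_ids[0]: "m0"}), METABOLITE)
        model = fit_spls(x, y, n_components=1)
        assert abs(abs(model.x_loadings[0, 0]) - 1.0) < 1e-12
        assert abs(abs(model.y_loadings[0, 0]) - 1.0) < 1e-12
        assert model.component_correlations[0] == pytest.approx(1.0)

    def test_dense_fit_matches_svd_oracle(self, small_blocks):
        """No sparsity, H=1: loadings equal the leading singular pair of X'Y."""
        x, y = small_blocks
        model = fit_spls(x, y, n_components=1)
        xc = x.values - x.values.mean(axis=0)
        yc = y.values - y.values.mean(axis=0)
        u_svd, _, vt_svd = np.linalg.svd(xc.T @ yc)
        u, v = model.x_loadings[:, 0], model.y_loadings[:, 0]
        sign = np.sign(u @ u_svd[:, 0])
        assert np.allclose(u, sign * u_svd[:, 0], atol=1e-6)
        assert np.allclose(v, sign * vt_svd[0], atol=1e-6)

    def test_unit_norm_sparsity_and_orthogonal_scores(self, rng):
        x = make_block(rng.normal(size=(15, 10)), RADIOMICS, "rf")
        y = make_block(rng.normal(size=(15, 12)), METABOLITE, "C")
        model = fit_spls(x, y, n_components=3, keep_x=4, keep_y=5)
        for h in range(3):
            assert np.linalg.norm(model.x_loadings[:, h]) == pytest.approx(1.0)
            assert np.linalg.norm(model.y_loadings[:, h]) == pytest.approx(1.0)
            assert np.count_nonzero(model.x_loadings[:, h]) <= 4
            assert np.count_nonzero(model.y_loadings[:, h]) <= 5
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_invalid_arguments(self, small_blocks):
        x, y = small_blocks
        with pytest.raises(ValueError):
            fit_spls(x, y, n_components=0)
        with pytest.raises(ValueError):
            fit_spls(x, y, n_components=5)  # > min(p, q, n-1) = 3
        with pytest.raises(ValueError):
            fit_spls(x, y, n_components=1, keep_x=0)


class TestAssociationMatrix:
    def test_single_outer_product(self):
        from radiomet.integration import SplsModel

        model = SplsModel(
            x_loadings=np.array([[1.0], [0.0]]),
            y_loadings=np.array([[0.0], [1.0]]),
            x_scores=np.zeros((3, 1)),
            y_scores=np.zeros((3, 1)),
            component_correlations=np.array([0.8]),
            x_feature_ids=["rf1", "rf2"],
            y_feature_ids=["C1", "C2"],
            keep_x=2,
            keep_y=2,
        )
        M = association_matrix(model).scores.to_numpy()
        assert np.allclose(M, [[0.0, 0.8], [0.0, 0.0]])

    def test_zero_loadings_give_zero_matrix(self):
        from radiomet.integration import SplsModel

        model = SplsModel(
            x_loadings=np.zeros((3, 2)),
            y_loadings=np.zeros((4, 2)),
            x_scores=np.zeros((5, 2)),
            y_scores=np.zeros((5, 2)),
            component_correlations=np.array([0.5, 0.1]),
            x_feature_ids=list("abc"),
            y_feature_ids=list("defg"),
            keep_x=3,
            keep_y=4,
        )
        assert not association_matrix(model).scores.to_numpy().any()

    def test_three_component_sum_matches_bruteforce(self, rng):
        x = make_block(rng.normal(size=(12, 6)), RADIOMICS, "rf")
        y = make_block(rng.normal(size=(12, 7)), METABOLITE, "C")
        model = fit_spls(x, y, n_components=3, keep_x=4, keep_y=4)
        brute = np.zeros((6, 7))
        for h in range(3):
            brute += model.component_correlations[h] * np.outer(
                model.x_loadings[:, h], model.y_loadings[:, h]
            )
        brute = np.clip(brute, -1, 1)
        assert np.allclose(association_matrix(model).scores.to_numpy(), brute,
                           atol=1e-12)


class TestBuildNetwork:
    def test_threshold_by_inspection(self):
        net = build_network(_assoc([[0.5, 0.1], [-0.45, 0.0]]), 0.4)
        edges = {(u, v): d["weight"] for u, v, d in net.graph.edges(data=True)}
        weights = {frozenset(k): w for k, w in edges.items()}
        assert weights == {
            frozenset({"rf1", "C1"}): 0.5,
            frozenset({"rf2", "C1"}): -0.45,
        }
        assert net.isolated[METABOLITE] == ["C2"]

    def test_zero_threshold_keeps_all_nonzero(self):
        net = build_network(_assoc([[0.2, 0.0], [0.3, -0.1]]), 0.0)
        assert net.n_edges == 3  # the exact zero never makes an edge

    def test_unit_threshold_keeps_only_saturated(self):
        net = build_network(_assoc([[1.0, 0.99], [-1.0, 0.5]]), 1.0)
        assert net.n_edges == 2

    def test_bipartite(self, rng):
        net = build_network(_assoc(rng.uniform(-1, 1, size=(5, 6))), 0.3)
        for u, v in net.graph.edges:
            assert net.graph.nodes[u]["block"] != net.graph.nodes[v]["block"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_network(_assoc([[0.5]]), 1.5)


class TestCommunities:
    def test_two_disjoint_cliques(self):
        m = np.zeros((4, 4))
        m[:2, :2] = 0.9
        m[2:, 2:] = 0.9
        part = detect_communities(build_network(_assoc(m), 0.5), seed=1)
        assert part.n_communities == 2
        assert part.membership["rf1"] == part.membership["C1"] == part.membership["rf2"]
        assert part.membership["rf3"] == part.membership["C3"]

    def test_single_edge_one_community(self):
        part = detect_communities(build_network(_assoc([[0.7]]), 0.5), seed=0)
        assert part.n_communities == 1

    def test_beats_planted_partition_modularity(self, rng):
        """Louvain Q on a planted two-community bipartite graph is at least
        the planted partition's exhaustively computed modularity."""
        m = np.zeros((6, 6))
        m[:3, :3] = rng.uniform(0.7, 1.0, size=(3, 3))
        m[3:, 3:] = rng.uniform(0.7, 1.0, size=(3, 3))
        m[0, 5] = 0.71  # one cross edge
        net = build_network(_assoc(m), 0.7)
        part = detect_communities(net, seed=3)
        planted = [
            {f"rf{i}" for i in (1, 2, 3)} | {f"C{i}" for i in (1, 2, 3)},
            {f"rf{i}" for i in (4, 5, 6)} | {f"C{i}" for i in (4, 5, 6)},
        ]
        q_planted = nx.community.modularity(net.graph, planted, weight="abs_weight")
        assert part.modularity >= q_planted - 1e-9

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(build_network(_assoc([[0.1]]), 0.5))


class TestEigenvectorCentrality:
    def test_single_edge_both_one(self):
        ec = eigenvector_centrality(build_network(_assoc([[0.8]]), 0.5))
        assert ec["rf1"] == pytest.approx(1.0)
        assert ec["C1"] == pytest.approx(1.0)

    def test_star_closed_form(self):
        """Unit-weight star with 3 leaves: center 1, leaves 1/sqrt(3)."""
        ec = eigenvector_centrality(build_network(_assoc([[1.0, 1.0, 1.0]]), 0.5))
        assert ec["rf1"] == pytest.approx(1.0, abs=1e-8)
        for leaf in ("C1", "C2", "C3"):
            assert ec[leaf] == pytest.approx(1 / np.sqrt(3), abs=1e-8)

    def test_outside_largest_component_zero(self):
        m = np.zeros((3, 3))
        m[0, 0] = m[0, 1] = m[1, 0] = 0.9  # 4-node component
        m[2, 2] = 0.9  # 2-node component
        ec = eigenvector_centrality(build_network(_assoc(m), 0.5))
        assert ec["rf3"] == 0.0 and ec["C3"] == 0.0
        assert max(ec.values()) == pytest.approx(1.0)

    def test_invariant_to_global_rescaling(self, rng):
        m = rng.uniform(0.3, 1.0, size=(4, 5))
        ec1 = eigenvector_centrality(build_network(_assoc(m), 0.3))
        ec2 = eigenvector_centrality(build_network(_assoc(0.5 * m), 0.0))
        for node, v in ec1.items():
            assert ec2[node] == pytest.approx(v, abs=1e-7)

    def test_matches_networkx(self, rng):
        m = rng.uniform(0.2, 1.0, size=(5, 6))
        net = build_network(_assoc(m), 0.2)
        ec = eigenvector_centrality(net)
        ref = nx.eigenvector_centrality_numpy(net.graph, weight="abs_weight")
        ref_max = max(abs(v) for v in ref.values())
        for node in net.graph.nodes:
            assert ec[node] == pytest.approx(abs(ref[node]) / ref_max, abs=1e-6)


class TestDeltaCentrality:
    def test_subtraction_and_missing_as_zero(self):
        table = delta_centrality({"a": 0.6, "c": 0.3}, {"a": 0.2, "b": 0.5})
        dc = table.table["dc"]
        assert dc["a"] == pytest.approx(0.4)
        assert dc["b"] == pytest.approx(-0.5)
        assert dc["c"] == pytest.approx(0.3)

    def test_identical_networks_zero(self):
        ec = {"a": 0.7, "b": 0.2}
        assert (delta_centrality(ec, ec).table["dc"] == 0).all()

    def test_antisymmetry_under_label_swap(self, rng):
        eb = {f"n{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 10))}
        em = {f"n{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 10))}
        forward = delta_centrality(eb, em).table["dc"]
        backward = delta_centrality(em, eb).table["dc"]
        assert np.allclose(forward.to_numpy(), -backward.to_numpy())

    def test_selection_modes(self):
        table = delta_centrality({"a": 0.15, "c": 0.05}, {"b": 0.2})
        assert select_discriminative_nodes(table, 0.1, "absolute") == {"a", "b"}
        assert select_discriminative_nodes(table, 0.1, "signed") == {"a"}
        assert select_discriminative_nodes(table, 1.0, "absolute") == set()
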