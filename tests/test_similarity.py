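import math

import networkx as nx
import numpy as np
import pytest

from birwalk.net_core import (
    DISEASE,
    DRUG,
    AssociationMatrix,
    EntityIndex,
    IndexMismatchError,
    SimilarityMatrix,
)
from birwalk.similarity import (
    Cluster,
    ClusterSet,
    GIPParams,
    LogisticParams,
    SimilarityConfig,
    cluster_boost,
    cluster_cohesiveness,
    cluster_one,
    combine,
    composite_similarity,
    cosine_similarity,
    gip_kernel,
    informative_threshold,
    logistic_adjust,
    sharing_graph,
)

from conftest import make_assoc, make_features
from oracles import gip_by_loops, random_bipartite, sharing_weights_by_loops


class TestCosine:
    def test_identical_rows_give_one(self):
        fm = make_features([[1, 1, 0], [1, 1, 0]])
        assert cosine_similarity(fm).values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows_give_zero(self):
        fm = make_features([[1, 0, 0], [0, 1, 0]])
        assert cosine_similarity(fm).values[0, 1] == 0.0

    def test_half_overlap(self):
        fm = make_features([[1, 1, 0], [1, 0, 1]])
        assert cosine_similarity(fm).values[0, 1] == pytest.approx(0.5)

    def test_zero_row_convention(self):
        fm = make_features([[0, 0, 0], [1, 1, 0]])
        sim = cosine_similarity(fm)
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 0.0

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(0)
        fm = make_features((rng.random((9, 6)) < 0.5).astype(int))
        sim = cosine_similarity(fm).values
        assert np.abs(sim - sim.T).max() < 1e-12
        assert sim.min() >= 0.0 and sim.max() <= 1.0


def planted_threshold_fixture(boundary_bin: int = 4):
    """Two drug groups: cross-group pairs sit below the boundary and never
    share a disease, within-group pairs sit above it and always do."""
    n = 12
    group = np.array([0] * 6 + [1] * 6)
    low, high = [], []
    s1 = np.eye(n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    cross = [(i, j) for i, j in pairs if group[i] != group[j]]
    within = [(i, j) for i, j in pairs if group[i] == group[j]]
    bound = boundary_bin / 10
    cross_vals = np.linspace(0.02, bound - 0.02, len(cross))
    within_vals = np.linspace(bound + 0.02, 0.99, len(within))
    for (i, j), v in zip(cross, cross_vals):
        s1[i, j] = s1[j, i] = v
    for (i, j), v in zip(within, within_vals):
        s1[i, j] = s1[j, i] = v
    index = EntityIndex(kind="drug", ids=tuple(f"r{i}" for i in range(n)))
    sim = SimilarityMatrix(index=index, values=s1, stage="raw")
    w = np.zeros((n, 2), dtype=np.int8)
    w[group == 0, 0] = 1
    w[group == 1, 1] = 1
    assoc = AssociationMatrix(
        drug_index=index,
        disease_index=EntityIndex(kind="disease", ids=("d0", "d1")),
        values=w,
    )
    return sim, assoc, bound


class TestInformativeThreshold:
    def test_recovers_planted_boundary(self):
        sim, assoc, bound = planted_threshold_fixture()
        assert informative_threshold(sim, assoc, seed=5) == pytest.approx(bound)

    @pytest.mark.parametrize("boundary_bin", [2, 6])
    def test_other_boundaries(self, boundary_bin):
        sim, assoc, bound = planted_threshold_fixture(boundary_bin)
        assert informative_threshold(sim, assoc, seed=5) == pytest.approx(bound)

    def test_all_zero_associations_fall_back(self, caplog):
        sim, assoc, _ = planted_threshold_fixture()
        empty = AssociationMatrix(
            drug_index=assoc.drug_index,
            disease_index=assoc.disease_index,
            values=np.zeros_like(assoc.values),
        )
        with caplog.at_level("WARNING"):
            assert informative_threshold(sim, empty, seed=5) == pytest.approx(0.1)
        assert "0.1" in caplog.text

    def test_invariant_to_entity_ordering(self):
        sim, assoc, _ = planted_threshold_fixture()
        rng = np.random.default_rng(17)
        perm = rng.permutation(sim.index.size)
        ids = tuple(sim.index.ids[p] for p in perm)
        index = EntityIndex(kind="drug", ids=ids)
        sim_p = SimilarityMatrix(
            index=index, values=sim.values[np.ix_(perm, perm)], stage="raw"
        )
        assoc_p = AssociationMatrix(
            drug_index=index,
            disease_index=assoc.disease_index,
            values=assoc.values[perm],
        )
        assert informative_threshold(sim_p, assoc_p, seed=5) == informative_threshold(
            sim, assoc, seed=5
        )


class TestLogisticAdjust:
    def test_zero_maps_to_one_permille(self):
        sim = SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=("a", "b")),
            values=np.array([[1.0, 0.0], [0.0, 1.0]]),
            stage="raw",
        )
        out = logistic_adjust(sim, LogisticParams(x_star=0.5))
        assert out.values[0, 1] == pytest.approx(1.0 / (1.0 + 999.0))

    def test_midpoint_at_threshold(self):
        x_star = 0.3
        sim = SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=("a", "b")),
            values=np.array([[1.0, x_star], [x_star, 1.0]]),
            stage="raw",
        )
        out = logistic_adjust(sim, LogisticParams(x_star=x_star))
        assert out.values[0, 1] == pytest.approx(0.5)

    def test_strictly_increasing(self):
        rng = np.random.default_rng(2)
        vals = np.sort(rng.random(50))
        params = LogisticParams(x_star=0.4)
        transformed = 1.0 / (1.0 + np.exp(params.steepness * vals + params.d))
        assert (np.diff(transformed) > 0).all()

    def test_preserves_pair_ranking(self):
        rng = np.random.default_rng(7)
        raw = rng.random((8, 8))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 1.0)
        sim = SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=tuple(f"r{i}" for i in range(8))),
            values=raw,
            stage="raw",
        )
        out = logistic_adjust(sim, LogisticParams(x_star=0.6))
        iu = np.triu_indices(8, 1)
        order = np.argsort(sim.values[iu], kind="stable")
        assert (np.diff(out.values[iu][order]) >= 0).all()

    def test_diagonal_forced_to_one(self):
        sim = SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=("a", "b")),
            values=np.array([[1.0, 0.2], [0.2, 1.0]]),
            stage="raw",
        )
        out = logistic_adjust(sim, LogisticParams(x_star=0.5))
        np.testing.assert_allclose(np.diag(out.values), 1.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(x_star=0.0)
        with pytest.raises(ValueError):
            LogisticParams(x_star=-0.2)


class TestSharingGraph:
    def test_single_shared_disease(self, small_assoc):
        g = sharing_graph(small_assoc, DRUG)
        assert g["r1"]["r2"]["weight"] == 1

    def test_disjoint_columns_give_empty_edges(self):
        assoc = make_assoc([[1, 0], [0, 1]])
        g = sharing_graph(assoc, DRUG)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            w = random_bipartite(rng, 10, 8)
            assoc = make_assoc(w)
            for kind, axis in ((DRUG, 0), (DISEASE, 1)):
                g = sharing_graph(assoc, kind)
                ids = assoc.drug_index.ids if kind == DRUG else assoc.disease_index.ids
                expected = sharing_weights_by_loops(w, axis)
                got = {
                    tuple(sorted((ids.index(u), ids.index(v)))): d["weight"]
                    for u, v, d in g.edges(data=True)
                }
                assert got == expected


class TestClusterOne:
    def two_triangles(self):
        g = nx.Graph()
        for offset in (0, 3):
            nodes = [f"n{offset + k}" for k in range(3)]
            for a in range(3):
                for b in range(a + 1, 3):
                    g.add_edge(nodes[a], nodes[b], weight=1)
        return g

    def test_two_disconnected_triangles(self):
        clusters = cluster_one(self.two_triangles(), penalty_per_node=0.0)
        assert len(clusters) == 2
        assert {frozenset(c.members) for c in clusters.clusters} == {
            frozenset({"n0", "n1", "n2"}),
            frozenset({"n3", "n4", "n5"}),
        }
        for c in clusters.clusters:
            assert c.cohesiveness == pytest.approx(1.0)

    def test_cohesiveness_arithmetic(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=4)
        g.add_edge("a", "c", weight=2)
        g.add_edge("b", "d", weight=2)
        assert cluster_cohesiveness(g, frozenset({"a", "b"}), 0.0) == pytest.approx(0.5)

    def test_penalty_never_increases_cohesiveness(self):
        g = self.two_triangles()
        base = cluster_one(g, penalty_per_node=0.0)
        penalised = cluster_one(g, penalty_per_node=1.5)
        for c0, c1 in zip(base.clusters, penalised.clusters):
            assert c1.cohesiveness <= c0.cohesiveness + 1e-12

    def test_empty_graph(self):
        assert len(cluster_one(nx.Graph())) == 0

    def test_cohesiveness_recomputable(self, planted_fixture):
        _, _, _, observed, _ = planted_fixture
        g = sharing_graph(observed, DRUG)
        clusters = cluster_one(g)
        for c in clusters.clusters:
            assert c.cohesiveness == pytest.approx(
                cluster_cohesiveness(g, c.members, clusters.penalty_per_node), abs=1e-9
            )


class TestClusterBoost:
    def _sim(self, values):
        n = len(values)
        return SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=tuple(f"r{i}" for i in range(n))),
            values=np.asarray(values, dtype=float),
            stage="adjusted",
        )

    def test_unclustered_pair_unchanged(self):
        sim = self._sim([[1.0, 0.4], [0.4, 1.0]])
        out = cluster_boost(sim, ClusterSet(clusters=()))
        np.testing.assert_allclose(out.values, sim.values)

    def test_full_cohesiveness_doubles(self):
        sim = self._sim([[1.0, 0.4], [0.4, 1.0]])
        clusters = ClusterSet(
            clusters=(Cluster(members=frozenset({"r0", "r1"}), cohesiveness=1.0),)
        )
        assert cluster_boost(sim, clusters).values[0, 1] == pytest.approx(0.8)

    def test_max_cohesiveness_wins_for_overlaps(self):
        sim = self._sim([[1.0, 0.4], [0.4, 1.0]])
        clusters = ClusterSet(
            clusters=(
                Cluster(members=frozenset({"r0", "r1"}), cohesiveness=0.25),
                Cluster(members=frozenset({"r0", "r1"}), cohesiveness=0.75),
            )
        )
        assert cluster_boost(sim, clusters).values[0, 1] == pytest.approx(0.4 * 1.75)

    def test_never_decreases_and_stays_symmetric(self):
        rng = np.random.default_rng(4)
        raw = rng.random((6, 6))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 1.0)
        sim = self._sim(raw)
        clusters = ClusterSet(
            clusters=(
                Cluster(members=frozenset({"r0", "r2", "r4"}), cohesiveness=0.6),
            )
        )
        out = cluster_boost(sim, clusters)
        assert (out.values >= sim.values - 1e-12).all()
        assert np.abs(out.values - out.values.T).max() < 1e-12
        assert out.values.max() <= 2.0


class TestGIPKernel:
    def test_identical_profiles_give_one(self):
        assoc = make_assoc([[1, 0], [1, 0]])
        assert gip_kernel(assoc, DRUG).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        assoc = make_assoc([[1, 0], [0, 1]])
        out = gip_kernel(assoc, DRUG, GIPParams(gamma_tilde=1.0))
        assert out.values[0, 1] == pytest.approx(math.exp(-2.0))

    def test_doubling_bandwidth_squares_entries(self):
        rng = np.random.default_rng(9)
        assoc = make_assoc(random_bipartite(rng, 6, 5))
        s1 = gip_kernel(assoc, DRUG, GIPParams(gamma_tilde=1.0)).values
        s2 = gip_kernel(assoc, DRUG, GIPParams(gamma_tilde=2.0)).values
        np.testing.assert_allclose(s2, s1**2, atol=1e-12)

    def test_all_zero_matrix_rejected(self):
        assoc = make_assoc(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="GIP undefined"):
            gip_kernel(assoc, DRUG)

    def test_entries_in_unit_interval_diag_one(self):
        rng = np.random.default_rng(21)
        assoc = make_assoc(random_bipartite(rng, 8, 6))
        for kind in (DRUG, DISEASE):
            out = gip_kernel(assoc, kind).values
            assert out.min() > 0.0 and out.max() <= 1.0
            np.testing.assert_allclose(np.diag(out), 1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            w = random_bipartite(rng, 10, 8)
            assoc = make_assoc(w)
            np.testing.assert_allclose(
                gip_kernel(assoc, DRUG).values,
                gip_by_loops(w.astype(float), 1.0),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                gip_kernel(assoc, DISEASE).values,
                gip_by_loops(w.T.astype(float), 1.0),
                atol=1e-12,
            )


class TestCombine:
    def test_identity_when_equal(self):
        idx = EntityIndex(kind="drug", ids=("a", "b"))
        s = SimilarityMatrix(
            index=idx, values=np.array([[1.0, 0.3], [0.3, 1.0]]), stage="boosted"
        )
        k = SimilarityMatrix(index=idx, values=s.values.copy(), stage="gip")
        np.testing.assert_allclose(combine(s, k).values, s.values)

    def test_arithmetic_mean(self):
        idx = EntityIndex(kind="drug", ids=("a", "b"))
        s = SimilarityMatrix(
            index=idx, values=np.array([[1.0, 0.8], [0.8, 1.0]]), stage="boosted"
        )
        k = SimilarityMatrix(
            index=idx, values=np.array([[1.0, 0.2], [0.2, 1.0]]), stage="gip"
        )
        assert combine(s, k).values[0, 1] == pytest.approx(0.5)

    def test_index_mismatch_rejected(self):
        a = SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=("a", "b")), values=np.eye(2), stage="boosted"
        )
        b = SimilarityMatrix(
            index=EntityIndex(kind="drug", ids=("x", "y")), values=np.eye(2), stage="gip"
        )
        with pytest.raises(IndexMismatchError):
            combine(a, b)


class TestCompositePipeline:
    def test_step1_only_equals_cosine(self, planted_fixture):
        _, features_drug, _, observed, _ = planted_fixture
        config = SimilarityConfig(
            step2_enabled=False, step3_enabled=False, step4_enabled=False
        )
        out = composite_similarity(features_drug, observed, DRUG, config)
        np.testing.assert_allclose(out.values, cosine_similarity(features_drug).values)

    def test_full_pipeline_equals_manual_composition(self, planted_fixture):
        _, features_drug, _, observed, _ = planted_fixture
        config = SimilarityConfig(seed=3)
        out = composite_similarity(features_drug, observed, DRUG, config)

        s1 = cosine_similarity(features_drug)
        x_star = informative_threshold(
            s1, observed, n_shuffles=config.n_shuffles, seed=config.seed
        )
        s2 = logistic_adjust(s1, LogisticParams(x_star=x_star, d=config.logistic_d))
        clusters = cluster_one(
            sharing_graph(observed, DRUG),
            penalty_per_node=config.clusterone_penalty,
            min_size=config.clusterone_min_size,
            overlap_threshold=config.clusterone_overlap,
        )
        s3 = cluster_boost(s2, clusters)
        expected = combine(s3, gip_kernel(observed, DRUG))
        np.testing.assert_allclose(out.values, expected.values, atol=1e-12)

    def test_variant_without_boost_differs_only_through_s3(self, planted_fixture):
        _, features_drug, _, observed, _ = planted_fixture
        full = composite_similarity(features_drug, observed, DRUG, SimilarityConfig())
        no_boost = composite_similarity(
            features_drug, observed, DRUG, SimilarityConfig(step3_enabled=False)
        )
        gip_part = gip_kernel(observed, DRUG).values / 2.0
        # subtracting the shared kernel term leaves the S3 halves
        delta = (full.values - gip_part) - (no_boost.values - gip_part)
        assert np.abs(delta).max() > 0  # the boost changes something
        np.testing.assert_allclose(
            full.values - no_boost.values, delta, atol=1e-12
        )

    def test_every_stage_is_symmetric_nonnegative_bounded(self, planted_fixture):
        _, features_drug, _, observed, _ = planted_fixture
        out = composite_similarity(features_drug, observed, DRUG, SimilarityConfig())
        assert np.abs(out.values - out.values.T).max() < 1e-9
        assert out.values.min() >= 0.0
        assert out.values.max() <= 1.5 + 1e-12
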