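import math

import networkx as nx
import numpy as np
import pytest

from peakclust import KernelParams, nspdk_features, similarity, similarity_matrix, transform
from peakclust.errors import EmptyGraph, EmptyVector
from peakclust.kernel import (
    SparseFeatureVector,
    canonical_label,
    read_similarity_tsv,
    similarity_matrix_from_features,
    write_similarity_tsv,
)


def labeled_path(labels, edge="e"):
    g = nx.Graph()
    for i, lab in enumerate(labels):
        g.add_node(i, label=lab)
    for i in range(len(labels) - 1):
        g.add_edge(i, i + 1, label=edge)
    return g


class TestCanonicalLabel:
    def test_radius_zero_depends_only_on_root_label(self):
        g1 = labeled_path("AB")
        g2 = labeled_path("AC")
        assert canonical_label(g1, 0, 0) == canonical_label(g2, 0, 0)
        assert canonical_label(g1, 0, 0) != canonical_label(g1, 1, 0)

    def test_reflection_symmetry(self):
        g = labeled_path("ABC")
        h = labeled_path("CBA")
        assert canonical_label(g, 1, 1) == canonical_label(h, 1, 1)

    def test_label_and_edge_sensitivity(self):
        g = labeled_path("ABC")
        h = labeled_path("ABD")
        assert canonical_label(g, 1, 1) != canonical_label(h, 1, 1)
        k = labeled_path("ABC")
        k[0][1]["label"] = "f"
        assert canonical_label(g, 1, 1) != canonical_label(k, 1, 1)


class TestFeatures:
    def test_single_node_single_feature(self):
        g = nx.Graph()
        g.add_node(0, label="A")
        v = nspdk_features(g, KernelParams(R=0, D=0))
        assert len(v.weights) == 1
        assert math.isclose(sum(w * w for w in v.weights.values()), 1.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(EmptyGraph):
            nspdk_features(nx.Graph(), KernelParams())

    def test_isomorphic_graphs_identical_vectors(self):
        g = labeled_path("AGCA")
        h = nx.relabel_nodes(g, {0: 9, 1: 4, 2: 7, 3: 1})
        va, vb = nspdk_features(g), nspdk_features(h)
        assert va.weights == vb.weights

    def test_three_node_path_matches_hand_enumeration(self):
        """R=1, D=1 on path A-B-C: enumerate every (pair, r) combination by
        hand and compare the per-feature counts."""
        g = labeled_path("ABC")
        p = KernelParams(R=1, D=1)
        v = nspdk_features(g, p)
        # pairs at d=0: (0,0),(1,1),(2,2); d=1: (0,1),(1,2); r in {0,1}
        # distinct features by (r, d, unordered ball-label pair):
        #   r=0,d=0: A|A, B|B, C|C            -> 3 features, count 1 each
        #   r=0,d=1: A|B, B|C                 -> 2 features, count 1 each
        #   r=1,d=0: ball(A)|ball(A) etc.     -> 3 features, count 1 each
        #   r=1,d=1: ball(A)|ball(B), ball(B)|ball(C) -> 2 features
        # balls at r=1 around A, B, C are pairwise distinct (degree/labels),
        # so no two of the 10 (pair, r) combinations ever share a feature.
        assert len(v.weights) == 10
        # block normalization: 4 blocks; within each block counts are equal,
        # so each feature weight is 1/sqrt(n_block * 4)
        expected = set()
        for block_size in (3, 2, 3, 2):
            expected.add(round(1 / math.sqrt(block_size * 4), 12))
        assert {round(w, 12) for w in v.weights.values()} == expected

    def test_feature_count_monotone_in_R_and_D(self, fig2_record):
        g = transform(fig2_record, 11)
        base = len(nspdk_features(g, KernelParams(R=1, D=1)).weights)
        assert len(nspdk_features(g, KernelParams(R=2, D=1)).weights) >= base
        assert len(nspdk_features(g, KernelParams(R=1, D=2)).weights) >= base

    def test_params_validation(self):
        with pytest.raises(ValueError):
            KernelParams(R=-1)
        with pytest.raises(ValueError):
            KernelParams(bits=31)


class TestSimilarity:
    def test_identical_vectors(self):
        v = SparseFeatureVector({1: 0.6, 2: 0.8}, norm=1.0)
        assert math.isclose(similarity(v, v), 1.0)

    def test_disjoint_support(self):
        a = SparseFeatureVector({1: 1.0}, norm=1.0)
        b = SparseFeatureVector({2: 1.0}, norm=1.0)
        assert similarity(a, b) == 0.0

    def test_hand_computed_two_feature_case(self):
        s = 1 / math.sqrt(2)
        a = SparseFeatureVector({1: s, 2: s}, norm=math.sqrt(2))
        b = SparseFeatureVector({1: 1.0}, norm=1.0)
        assert math.isclose(similarity(a, b), s)

    def test_empty_vector_rejected(self):
        with pytest.raises(EmptyVector):
            similarity(SparseFeatureVector({}, norm=0.0), SparseFeatureVector({1: 1.0}, norm=1.0))


class TestSimilarityMatrix:
    def test_single_graph(self, fig2_record):
        S = similarity_matrix([transform(fig2_record, 11)])
        assert S.shape == (1, 1) and S[0, 0] == 1.0

    def test_duplicate_graph(self, fig2_record):
        g = transform(fig2_record, 11)
        S = similarity_matrix([g, g.copy()])
        assert np.allclose(S, 1.0)

    def test_matches_pairwise_similarity(self, gaga_records, small_benchmark):
        recs = list(small_benchmark.records)[:6]
        p = KernelParams()
        graphs = [transform(r, 11) for r in recs]
        vecs = [nspdk_features(g, p) for g in graphs]
        S = similarity_matrix(graphs, p)
        for i in range(len(recs)):
            for j in range(len(recs)):
                expect = 1.0 if i == j else similarity(vecs[i], vecs[j])
                assert math.isclose(S[i, j], expect, abs_tol=1e-9)

    def test_matrix_properties(self, small_benchmark):
        recs = list(small_benchmark.records)[:30]
        S = similarity_matrix([transform(r, 11) for r in recs])
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)
        assert S.min() >= 0.0 and S.max() <= 1.0

    def test_positive_semidefinite(self, small_benchmark):
        recs = list(small_benchmark.records)[:25]
        S = similarity_matrix([transform(r, 11) for r in recs])
        evals = np.linalg.eigvalsh(S)
        assert evals.min() >= -1e-8

    def test_collision_robustness_16_vs_20_bits(self, fig2_record, gaga_records):
        """Hash-collision audit: widening the hash space barely moves
        similarities."""
        recs = [fig2_record] + gaga_records[:5]
        graphs = [transform(r, 11) for r in recs]
        S16 = similarity_matrix(graphs, KernelParams(bits=16))
        S20 = similarity_matrix(graphs, KernelParams(bits=20))
        assert np.abs(S16 - S20).max() < 0.01

    def test_tsv_roundtrip(self, tmp_path, gaga_records):
        graphs = [transform(r, 11) for r in gaga_records[:4]]
        S = similarity_matrix(graphs)
        ids = [r.id for r in gaga_records[:4]]
        write_similarity_tsv(S, ids, tmp_path / "s.tsv")
        back, back_ids = read_similarity_tsv(tmp_path / "s.tsv")
        assert back_ids == ids
        assert np.allclose(back, S, atol=1e-6)
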