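import numpy as np
import pytest

from peakclust import ClusterParams, SeqStruct, batched_cluster, dbscan_cluster, survey_thresholds
from peakclust.cluster import NOISE, generic_cluster, write_assignment_tsv
from peakclust.errors import DimensionMismatch
from peakclust.kernel import KernelParams

from oracles import dbscan_bruteforce


def ids_for(n):
    return [f"r{i}" for i in range(n)]


class TestDBSCAN:
    def test_identical_records_one_cluster(self):
        S = np.ones((20, 20))
        part = dbscan_cluster(S, ids_for(20), ClusterParams(threshold=0.3, min_samples=10))
        labels = set(part.assignment.values())
        assert labels == {0}

    def test_all_dissimilar_all_noise(self):
        S = np.eye(15)
        part = dbscan_cluster(S, ids_for(15), ClusterParams(threshold=0.3, min_samples=10))
        assert set(part.assignment.values()) == {NOISE}

    def test_two_blocks(self):
        """Two 12-record blocks, within-similarity 0.9 and cross 0.1: at
        eps 0.3 only within-block edges exist, giving exactly 2 clusters."""
        S = np.full((24, 24), 0.1)
        S[:12, :12] = 0.9
        S[12:, 12:] = 0.9
        np.fill_diagonal(S, 1.0)
        part = dbscan_cluster(S, ids_for(24), ClusterParams(threshold=0.3, min_samples=10))
        assert part.n_clusters == 2
        assert NOISE not in part.assignment.values()

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatch):
            dbscan_cluster(np.eye(3), ids_for(4), ClusterParams())

    def test_threshold_semantics(self):
        """Two records with similarity below 1 - x can never share a
        neighborhood at threshold x."""
        S = np.array([[1.0, 0.49], [0.49, 1.0]])
        part = dbscan_cluster(S, ids_for(2), ClusterParams(threshold=0.5, min_samples=2))
        assert set(part.assignment.values()) == {NOISE}
        S2 = np.array([[1.0, 0.51], [0.51, 1.0]])
        part2 = dbscan_cluster(S2, ids_for(2), ClusterParams(threshold=0.5, min_samples=2))
        assert part2.n_clusters == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_agrees_with_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 41))
        X = rng.random((n, 3))
        S = 1.0 - np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)) / np.sqrt(3)
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        eps = float(rng.uniform(0.1, 0.5))
        ms = int(rng.integers(2, 6))
        part = dbscan_cluster(S, ids_for(n), ClusterParams(threshold=eps, min_samples=ms))
        got = np.array([part.assignment[f"r{i}"] for i in range(n)])
        D = np.clip(1.0 - S, 0.0, None)
        np.fill_diagonal(D, 0.0)
        want = dbscan_bruteforce(D, eps, ms)
        # same noise set and same partition of the clustered points
        assert ((got == NOISE) == (want == NOISE)).all()
        for a in range(n):
            for b in range(a + 1, n):
                if got[a] != NOISE and got[b] != NOISE:
                    assert (got[a] == got[b]) == (want[a] == want[b])

    def test_coarsening_monotone_in_threshold(self):
        """Raising eps never increases the number of connected components of
        the eps-neighborhood graph."""
        rng = np.random.default_rng(5)
        S = rng.random((30, 30))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        import networkx as nx

        def n_components(eps):
            g = nx.Graph()
            g.add_nodes_from(range(30))
            D = 1 - S
            for i in range(30):
                for j in range(i + 1, 30):
                    if D[i, j] <= eps:
                        g.add_edge(i, j)
            return nx.number_connected_components(g)

        comps = [n_components(e) for e in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert comps == sorted(comps, reverse=True)


class TestBatched:
    def test_single_batch_identical_to_direct(self, small_benchmark):
        recs = list(small_benchmark.records)[:60]
        kp, cp = KernelParams(), ClusterParams(threshold=0.45, min_samples=5)
        from peakclust.graphs import transform
        from peakclust.kernel import nspdk_features, similarity_matrix_from_features

        S = similarity_matrix_from_features([nspdk_features(transform(r, 11), kp) for r in recs], kp.bits)
        direct = dbscan_cluster(S, [r.id for r in recs], cp)
        batched = batched_cluster(recs, kp, cp, option=11, seed=3)
        assert batched.assignment == direct.assignment

    def test_many_copies_merge_to_one_cluster(self):
        recs = [
            SeqStruct(id=f"c{i}", seq="GGGGAAAACCCC", struct="((((....))))")
            for i in range(2000)
        ]
        cp = ClusterParams(threshold=0.5, min_samples=10, batch_size=1400)
        part = batched_cluster(recs, KernelParams(), cp, option=11, seed=1)
        assert part.n_clusters == 1
        assert set(part.assignment.values()) == {0}

    def test_two_batches_recover_single_batch_structure(self):
        """Splitting the data across batches with merging yields the same
        number of non-noise clusters (within 1) as one direct run."""
        from peakclust import build_benchmark

        ds = build_benchmark(n_per_motif=30, n_decoys=120, seed=11)
        recs = list(ds.records)
        kp = KernelParams()
        single = batched_cluster(recs, kp, ClusterParams(threshold=0.45), option=11, seed=2)
        split = batched_cluster(
            recs, kp, ClusterParams(threshold=0.45, batch_size=135), option=11, seed=2
        )
        assert abs(single.n_clusters - split.n_clusters) <= 1


class TestSurvey:
    def test_empty_threshold_list(self, small_benchmark):
        recs = list(small_benchmark.records)
        tab = survey_thresholds(recs, KernelParams(), 11, [], small_benchmark.labels)
        assert tab.empty

    def test_identical_records_single_class(self):
        recs = [SeqStruct(id=f"i{k}", seq="GAGAGAGA", struct="........") for k in range(12)]
        tab = survey_thresholds(recs, KernelParams(), 3, [0.2, 0.6], ["m"] * 12, min_samples=5)
        assert np.allclose(tab["VMS"], 1.0)

    def test_rows_per_threshold(self, small_benchmark):
        recs = list(small_benchmark.records)
        tab = survey_thresholds(recs, KernelParams(), 11, [0.4, 0.5], small_benchmark.labels)
        assert list(tab["threshold"]) == [0.4, 0.5]
        assert set(tab.columns) >= {"ARI", "AMI", "HS", "CS", "VMS", "FMS", "n_clusters"}


class TestOtherAlgorithms:
    @pytest.mark.parametrize("algorithm", ["kmeans", "spectral", "affinity", "meanshift", "density"])
    def test_alternatives_run_and_assign_everyone(self, small_benchmark, algorithm):
        recs = list(small_benchmark.records)[:40]
        from peakclust.graphs import transform
        from peakclust.kernel import nspdk_features, similarity_matrix_from_features

        kp = KernelParams()
        S = similarity_matrix_from_features([nspdk_features(transform(r, 11), kp) for r in recs], kp.bits)
        part = generic_cluster(S, [r.id for r in recs], ClusterParams(algorithm=algorithm, n_clusters=3))
        assert len(part.assignment) == 40

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ClusterParams(threshold=0.0)
        with pytest.raises(ValueError):
            ClusterParams(min_samples=0)
        with pytest.raises(ValueError):
            ClusterParams(algorithm="upgma")
        with pytest.raises(ValueError):
            ClusterParams(batch_size=5, min_samples=10)


def test_assignment_tsv(tmp_path):
    S = np.ones((3, 3))
    part = dbscan_cluster(S, ids_for(3), ClusterParams(threshold=0.4, min_samples=2))
    write_assignment_tsv(part, tmp_path / "c.tsv", option=11, threshold=0.4)
    lines = (tmp_path / "c.tsv").read_text().splitlines()
    assert lines[0] == "record_id\tcluster\toption\tthreshold"
    assert len(lines) == 4
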