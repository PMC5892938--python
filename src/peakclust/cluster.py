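"""Density clustering of sequence/structure records from kernel similarities.

DBSCAN runs on the precomputed dissimilarity d = 1 - similarity with
eps = ``threshold``: at a threshold of x, two records whose similarity is
below 1 - x can never share a neighborhood.  Records that are not
density-reachable get the noise id (-1).

Large inputs are processed in seeded-shuffle batches (default 1400 records
per batch); clusters found in different batches are merged afterwards when
sampled cross-batch members are, on average, at least as similar as the
clustering threshold demands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import (
    DBSCAN,
    AffinityPropagation,
    KMeans,
    MeanShift,
    SpectralClustering,
)

from . import kernel as _kernel
from . import metrics as _metrics
from .errors import DimensionMismatch
from .graphs import transform
from .kernel import KernelParams
from .seqstruct import SeqStruct

#: distinguished cluster id for noise records
NOISE = -1

_ALGORITHMS = ("dbscan", "kmeans", "meanshift", "affinity", "spectral", "density")


@dataclass(frozen=True)
class ClusterParams:
    """Clustering controls.

    ``threshold`` is the dissimilarity threshold x in (0, 1); DBSCAN uses it
    as eps on d = 1 - similarity.  ``min_samples`` counts the point itself.
    """

    threshold: float = 0.5
    min_samples: int = 10
    algorithm: str = "dbscan"
    batch_size: int = 1400
    n_clusters: int = 5  # used only by kmeans/spectral
    density_delta: float = 0.3  # density-peak center cutoff

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.batch_size < self.min_samples:
            raise ValueError("batch_size must be >= min_samples")
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")


@dataclass(frozen=True)
class ClusterAssignment:
    """Mapping record-id -> cluster id; noise id is -1."""

    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len({c for c in self.assignment.values() if c != NOISE})

    def labels_for(self, ids: Sequence[str]) -> list[int]:
        return [self.assignment[i] for i in ids]


def _check_matrix(S: np.ndarray, n: Optional[int] = None) -> None:
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DimensionMismatch(f"similarity matrix must be square, got {S.shape}")
    if n is not None and S.shape[0] != n:
        raise DimensionMismatch(f"matrix of size {S.shape[0]} for {n} records")


def dbscan_cluster(S: np.ndarray, ids: Sequence[str], p: ClusterParams) -> ClusterAssignment:
    """DBSCAN on the precomputed distance 1 - S with eps = threshold."""
    _check_matrix(S, len(ids))
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    labels = DBSCAN(
        eps=p.threshold, min_samples=p.min_samples, metric="precomputed"
    ).fit_predict(D)
    return ClusterAssignment(dict(zip(ids, (int(c) for c in labels))))


def generic_cluster(S: np.ndarray, ids: Sequence[str], p: ClusterParams) -> ClusterAssignment:
    """Dispatch to the chosen clustering algorithm on the similarity matrix.

    DBSCAN is the algorithm all benchmark results use; the alternatives are
    exposed behind the same interface for exploration.
    """
    _check_matrix(S, len(ids))
    if p.algorithm == "dbscan":
        return dbscan_cluster(S, ids, p)
    D = np.clip(1.0 - S, 0.0, None)
    if p.algorithm == "density":
        labels = _density_peak(D, p)
    elif p.algorithm == "affinity":
        labels = AffinityPropagation(affinity="precomputed", random_state=0).fit_predict(S)
    elif p.algorithm == "spectral":
        labels = SpectralClustering(
            n_clusters=p.n_clusters, affinity="precomputed", random_state=0
        ).fit_predict(S)
    else:
        # kmeans / meanshift need a vector embedding; use classical MDS of
        # the kernel matrix (top components of the centered Gram matrix)
        coords = _kernel_embedding(S, dims=min(10, S.shape[0]))
        if p.algorithm == "kmeans":
            labels = KMeans(n_clusters=p.n_clusters, n_init=10, random_state=0).fit_predict(coords)
        else:
            labels = MeanShift().fit_predict(coords)
    return ClusterAssignment(dict(zip(ids, (int(c) for c in labels))))


def _kernel_embedding(S: np.ndarray, dims: int) -> np.ndarray:
    n = S.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ S @ J
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:dims]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def _density_peak(D: np.ndarray, p: ClusterParams) -> np.ndarray:
    """Density-peak clustering: centers have high local density and large
    distance to any denser point; remaining points follow their nearest
    denser neighbor."""
    n = D.shape[0]
    rho = (D < p.threshold).sum(axis=1) - 1
    order = np.argsort(-rho)
    delta = np.full(n, np.inf)
    nearest_denser = np.full(n, -1)
    for rank, i in enumerate(order):
        for j in order[:rank]:
            if D[i, j] < delta[i]:
                delta[i] = D[i, j]
                nearest_denser[i] = j
    delta[order[0]] = D[order[0]].max() if n > 1 else 0.0
    centers = [i for i in range(n) if rho[i] >= p.min_samples and delta[i] > p.density_delta]
    labels = np.full(n, NOISE)
    for c, i in enumerate(centers):
        labels[i] = c
    for i in order:
        if labels[i] == NOISE and nearest_denser[i] >= 0:
            labels[i] = labels[nearest_denser[i]]
    return labels


# ---------------------------------------------------------------------------
# Batched clustering with cross-batch merging
# ---------------------------------------------------------------------------


def batched_cluster(
    records: Sequence[SeqStruct],
    kp: KernelParams,
    cp: ClusterParams,
    option: int,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster any number of records, batching at ``cp.batch_size``.

    With a single batch this is identical to :func:`dbscan_cluster` on the
    full similarity matrix.  Otherwise records are shuffled with ``seed``,
    split into batches, clustered per batch, and clusters from different
    batches are merged when the mean similarity between up to 10 sampled
    members of each is at least 1 - threshold (transitive closure).
    """
    ids = [r.id for r in records]
    if len(records) <= cp.batch_size:
        vectors = [_featurize(r, kp, option) for r in records]
        S = _kernel.similarity_matrix_from_features(vectors, kp.bits)
        return generic_cluster(S, ids, cp)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    batches = [perm[i : i + cp.batch_size] for i in range(0, len(records), cp.batch_size)]

    vectors: dict[int, _kernel.SparseFeatureVector] = {}
    raw: dict[str, tuple[int, int]] = {}  # record id -> (batch, local cluster)
    n_clusters_per_batch: list[int] = []
    for b, batch_idx in enumerate(batches):
        vecs = []
        for i in batch_idx:
            v = _featurize(records[i], kp, option)
            vectors[i] = v
            vecs.append(v)
        S = _kernel.similarity_matrix_from_features(vecs, kp.bits)
        part = generic_cluster(S, [records[i].id for i in batch_idx], cp)
        for i in batch_idx:
            raw[records[i].id] = (b, part.assignment[records[i].id])
        n_clusters_per_batch.append(part.n_clusters)

    # union-find over (batch, cluster) keys
    members: dict[tuple[int, int], list[int]] = {}
    for i, r in enumerate(records):
        b, c = raw[r.id]
        if c != NOISE:
            members.setdefault((b, c), []).append(i)
    keys = sorted(members)
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for a_i, ka in enumerate(keys):
        for kb in keys[a_i + 1 :]:
            if ka[0] == kb[0]:
                continue  # same batch: DBSCAN already separated them
            if _mean_cross_similarity(members[ka], members[kb], vectors, rng) >= 1 - cp.threshold:
                ra, rb = find(ka), find(kb)
                if ra != rb:
                    parent[rb] = ra
    roots = sorted({find(k) for k in keys})
    root_id = {r: k for k, r in enumerate(roots)}
    assignment = {}
    for r in records:
        b, c = raw[r.id]
        assignment[r.id] = NOISE if c == NOISE else root_id[find((b, c))]
    return ClusterAssignment(assignment)


def _mean_cross_similarity(a: list[int], b: list[int], vectors, rng, k: int = 10) -> float:
    sa = a if len(a) <= k else list(rng.choice(a, size=k, replace=False))
    sb = b if len(b) <= k else list(rng.choice(b, size=k, replace=False))
    sims = [_kernel.similarity(vectors[i], vectors[j]) for i in sa for j in sb]
    return float(np.mean(sims))


def _featurize(record: SeqStruct, kp: KernelParams, option: int):
    return _kernel.nspdk_features(transform(record, option), kp)


def survey_thresholds(
    records: Sequence[SeqStruct],
    kp: KernelParams,
    option: int,
    thresholds: Sequence[float],
    truth: Sequence[str],
    min_samples: int = 10,
) -> pd.DataFrame:
    """Quality scores at each threshold (noise scored as one cluster).

    The similarity matrix is computed once and reused across thresholds.
    """
    rows = []
    if len(thresholds) > 0:
        ids = [r.id for r in records]
        vectors = [_featurize(r, kp, option) for r in records]
        S = _kernel.similarity_matrix_from_features(vectors, kp.bits)
        for thr in thresholds:
            cp = ClusterParams(threshold=thr, min_samples=min_samples)
            part = dbscan_cluster(S, ids, cp)
            q = _metrics.quality_scores(list(truth), part.labels_for(ids))
            rows.append({"threshold": thr, "n_clusters": part.n_clusters, **q.as_dict()})
    return pd.DataFrame(rows, columns=["threshold", "n_clusters", "ARI", "AMI", "HS", "CS", "VMS", "FMS"])


def write_assignment_tsv(part: ClusterAssignment, path, option: int, threshold: float) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tcluster\toption\tthreshold\n")
        for rid, c in part.assignment.items():
            fh.write(f"{rid}\t{c}\t{option}\t{threshold}\n")
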