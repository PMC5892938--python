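"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (enumeration, permutation, O(n^2)
pair counting) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

_VALID = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_HAIRPIN = 3


def max_pairing_bruteforce(seq: str) -> int:
    """Maximum number of nested WC/GU pairs (min hairpin loop 3) by
    exhaustive recursion over all nested pairings."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < MIN_HAIRPIN + 1:
            return 0
        out = best(i + 1, j)  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if (seq[i], seq[k]) in _VALID:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1) if seq else 0


def dbscan_bruteforce(D: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Textbook DBSCAN: core points have >= min_samples points (self
    included) within eps; clusters grow by BFS over cores in index order;
    border points join the first cluster that reaches them."""
    n = D.shape[0]
    neighbors = [np.where(D[i] <= eps)[0] for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cid
                if core[j]:
                    queue.extend(neighbors[j])
        cid += 1
    return labels


# ---------------------------------------------------------------------------
# rooted-labeled-graph canonical form (exact, via permutations)
# ---------------------------------------------------------------------------


def rooted_canonical_form(n: int, edges: frozenset, labels: tuple, root: int):
    """Exact canonical form of a rooted node-labeled graph: lexicographic
    minimum over all node permutations fixing the root."""
    best = None
    others = [v for v in range(n) if v != root]
    for perm in itertools.permutations(others):
        mapping = {root: 0}
        for k, v in enumerate(perm):
            mapping[v] = k + 1
        e = tuple(sorted(tuple(sorted((mapping[a], mapping[b]))) for a, b in edges))
        l = tuple(labels[v] for v in sorted(mapping, key=mapping.get))
        cand = (l, e)
        if best is None or cand < best:
            best = cand
    return best


def connected(n: int, edges) -> bool:
    seen = {0}
    frontier = [0]
    adj = {v: [] for v in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    while frontier:
        v = frontier.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                frontier.append(w)
    return len(seen) == n


# ---------------------------------------------------------------------------
# clustering-metric oracles
# ---------------------------------------------------------------------------


def rand_counts(truth, pred):
    """(TP, FP, FN, TN) over all unordered pairs."""
    n = len(truth)
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = truth[i] == truth[j]
            same_p = pred[i] == pred[j]
            if same_t and same_p:
                tp += 1
            elif not same_t and same_p:
                fp += 1
            elif same_t and not same_p:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def ari_oracle(truth, pred) -> float:
    tp, fp, fn, tn = rand_counts(truth, pred)
    a, b = tp + fn, tp + fp  # same-truth pairs, same-pred pairs
    total = tp + fp + fn + tn
    expected = a * b / total
    maximum = (a + b) / 2
    if maximum == expected:
        return 1.0
    return (tp - expected) / (maximum - expected)


def fms_oracle(truth, pred) -> float:
    tp, fp, fn, _ = rand_counts(truth, pred)
    if tp == 0:
        return 0.0
    return tp / math.sqrt((tp + fp) * (tp + fn))


def _entropy(labels) -> float:
    n = len(labels)
    out = 0.0
    for lab in set(labels):
        p = sum(1 for x in labels if x == lab) / n
        out -= p * math.log(p)
    return out


def _conditional_entropy(a, b) -> float:
    """H(a | b)."""
    n = len(a)
    out = 0.0
    for lab_b in set(b):
        idx = [i for i in range(n) if b[i] == lab_b]
        sub = [a[i] for i in idx]
        out += len(idx) / n * _entropy(sub)
    return out


def hcv_oracle(truth, pred):
    """Homogeneity, completeness, V-measure from first-principles entropy."""
    h_c, h_k = _entropy(truth), _entropy(pred)
    hs = 1.0 if h_c == 0 else 1.0 - _conditional_entropy(truth, pred) / h_c
    cs = 1.0 if h_k == 0 else 1.0 - _conditional_entropy(pred, truth) / h_k
    vms = 0.0 if hs + cs == 0 else 2 * hs * cs / (hs + cs)
    return hs, cs, vms


def mutual_information(truth, pred) -> float:
    return _entropy(truth) - _conditional_entropy(truth, pred)


def ami_permutation_oracle(truth, pred, n_draws: int = 100_000, seed: int = 0) -> float:
    """AMI with E[MI] estimated by Monte-Carlo label permutation."""
    rng = np.random.default_rng(seed)
    pred = list(pred)
    mi = mutual_information(truth, pred)
    emi = 0.0
    arr = np.array(pred)
    for _ in range(n_draws):
        rng.shuffle(arr)
        emi += mutual_information(truth, arr.tolist())
    emi /= n_draws
    denom = (_entropy(truth) + _entropy(pred)) / 2 - emi
    if denom == 0:
        return 0.0
    return (mi - emi) / denom


def overlap_pairs_naive(a_peaks, b_peaks):
    """Ids of peaks in `a` overlapping (>=1 bp, same chrom+strand) any peak
    of `b`, by O(n*m) comparison."""
    keep = []
    for p in a_peaks:
        for q in b_peaks:
            if (
                p.chrom == q.chrom
                and p.strand == q.strand
                and p.start < q.end
                and q.start < p.end
            ):
                keep.append(p.id)
                break
    return keep
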