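"""Clustering-quality measures.

Six external-validation scores comparing a predicted clustering against the
true motif classes: adjusted Rand index (ARI), adjusted mutual information
(AMI, arithmetic-mean normalization, natural-log entropies), homogeneity
(HS), completeness (CS), their harmonic mean the V-measure (VMS), and the
Fowlkes-Mallows score (FMS).  Computation delegates to scikit-learn.

Conventions for density clustering: all noise records form one predicted
cluster, and all random decoys share one true class label ("random").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sklearn import metrics as _skm

from .errors import LengthMismatch


@dataclass(frozen=True)
class QualityScores:
    ARI: float
    AMI: float
    HS: float
    CS: float
    VMS: float
    FMS: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ARI": self.ARI,
            "AMI": self.AMI,
            "HS": self.HS,
            "CS": self.CS,
            "VMS": self.VMS,
            "FMS": self.FMS,
        }


def _check(truth: Sequence, pred: Sequence) -> None:
    if len(truth) != len(pred):
        raise LengthMismatch(f"truth has {len(truth)} labels, prediction {len(pred)}")


def homogeneity_completeness_v(truth: Sequence, pred: Sequence) -> tuple[float, float, float]:
    """HS = 1 - H(C|K)/H(C), CS = 1 - H(K|C)/H(K), VMS their harmonic mean.

    Degenerate conventions: a conditional-entropy ratio with zero denominator
    scores 1; VMS is 0 when HS + CS = 0.
    """
    _check(truth, pred)
    hs, cs, vms = _skm.homogeneity_completeness_v_measure(truth, pred)
    return float(hs), float(cs), float(vms)


def adjusted_rand(truth: Sequence, pred: Sequence) -> float:
    """Pair-counting Rand index adjusted for chance."""
    _check(truth, pred)
    return float(_skm.adjusted_rand_score(truth, pred))


def adjusted_mutual_info(truth: Sequence, pred: Sequence) -> float:
    """Mutual information adjusted by its hypergeometric expectation and
    normalized by the arithmetic mean of the two entropies."""
    _check(truth, pred)
    return float(_skm.adjusted_mutual_info_score(truth, pred, average_method="arithmetic"))


def fowlkes_mallows(truth: Sequence, pred: Sequence) -> float:
    """TP / sqrt((TP+FP)(TP+FN)) over co-clustered pairs."""
    _check(truth, pred)
    return float(_skm.fowlkes_mallows_score(truth, pred))


def quality_scores(truth: Sequence, pred: Sequence) -> QualityScores:
    """All six measures for one truth/prediction pair."""
    hs, cs, vms = homogeneity_completeness_v(truth, pred)
    return QualityScores(
        ARI=adjusted_rand(truth, pred),
        AMI=adjusted_mutual_info(truth, pred),
        HS=hs,
        CS=cs,
        VMS=vms,
        FMS=fowlkes_mallows(truth, pred),
    )
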