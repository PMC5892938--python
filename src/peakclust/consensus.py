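"""Consensus motifs from clusters of sequence/structure records.

Members of a cluster are aligned globally over the combined alphabet of
(base, bracket) pairs: a column scores ``s_seq`` if the bases match plus
``s_str`` if the brackets match (defaults 2 + 2), 0 on a full mismatch, and
-1 per gap.  A center-star progressive alignment is seeded at the member
with the highest mean pairwise score; members whose clipped score against
the center is 0 are discarded as unalignable.  Column majorities give the
consensus sequence (base if it reaches half the members, else N) and the
consensus bracket.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Sequence

import numpy as np

from .errors import EmptyCluster
from .seqstruct import SeqStruct

GAP = "-"

S_SEQ = 2
S_STR = 2
GAP_PENALTY = -1


def align_pair(
    a: SeqStruct,
    b: SeqStruct,
    s_seq: int = S_SEQ,
    s_str: int = S_STR,
    gap: int = GAP_PENALTY,
) -> tuple[int, tuple[str, str], tuple[str, str]]:
    """Global alignment of two records over (base, bracket) columns.

    Returns (score, (gapped seq a, gapped struct a), (gapped seq b, gapped
    struct b)); the score is clipped at 0, which drives the discard rule.
    """
    n, m = len(a), len(b)
    F = np.zeros((n + 1, m + 1), dtype=np.int64)
    F[:, 0] = gap * np.arange(n + 1)
    F[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = F[i - 1, j - 1] + _col_score(a, b, i - 1, j - 1, s_seq, s_str)
            F[i, j] = max(match, F[i - 1, j] + gap, F[i, j - 1] + gap)
    # traceback (diagonal preferred, then up, then left — deterministic)
    i, j = n, m
    sa, ta, sb, tb = [], [], [], []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + _col_score(a, b, i - 1, j - 1, s_seq, s_str):
            sa.append(a.seq[i - 1]); ta.append(a.struct[i - 1])
            sb.append(b.seq[j - 1]); tb.append(b.struct[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            sa.append(a.seq[i - 1]); ta.append(a.struct[i - 1])
            sb.append(GAP); tb.append(GAP)
            i -= 1
        else:
            sa.append(GAP); ta.append(GAP)
            sb.append(b.seq[j - 1]); tb.append(b.struct[j - 1])
            j -= 1
    score = max(0, int(F[n, m]))
    rev = lambda parts: "".join(reversed(parts))
    return score, (rev(sa), rev(ta)), (rev(sb), rev(tb))


def _col_score(a, b, i, j, s_seq, s_str) -> int:
    return s_seq * (a.seq[i] == b.seq[j]) + s_str * (a.struct[i] == b.struct[j])


@dataclass(frozen=True)
class ConsensusMotif:
    cluster_id: int
    member_ids: tuple[str, ...]
    aligned_seqs: tuple[str, ...]
    aligned_structs: tuple[str, ...]
    consensus_seq: str
    consensus_struct: str
    base_profile: np.ndarray  # columns x alphabet {A,C,G,U,-}
    bracket_profile: np.ndarray  # columns x {(,),.,-}

    @property
    def length(self) -> int:
        return len(self.consensus_seq)


_BASE_ALPHA = "ACGU" + GAP
_BRACKET_ALPHA = "()." + GAP


def build_consensus(members: Sequence[SeqStruct], cluster_id: int = 0) -> ConsensusMotif:
    """Center-star progressive alignment and column-majority consensus.

    The center is the member with the highest mean pairwise alignment score;
    members scoring 0 against the center are discarded.  Gaps inserted into
    the center during progressive alignment are propagated into previously
    aligned rows (once a gap, always a gap).
    """
    if len(members) < 2:
        raise EmptyCluster("consensus needs at least 2 members")
    k = len(members)
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s, _, _ = align_pair(members[i], members[j])
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))

    kept = [i for i in range(k) if i == center or scores[center, i] > 0]
    if len(kept) < 2:
        raise EmptyCluster("all members discarded against the center")

    c = members[center]
    rows_seq = [c.seq]
    rows_struct = [c.struct]
    row_ids = [members[center].id]
    for i in kept:
        if i == center:
            continue
        # align the member against the ungapped center, then reconcile the
        # two gapped center versions (once a gap, always a gap)
        _, (ca_s, _), (mb_s, mb_t) = align_pair(c, members[i])
        master_gaps, new_gaps = _merge_gap_sets(rows_seq[0], ca_s)
        rows_seq = [_insert_gaps(r, master_gaps) for r in rows_seq]
        rows_struct = [_insert_gaps(r, master_gaps) for r in rows_struct]
        rows_seq.append(_insert_gaps(mb_s, new_gaps))
        rows_struct.append(_insert_gaps(mb_t, new_gaps))
        row_ids.append(members[i].id)

    L = len(rows_seq[0])
    base_prof = np.zeros((L, len(_BASE_ALPHA)))
    brack_prof = np.zeros((L, len(_BRACKET_ALPHA)))
    for r_seq, r_str in zip(rows_seq, rows_struct):
        for col in range(L):
            base_prof[col, _BASE_ALPHA.find(r_seq[col]) if r_seq[col] in _BASE_ALPHA else _BASE_ALPHA.index(GAP)] += 1
            brack_prof[col, _BRACKET_ALPHA.index(r_str[col])] += 1
    base_prof /= len(rows_seq)
    brack_prof /= len(rows_seq)

    cons_seq = []
    cons_struct = []
    for col in range(L):
        if base_prof[col, _BASE_ALPHA.index(GAP)] >= 0.5:
            cons_seq.append(GAP)
        else:
            top = int(np.argmax(base_prof[col, :4]))
            cons_seq.append(_BASE_ALPHA[top] if base_prof[col, top] >= 0.5 else "N")
        top_b = int(np.argmax(brack_prof[col, :3]))
        cons_struct.append(_BRACKET_ALPHA[top_b])
    return ConsensusMotif(
        cluster_id=cluster_id,
        member_ids=tuple(row_ids),
        aligned_seqs=tuple(rows_seq),
        aligned_structs=tuple(rows_struct),
        consensus_seq="".join(cons_seq),
        consensus_struct="".join(cons_struct),
        base_profile=base_prof,
        bracket_profile=brack_prof,
    )


def _merge_gap_sets(master: str, other: str) -> tuple[list[int], list[int]]:
    """Reconcile two gapped versions of the same ungapped string.

    Returns (columns of the merged alignment where `master` needs a new gap,
    columns where `other` needs a new gap), as insertion positions into the
    merged coordinate system, left to right.
    """
    a_gaps, b_gaps = [], []
    i = j = col = 0
    while i < len(master) or j < len(other):
        a = master[i] if i < len(master) else None
        b = other[j] if j < len(other) else None
        if a == GAP and b == GAP:
            i += 1; j += 1
        elif a == GAP:
            b_gaps.append(col)
            i += 1
        elif b == GAP:
            a_gaps.append(col)
            j += 1
        elif a is None:
            a_gaps.append(col)
            j += 1
        elif b is None:
            b_gaps.append(col)
            i += 1
        else:
            i += 1; j += 1
        col += 1
    return a_gaps, b_gaps


def _insert_gaps(row: str, positions: list[int]) -> str:
    out = list(row)
    for p in positions:  # positions are ascending merged-frame columns
        out.insert(p, GAP)
    return "".join(out)


def information_content(profile: np.ndarray, alphabet_size: int = 4) -> float:
    """Total information content of a base-frequency profile, in bits.

    Per column: log2(alphabet) - Shannon entropy of the base frequencies
    (gap mass ignored, frequencies renormalized).  A fully fixed column
    contributes 2 bits for RNA, so a fixed length-11 motif carries 22 bits.
    """
    total = 0.0
    for col in profile:
        p = np.asarray(col[:alphabet_size], dtype=float)
        if p.sum() <= 0:
            continue
        p = p / p.sum()
        h = -sum(x * log2(x) for x in p if x > 0)
        total += log2(alphabet_size) - h
    return total


def write_stockholm(motifs: Sequence[ConsensusMotif], path) -> None:
    """Stockholm-like text blocks: aligned rows plus #=GC SS_cons/seq_cons."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"# STOCKHOLM 1.0-like  cluster={m.cluster_id}\n")
            width = max(len(i) for i in m.member_ids) + 2
            for rid, row in zip(m.member_ids, m.aligned_seqs):
                fh.write(f"{rid:<{width}}{row}\n")
            fh.write(f"{'#=GC SS_cons':<{width}}{m.consensus_struct}\n")
            fh.write(f"{'#=GC seq_cons':<{width}}{m.consensus_seq}\n")
            fh.write("//\n")


def write_profile_tsv(m: ConsensusMotif, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\t" + "\t".join(_BASE_ALPHA) + "\t" + "\t".join(f"S{c}" for c in _BRACKET_ALPHA) + "\n")
        for col in range(m.length):
            fh.write(
                f"{col}\t"
                + "\t".join(f"{x:.4f}" for x in m.base_profile[col])
                + "\t"
                + "\t".join(f"{x:.4f}" for x in m.bracket_profile[col])
                + "\n"
            )
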