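"""Sequence/structure records, dot-bracket parsing, folding, and structured-FASTA I/O.

The central data model is :class:`SeqStruct` — one RNA with its secondary
structure in dot-bracket notation (matched parentheses are base pairs, dots
are unpaired).  Structures are required to be nested (no pseudoknots), which
is what the downstream graph representations assume.

Folding goes through a small engine registry.  The built-in engine is a
Nussinov maximum base-pairing folder (Watson-Crick + GU wobble, minimum
hairpin loop of 3 unpaired nucleotides, deterministic traceback).  An
``rnafold`` adapter shells out to the ViennaRNA ``RNAfold`` binary when it is
on PATH, for thermodynamic MFE structures; arbitrary callables mapping
sequence -> dot-bracket can be registered as additional engines.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .errors import (
    AdapterUnavailable,
    EmptySequence,
    FormatError,
    IllegalCharacter,
    UnbalancedStructure,
)

RNA_ALPHABET = frozenset("ACGUN")
STRUCT_ALPHABET = frozenset("().")

#: sentinel for unpaired positions in a PairTable
UNPAIRED = -1

#: allowed base pairs: Watson-Crick plus GU wobble
VALID_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: minimum number of unpaired nucleotides enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3


def normalize_seq(seq: str) -> str:
    """Uppercase and map DNA T to RNA U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise IllegalCharacter(f"illegal sequence characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SeqStruct:
    """One RNA record: id, sequence, dot-bracket structure, optional class label."""

    id: str
    seq: str
    struct: str
    label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_seq(self.seq))
        if len(self.seq) != len(self.struct):
            raise FormatError(
                f"{self.id}: sequence length {len(self.seq)} != "
                f"structure length {len(self.struct)}"
            )
        # validates alphabet and balance
        parse_dotbracket(self.struct)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairTable:
    """Canonical pairing map for a nested dot-bracket string.

    ``pairs[i]`` is the partner of position ``i`` (0-based) or ``UNPAIRED``.
    The mapping is involutive and nested by construction.
    """

    n: int
    pairs: np.ndarray = field(repr=False)

    def partner(self, i: int) -> int:
        return int(self.pairs[i])

    def is_paired(self, i: int) -> bool:
        return self.pairs[i] != UNPAIRED

    def pair_list(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, in order of opening position."""
        return [(i, int(j)) for i, j in enumerate(self.pairs) if j > i]

    @property
    def n_pairs(self) -> int:
        return int(np.sum(self.pairs >= 0)) // 2


def parse_dotbracket(struct: str) -> PairTable:
    """Stack-parse a dot-bracket string into a :class:`PairTable`.

    Raises :class:`UnbalancedStructure` on surplus brackets and
    :class:`IllegalCharacter` on anything outside ``(``, ``)``, ``.``
    (pseudoknot bracket alphabets are rejected, not coerced).
    """
    bad = set(struct) - STRUCT_ALPHABET
    if bad:
        raise IllegalCharacter(f"illegal structure characters: {sorted(bad)}")
    pairs = np.full(len(struct), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(struct):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise UnbalancedStructure(f"surplus ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
    if stack:
        raise UnbalancedStructure(f"surplus '(' at position {stack[-1]}")
    return PairTable(n=len(struct), pairs=pairs)


def render_dotbracket(pt: PairTable) -> str:
    """Inverse of :func:`parse_dotbracket` for nested pair tables."""
    out = ["."] * pt.n
    for i, j in pt.pair_list():
        out[i], out[j] = "(", ")"
    return "".join(out)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in VALID_PAIRS


# ---------------------------------------------------------------------------
# Folding engines
# ---------------------------------------------------------------------------


def nussinov_max_pairs(seq: str, min_hairpin: int = MIN_HAIRPIN) -> np.ndarray:
    """Nussinov DP table of maximum nested pair counts over all intervals.

    ``N[i, j]`` = max pairs in seq[i..j]; WC+GU pairs, hairpin loops must
    enclose at least ``min_hairpin`` unpaired bases.
    """
    n = len(seq)
    N = np.zeros((n, n), dtype=np.int32)  # inclusive interval indices
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j] if i + 1 <= j else 0
            for k in range(i + min_hairpin + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


def fold_nussinov(seq: str) -> str:
    """Maximum base-pairing structure with deterministic traceback.

    Tie-break: when leaving position i unpaired achieves the optimum, do so;
    otherwise pair i with the smallest admissible k (smallest bifurcation
    split point first).
    """
    n = len(seq)
    N = nussinov_max_pairs(seq)
    pairs = np.full(n, UNPAIRED, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < MIN_HAIRPIN + 1:
            continue
        if N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = N[k + 1, j] if k + 1 <= j else 0
                if 1 + left + right == N[i, j]:
                    pairs[i], pairs[k] = k, i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return render_dotbracket(PairTable(n=n, pairs=pairs))


def fold_rnafold_many(seqs: list[str]) -> list[str]:
    """Fold many sequences in one ``RNAfold`` process (MFE structures)."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise AdapterUnavailable("RNAfold binary not found on PATH")
    proc = subprocess.run(
        [exe, "--noPS"],
        input="".join(s + "\n" for s in seqs),
        capture_output=True,
        text=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) != 2 * len(seqs):
        raise FormatError("unexpected RNAfold output")
    structs = []
    for seq, line in zip(seqs, lines[1::2]):
        struct = line.split(None, 1)[0].strip()
        if len(struct) != len(seq):
            raise FormatError("RNAfold returned a structure of unexpected length")
        structs.append(struct)
    return structs


def fold_rnafold(seq: str) -> str:
    """Adapter for the ViennaRNA ``RNAfold`` binary (MFE structure)."""
    return fold_rnafold_many([seq])[0]


_ENGINES: dict[str, Callable[[str], str]] = {
    "nussinov": fold_nussinov,
    "rnafold": fold_rnafold,
}


def register_engine(name: str, fn: Callable[[str], str]) -> None:
    """Register an external folding engine mapping sequence -> dot-bracket."""
    _ENGINES[name] = fn


def fold(seq: str, engine: str = "nussinov") -> str:
    """Fold a sequence to a dot-bracket string with the chosen engine.

    Folding is applied to the exact region given — no flank extension.
    """
    if not seq:
        raise EmptySequence("cannot fold an empty sequence")
    if engine not in _ENGINES:
        raise AdapterUnavailable(f"unknown folding engine {engine!r}")
    seq = normalize_seq(seq)
    struct = _ENGINES[engine](seq)
    parse_dotbracket(struct)  # enforce the contract
    if len(struct) != len(seq):
        raise FormatError("engine returned structure of wrong length")
    return struct


def fold_many(seqs: list[str], engine: str = "nussinov") -> list[str]:
    """Fold a batch of sequences; one subprocess call for external engines."""
    if engine == "rnafold":
        seqs = [normalize_seq(s) for s in seqs]
        if any(not s for s in seqs):
            raise EmptySequence("cannot fold an empty sequence")
        structs = fold_rnafold_many(seqs)
        for s in structs:
            parse_dotbracket(s)
        return structs
    return [fold(s, engine=engine) for s in seqs]


# ---------------------------------------------------------------------------
# Structured FASTA (RNAfold output dialect)
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")


def _is_struct_line(line: str) -> bool:
    stripped = _ENERGY_RE.sub("", line.strip())
    return bool(stripped) and set(stripped) <= STRUCT_ALPHABET


def read_structured_fasta(path) -> list[SeqStruct]:
    """Read records of the form ``>id`` / sequence line(s) / structure line.

    A trailing RNAfold energy annotation like ``(-1.20)`` on the structure
    line is stripped.  Sequence may span multiple lines; the structure is the
    final line of each record.
    """
    records: list[SeqStruct] = []
    with open(path) as fh:
        header: Optional[str] = None
        body: list[str] = []
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records.append(_finish_record(header, body))
                header = line[1:].strip()
                body = []
            elif line.strip():
                body.append(line.strip())
        if header is not None:
            records.append(_finish_record(header, body))
    return records


def _finish_record(header: str, body: list[str]) -> SeqStruct:
    if not body:
        raise FormatError(f"record {header!r} has no sequence/structure lines")
    if not _is_struct_line(body[-1]):
        raise FormatError(f"record {header!r} lacks a structure line")
    struct = _ENERGY_RE.sub("", body[-1].strip())
    seq = "".join(body[:-1])
    if not seq:
        raise FormatError(f"record {header!r} has a structure but no sequence")
    ident, _, label = header.partition(" label=")
    ss = SeqStruct(id=ident.strip(), seq=seq, struct=struct, label=label or None)
    return ss


def write_structured_fasta(records: Iterable[SeqStruct], path) -> None:
    """Write records in the structured-FASTA dialect read back by
    :func:`read_structured_fasta`; labels round-trip via a ``label=`` tag."""
    with open(path, "w") as fh:
        for r in records:
            header = r.id if r.label is None else f"{r.id} label={r.label}"
            fh.write(f">{header}\n{r.seq}\n{r.struct}\n")


def read_plain_fasta(path, engine: str = "nussinov") -> list[SeqStruct]:
    """Read a plain FASTA of sequences and fold each with the given engine."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        out.append(SeqStruct(id=rec.id, seq=seq, struct=fold(seq, engine=engine)))
    return out
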