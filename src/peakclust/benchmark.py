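"""Synthetic sequence/structure motif benchmark.

Five designed motifs, each a sequence-constraint string (IUPAC N = any base)
plus a target secondary structure, represent the kinds of signal an
RNA-binding domain might read: a pure structure, a fixed word in a bulge, a
pyrimidine tract in an external region, a fixed word in a hairpin loop, and
a fixed word inside a double-stranded stem.  Instances are sampled uniformly
among sequences compatible with both the constraint and the structure
(paired positions restricted to Watson-Crick/GU pairs), with a rejection
filter that discards sequences whose maximum nested pairing far exceeds the
designed structure — a surrogate for sampling the low-energy ensemble.
Decoys are uniform random sequences with the same length distribution,
folded by the folding contract.

The default dataset is 100 instances per motif plus 1000 decoys (1500
records), deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InfeasibleSpec
from .seqstruct import (
    SeqStruct,
    VALID_PAIRS,
    fold,
    fold_many,
    nussinov_max_pairs,
    parse_dotbracket,
    write_structured_fasta,
)

BASES = "ACGU"

#: fixed-order pair alphabet (a plain set would not be stable across runs)
PAIR_TYPES = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"))

#: partners[b] = bases that can pair with b (WC + GU)
PARTNERS = {
    "A": ("U",),
    "C": ("G",),
    "G": ("C", "U"),
    "U": ("A", "G"),
}

#: slack allowed between a sampled sequence's max pair count and the
#: designed structure's pair count before the sample is rejected
PAIR_EXCESS_TOLERANCE = 2

DECOY_LABEL = "random"


@dataclass(frozen=True)
class SyntheticMotifSpec:
    """A motif as a sequence constraint plus a target dot-bracket structure."""

    name: str
    constraint: str  # over {A,C,G,U,N}
    structure: str

    def __post_init__(self):
        if len(self.constraint) != len(self.structure):
            raise InfeasibleSpec(f"{self.name}: constraint/structure length mismatch")
        pt = parse_dotbracket(self.structure)
        for i, j in pt.pair_list():
            a, b = self.constraint[i], self.constraint[j]
            if a != "N" and b != "N" and (a, b) not in VALID_PAIRS:
                raise InfeasibleSpec(f"{self.name}: fixed pair {a}-{b} at ({i},{j}) is invalid")

    def __len__(self) -> int:
        return len(self.constraint)


def builtin_specs() -> list[SyntheticMotifSpec]:
    """The five benchmark motifs."""
    return [
        SyntheticMotifSpec(
            "special_structure",
            "NNNNNNNNNNNNNNNNNNNNNNNNNN",
            "((.((((..((...))..))..))))",
        ),
        SyntheticMotifSpec(
            "AUG_in_Bulge",
            "NNNNAUGNNNNNNNNNNNNN",
            "((((...(((...)))))))",
        ),
        SyntheticMotifSpec(
            "pyrimidine_tract",
            "NNNNNNNNNNNCCUCU",
            "((((...)))).....",
        ),
        SyntheticMotifSpec(
            "GAGA_in_Hairpin",
            "NNNNNGAGANNNNN",
            "(((((....)))))",
        ),
        SyntheticMotifSpec(
            "GGUCG_in_left_stem",
            "NNGGUCGNNNNNNNNNN",
            "(((((((...)))))))",
        ),
    ]


def sample_motif_instance(
    spec: SyntheticMotifSpec,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> SeqStruct:
    """Draw one constraint-compatible instance of a motif.

    Fixed positions are copied verbatim; unpaired Ns are uniform over ACGU;
    paired N-N positions are a uniform draw among the six valid pair types;
    a pair with one fixed side draws uniformly among that base's partners.
    Samples whose Nussinov maximum pair count exceeds the designed pair count
    by more than :data:`PAIR_EXCESS_TOLERANCE` are resampled (up to
    ``max_attempts``; then the least-excess sample seen is returned, so
    generation is total).
    """
    pt = parse_dotbracket(spec.structure)
    target_pairs = pt.n_pairs
    best: Optional[str] = None
    best_excess = None
    for _ in range(max_attempts):
        seq = _sample_sequence(spec, pt, rng)
        excess = int(nussinov_max_pairs(seq)[0, len(seq) - 1]) - target_pairs if len(seq) > 1 else 0
        if best_excess is None or excess < best_excess:
            best, best_excess = seq, excess
        if excess <= PAIR_EXCESS_TOLERANCE:
            break
    return SeqStruct(id="", seq=best, struct=spec.structure, label=spec.name)


def _sample_sequence(spec: SyntheticMotifSpec, pt, rng: np.random.Generator) -> str:
    seq = list(spec.constraint)
    for i, j in pt.pair_list():
        a, b = seq[i], seq[j]
        if a != "N" and b != "N":
            continue  # feasibility already validated by the spec
        if a != "N":
            seq[j] = PARTNERS[a][int(rng.integers(len(PARTNERS[a])))]
        elif b != "N":
            seq[i] = PARTNERS[b][int(rng.integers(len(PARTNERS[b])))]
        else:
            pair = PAIR_TYPES[int(rng.integers(6))]
            seq[i], seq[j] = pair
    for k, c in enumerate(seq):
        if c == "N":
            seq[k] = BASES[int(rng.integers(4))]
    return "".join(seq)


def motif_length_pool(specs: Optional[Sequence[SyntheticMotifSpec]] = None) -> list[int]:
    specs = list(specs) if specs is not None else builtin_specs()
    return [len(s) for s in specs]


#: decoys carry thermodynamic MFE structures (the RNAfold adapter); the
#: Nussinov fallback over-pairs uniform random sequences, which makes the
#: decoy pool artificially self-similar under paired-label masking
DECOY_ENGINE = "rnafold"


def sample_decoy(
    length_pool: Sequence[int],
    rng: np.random.Generator,
    engine: str = DECOY_ENGINE,
) -> SeqStruct:
    """Uniform random sequence with length drawn from the pool, folded."""
    n = int(rng.choice(np.asarray(length_pool)))
    seq = "".join(BASES[k] for k in rng.integers(4, size=n))
    return SeqStruct(id="", seq=seq, struct=fold(seq, engine=engine), label=DECOY_LABEL)


@dataclass(frozen=True)
class LabeledDataset:
    records: tuple[SeqStruct, ...]
    seed: int

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + 1
        return out


def build_benchmark(
    n_per_motif: int = 100,
    n_decoys: int = 1000,
    seed: int = 0,
    specs: Optional[Sequence[SyntheticMotifSpec]] = None,
    decoy_engine: str = DECOY_ENGINE,
) -> LabeledDataset:
    """The full labeled benchmark: motif instances plus decoys, shuffled.

    Deterministic given the seed; defaults give 5*100 + 1000 = 1500 records.
    """
    rng = np.random.default_rng(seed)
    specs = list(specs) if specs is not None else builtin_specs()
    pool = [len(s) for s in specs]
    records: list[SeqStruct] = []
    for spec in specs:
        for k in range(n_per_motif):
            inst = sample_motif_instance(spec, rng)
            records.append(
                SeqStruct(id=f"{spec.name}_{k:04d}", seq=inst.seq, struct=inst.struct, label=spec.name)
            )
    lengths = [int(rng.choice(np.asarray(pool))) for _ in range(n_decoys)]
    seqs = ["".join(BASES[b] for b in rng.integers(4, size=n)) for n in lengths]
    for k, (seq, struct) in enumerate(zip(seqs, fold_many(seqs, engine=decoy_engine))):
        records.append(SeqStruct(id=f"random_{k:04d}", seq=seq, struct=struct, label=DECOY_LABEL))
    order = rng.permutation(len(records))
    return LabeledDataset(tuple(records[i] for i in order), seed=seed)


def write_benchmark(ds: LabeledDataset, fasta_path, labels_path) -> None:
    """Structured FASTA plus a truth-labels TSV."""
    write_structured_fasta(ds.records, fasta_path)
    with open(labels_path, "w") as fh:
        fh.write("record_id\tlabel\n")
        for r in ds.records:
            fh.write(f"{r.id}\t{r.label}\n")
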