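"""CLIP peak post-processing.

Peaks arrive as BED intervals (one file per replicate plus a size-matched
control).  Processing keeps peaks supported by both replicates, removes
those overlapping the control, restricts lengths to a foldable range, splits
multi-stem-loop peaks into one derived peak per outermost stem-loop, and
extracts strand-aware sequences from a genome FASTA for folding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from intervaltree import IntervalTree
from pyfaidx import Fasta

from .errors import MissingChrom
from .seqstruct import SeqStruct, parse_dotbracket

MIN_PEAK_LEN = 10
MAX_PEAK_LEN = 80

_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")


@dataclass(frozen=True)
class Peak:
    """Genomic interval, 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str
    score: float = 0.0
    gene: Optional[str] = None
    region_type: Optional[str] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(path) -> list[Peak]:
    """BED6 (or BED3/4/5) reader; missing name/score/strand get defaults."""
    peaks = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            peaks.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    id=f[3] if len(f) > 3 and f[3] != "." else f"peak_{k}",
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{p.score:g}\t{p.strand}\n")


def _trees(peaks: Sequence[Peak]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for p in peaks:
        trees.setdefault((p.chrom, p.strand), IntervalTree()).addi(p.start, p.end)
    return trees


def intersect_replicates(a: Sequence[Peak], b: Sequence[Peak]) -> list[Peak]:
    """Keep peaks of `a` overlapping (>= 1 bp, same strand) any peak of `b`.

    The retained peak keeps replicate-A coordinates unchanged.
    """
    trees = _trees(b)
    return [p for p in a if trees.get((p.chrom, p.strand)) and trees[(p.chrom, p.strand)].overlap(p.start, p.end)]


def subtract_control(peaks: Sequence[Peak], control: Sequence[Peak]) -> list[Peak]:
    """Drop any peak overlapping (>= 1 bp, same strand) a control peak."""
    trees = _trees(control)
    return [
        p
        for p in peaks
        if not (trees.get((p.chrom, p.strand)) and trees[(p.chrom, p.strand)].overlap(p.start, p.end))
    ]


def _outermost_stemloops(struct: str) -> list[tuple[int, int]]:
    """Top-level paired intervals [i, j] (inclusive), left to right."""
    pt = parse_dotbracket(struct)
    spans = []
    p = 0
    while p < pt.n:
        if pt.is_paired(p) and pt.partner(p) > p:
            spans.append((p, pt.partner(p)))
            p = pt.partner(p) + 1
        else:
            p += 1
    return spans


def filter_and_split(
    peaks_with_structs: Sequence[tuple[Peak, SeqStruct]],
    min_len: int = MIN_PEAK_LEN,
    max_len: int = MAX_PEAK_LEN,
) -> list[tuple[Peak, SeqStruct]]:
    """Length-filter peaks (inclusive bounds) and split multi-stem-loop peaks.

    A retained peak whose structure has >= 2 outermost stem-loops yields one
    derived peak per stem-loop, spanning the stem-loop plus flanking unpaired
    bases up to the midpoint between neighboring stem-loops.  Derived ids
    suffix the parent id.  Local record coordinates map back to genomic
    coordinates strand-awarely (the record of a minus-strand peak is its
    reverse complement).
    """
    out: list[tuple[Peak, SeqStruct]] = []
    for peak, ss in peaks_with_structs:
        n = len(peak)
        if n < min_len or n > max_len:
            continue
        spans = _outermost_stemloops(ss.struct)
        if len(spans) < 2:
            out.append((peak, ss))
            continue
        # extend each span to the midpoint of the unpaired gap on each side
        bounds = []
        for k, (i, j) in enumerate(spans):
            left = 0 if k == 0 else (spans[k - 1][1] + 1 + i) // 2 + (spans[k - 1][1] + 1 + i) % 2
            right = n - 1 if k == len(spans) - 1 else (j + spans[k + 1][0]) // 2
            bounds.append((left, right))
        for k, (lo, hi) in enumerate(bounds):
            sub_seq = ss.seq[lo : hi + 1]
            sub_struct = ss.struct[lo : hi + 1]
            if peak.strand == "+":
                g_start, g_end = peak.start + lo, peak.start + hi + 1
            else:
                g_start, g_end = peak.end - hi - 1, peak.end - lo
            derived = replace(peak, start=g_start, end=g_end, id=f"{peak.id}/sl{k + 1}")
            out.append((derived, SeqStruct(id=derived.id, seq=sub_seq, struct=sub_struct, label=ss.label)))
    return out


def extract_sequences(peaks: Sequence[Peak], genome_fasta, flank: int = 0) -> list[tuple[Peak, str]]:
    """Strand-aware sequence extraction (reverse complement on minus strand).

    ``flank`` extends both sides (0 by default: structures are predicted on
    the exact binding region).  Out-of-bounds coordinates are clipped with a
    warning.
    """
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    out = []
    for p in peaks:
        if p.chrom not in genome:
            raise MissingChrom(f"{p.chrom} not present in {genome_fasta}")
        chrom_len = len(genome[p.chrom])
        start = p.start - flank
        end = p.end + flank
        if start < 0 or end > chrom_len:
            warnings.warn(f"{p.id}: flanked interval clipped to chromosome bounds")
            start, end = max(0, start), min(chrom_len, end)
        seq = str(genome[p.chrom][start:end]).upper().replace("T", "U")
        if p.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        out.append((p, seq))
    return out


def process_peaks(
    rep1: Sequence[Peak],
    rep2: Sequence[Peak],
    control: Sequence[Peak],
) -> list[Peak]:
    """Replicate intersection followed by control subtraction."""
    return subtract_control(intersect_replicates(rep1, rep2), control)
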