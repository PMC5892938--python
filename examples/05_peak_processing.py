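"""CLIP peak post-processing on a toy genome.

Run:  python examples/05_peak_processing.py
"""

import tempfile
from pathlib import Path

from peakclust import SeqStruct, extract_sequences, filter_and_split, fold
from peakclust.peaks import Peak, process_peaks

tmp = Path(tempfile.mkdtemp())
genome = tmp / "genome.fa"
genome.write_text(
    ">chr1\nACGTACGTACGTACGTGGGGAAACCAACCTGTACGTACGTACGTACGT\n"
    ">chr2\nAAAATTTTGGGGAAAACCCCAAGGGGAAAACCCCAAAATTTT\n"
)

rep1 = [
    Peak(chrom="chr1", start=16, end=32, strand="+", id="site1"),
    Peak(chrom="chr2", start=8, end=34, strand="+", id="site2"),
    Peak(chrom="chr1", start=0, end=8, strand="+", id="background"),
]
rep2 = [
    Peak(chrom="chr1", start=20, end=36, strand="+", id="r2a"),
    Peak(chrom="chr2", start=10, end=30, strand="+", id="r2b"),
]
control = [Peak(chrom="chr1", start=0, end=10, strand="+", id="ctl")]

kept = process_peaks(rep1, rep2, control)
print(f"{len(rep1)} replicate-1 peaks -> {len(kept)} after requiring replicate-2")
print("overlap and subtracting control hits:", [p.id for p in kept])

folded = []
for peak, seq in extract_sequences(kept, genome):
    ss = SeqStruct(id=peak.id, seq=seq, struct=fold(seq))
    folded.append((peak, ss))
    print(f"  {peak.id}: {seq} -> {ss.struct}")

derived = filter_and_split(folded)
print(f"\nafter the 10-80 nt filter and stem-loop splitting: {len(derived)} records")
for peak, ss in derived:
    print(f"  {peak.id:10s} {peak.chrom}:{peak.start}-{peak.end}  {ss.struct}")
print("\nsite2 folds into two independent stem-loops, so it is split into one")
print("derived peak per stem-loop (ids suffix the parent) before clustering.")
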