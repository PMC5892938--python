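import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from peakclust import SeqStruct, build_benchmark
from peakclust.benchmark import builtin_specs, sample_motif_instance


@pytest.fixture(scope="session")
def fig2_record() -> SeqStruct:
    """Worked stem-loop example: two stacked stems, a bulge, and a 3' tail."""
    return SeqStruct(id="fig2", seq="GGGGAAACCAACCUGU", struct="((((...))..))...")


@pytest.fixture(scope="session")
def gaga_records():
    """20 sampled instances of the GAGA-in-hairpin motif."""
    rng = np.random.default_rng(42)
    spec = next(s for s in builtin_specs() if s.name == "GAGA_in_Hairpin")
    out = []
    for k in range(20):
        inst = sample_motif_instance(spec, rng)
        out.append(SeqStruct(id=f"gaga_{k}", seq=inst.seq, struct=inst.struct, label=inst.label))
    return out


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced benchmark: 10 instances per motif + 40 decoys."""
    return build_benchmark(n_per_motif=10, n_decoys=40, seed=7)


@pytest.fixture()
def toy_genome(tmp_path) -> Path:
    """Two-chromosome toy genome FASTA with .fai-indexable layout."""
    path = tmp_path / "genome.fa"
    chr1 = "ACGTACGTACGTACGTGGGGAAACCAACCTGTACGTACGTACGTACGT"
    chr2 = "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA"
    path.write_text(f">chr1\n{chr1}\n>chr2\n{chr2}\n")
    return path
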