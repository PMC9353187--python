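import numpy as np
import pandas as pd
import pytest

from cpgfill.io import GenomeIndex, MethylomeProfile, write_fasta


@pytest.fixture()
def tiny_genome(tmp_path):
    """Two short chromosomes with known CpG sites."""
    seqs = {
        "chr1": "AACGTTCGATCGGGCGTTAACGTACGTA",   # CpGs at 3, 7, 11, 15, 21, 25
        "chr2": "TTTTACGTTTTTTTTTCGCGAAAT",       # CpGs at 6, 17, 19
    }
    path = tmp_path / "tiny.fa"
    write_fasta(seqs, path)
    return GenomeIndex(path)


@pytest.fixture()
def random_genome(tmp_path):
    """A 10-kb random chromosome for oracle comparisons."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), p=[0.29, 0.21, 0.21, 0.29],
                             size=10_000))
    path = tmp_path / "rand.fa"
    write_fasta({"chr1": seq}, path)
    return GenomeIndex(path)


def profile_from_records(sample_id, rows, role="source"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "level", "total_reads"])
    return MethylomeProfile(sample_id=sample_id, records=df, role=role)


@pytest.fixture()
def make_profile():
    return profile_from_records
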