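"""Shared hand-built fixtures used by unit and acceptance tests."""

import pandas as pd

# 20 calls against the tiny two-chromosome genome of conftest.tiny_genome
# (chr1 CpG sites: 3, 7, 11, 15, 21, 25; chr2: 6, 17, 19); expected
# outcomes of the cleaning pipeline are documented in test_preprocess.
TOY_CALLS = [
    ("chr1", 3, 5, 5), ("chr1", 4, 6, 6),        # concordant methylated
    ("chr1", 7, 5, 5), ("chr1", 8, 0, 6),        # hemi-methylated
    ("chr1", 11, 4, 8), ("chr1", 12, 0, 4),      # 0.5 binarises to 0
    ("chr1", 15, 4, 4),                          # single strand
    ("chr1", 21, 2, 3), ("chr1", 22, 5, 6),      # depth-filtered then single
    ("chr1", 25, 1, 10), ("chr1", 26, 2, 10),    # concordant unmethylated
    ("chr1", 5, 1, 4), ("chr1", 17, 2, 5), ("chr1", 27, 0, 6),
    ("chr2", 1, 3, 4),                           # non-CpG positions
    ("chr2", 6, 9, 10), ("chr2", 7, 8, 10),      # concordant methylated
    ("chr2", 17, 3, 3), ("chr2", 18, 4, 4),      # depth-filtered then single
    ("chr2", 20, 10, 10),                        # reverse strand only
]


def toy_frame():
    df = pd.DataFrame(TOY_CALLS, columns=["chrom", "pos", "meth_reads",
                                          "total_reads"])
    df["strand"] = "."
    return df[["chrom", "pos", "strand", "meth_reads", "total_reads"]]
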