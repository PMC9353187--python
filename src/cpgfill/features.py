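"""Genomic-feature coverage and methylation summarisation.

Features are 300-bp genome bins (tiling, trailing partial bins dropped),
1001-bp promoters centred on annotated TSSs, and CpG islands from a BED
annotation.  A bin "has data" in a profile when it contains at least 3 CpG
sites with a known state; promoters and CGIs, being longer, require at
least 10.  After imputation, "known state" means observed plus retained-
imputed sites.  A CpG is assigned to a feature by its forward-strand C
position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeIndex, MethylomeProfile, _open_text

MIN_CPGS = {"bin300": 3, "promoter": 10, "cgi": 10}
BIN_LEN = 300
PROMOTER_LEN = 1001


@dataclass
class FeatureSet:
    """Intervals (1-based inclusive) of one feature kind."""

    kind: str
    intervals: pd.DataFrame  # columns: chrom, start, end [, name]

    def __post_init__(self):
        if self.kind not in MIN_CPGS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        need = {"chrom", "start", "end"} - set(self.intervals.columns)
        if need:
            raise ValueError(f"intervals missing columns {sorted(need)}")
        self.intervals = self.intervals.reset_index(drop=True)

    @property
    def min_cpgs_with_data(self) -> int:
        return MIN_CPGS[self.kind]

    def __len__(self) -> int:
        return len(self.intervals)


def tile_genome(genome: GenomeIndex, bin_len: int = BIN_LEN) -> FeatureSet:
    """Equal-sized non-overlapping bins per chromosome (floor(L/bin) bins)."""
    rows = []
    for chrom in genome.chroms:
        n = genome.chrom_len(chrom) // bin_len
        for i in range(n):
            rows.append((chrom, i * bin_len + 1, (i + 1) * bin_len))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows else \
        pd.DataFrame(columns=["chrom", "start", "end"])
    return FeatureSet(kind="bin300", intervals=df)


def promoters_from_tss(tss_table: pd.DataFrame,
                       genome: GenomeIndex | None = None,
                       flank: int = (PROMOTER_LEN - 1) // 2) -> FeatureSet:
    """1001-bp promoter windows centred on TSSs, clipped to chromosome ends.

    ``tss_table`` needs columns chrom, tss (1-based) and optionally
    gene_id/strand.  Duplicate rows are dropped; clipped (short) promoters
    are flagged in a ``clipped`` column.
    """
    t = tss_table.drop_duplicates(subset=[c for c in ("chrom", "tss", "strand")
                                          if c in tss_table.columns])
    start = (t["tss"].astype(int) - flank).clip(lower=1)
    end = t["tss"].astype(int) + flank
    if genome is not None:
        lens = t["chrom"].map({c: genome.chrom_len(c) for c in genome.chroms})
        end = np.minimum(end, lens.astype(int))
    df = pd.DataFrame({"chrom": t["chrom"].to_numpy(), "start": start.to_numpy(),
                       "end": np.asarray(end)})
    if "gene_id" in t.columns:
        df["name"] = t["gene_id"].to_numpy()
    df["clipped"] = (df["end"] - df["start"] + 1) < PROMOTER_LEN
    return FeatureSet(kind="promoter", intervals=df)


def read_cgi_bed(path) -> FeatureSet:
    """CGI intervals from BED (0-based half-open, converted on read)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return FeatureSet(kind="cgi", intervals=pd.DataFrame(
        rows, columns=["chrom", "start", "end"]))


def _site_counts(sites: MethylomeProfile, fs: FeatureSet) -> np.ndarray:
    """Number of profile CpG sites inside each interval."""
    counts = np.zeros(len(fs), dtype=np.int64)
    by_chrom = sites.by_chrom()
    for chrom, sub in fs.intervals.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        p, _ = by_chrom[chrom]
        lo = np.searchsorted(p, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(p, sub["end"].to_numpy(), side="right")
        counts[sub.index.to_numpy()] = hi - lo
    return counts


def feature_coverage(profile: MethylomeProfile, fs: FeatureSet
                     ) -> tuple[float, np.ndarray]:
    """Fraction of features with data, plus the per-feature boolean flags."""
    counts = _site_counts(profile, fs)
    flags = counts >= fs.min_cpgs_with_data
    frac = float(flags.mean()) if len(fs) else 0.0
    return frac, flags


def _mean_levels(profile: MethylomeProfile, fs: FeatureSet) -> np.ndarray:
    """Per-feature mean CpG level; NaN where no site falls in the feature."""
    means = np.full(len(fs), np.nan)
    by_chrom = profile.by_chrom()
    for chrom, sub in fs.intervals.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        p, lv = by_chrom[chrom]
        cum = np.concatenate([[0.0], np.cumsum(lv)])
        lo = np.searchsorted(p, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(p, sub["end"].to_numpy(), side="right")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            m = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1), np.nan)
        means[sub.index.to_numpy()] = m
    return means


def feature_methylation_matrix(profiles: list[MethylomeProfile],
                               fs: FeatureSet) -> pd.DataFrame:
    """Features x profiles matrix of mean CpG levels.

    Rows are restricted to features that have data (>= the kind's minimum
    CpG count) in *every* profile, matching the complete-case bin analysis.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    flags = np.ones(len(fs), dtype=bool)
    cols = {}
    for prof in profiles:
        counts = _site_counts(prof, fs)
        flags &= counts >= fs.min_cpgs_with_data
        cols[prof.sample_id] = _mean_levels(prof, fs)
    if not flags.any():
        raise ValueError("no feature has data in every profile; "
                         "consider imputing more sites first")
    idx = fs.intervals.index[flags]
    labels = [f"{r.chrom}:{r.start}-{r.end}"
              for r in fs.intervals.loc[idx].itertuples(index=False)]
    mat = pd.DataFrame({k: v[flags] for k, v in cols.items()}, index=labels)
    return mat


def profile_correlations(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of profiles over complete features."""
    if len(matrix) < 2:
        raise ValueError("correlation needs at least two complete features")
    r = np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(r, index=matrix.columns, columns=matrix.columns)
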