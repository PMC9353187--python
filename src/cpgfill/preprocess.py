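"""Cleaning raw methylation calls into per-CpG-site profiles.

The pipeline order is fixed: merge replicates, drop low-depth calls, merge
strands.  Strand merging keeps a CpG site only when both strand cytosines
survive the depth filter *and* their binarised states agree (discordant
sites are hemi-methylated profiling artifacts; DNA methylation is expected
strand-symmetric).  The kept level pools the read counts of both strands,
counts being the sufficient statistic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import (GenomeIndex, MethylomeProfile, infer_strands,
                 merge_replicates, validate_calls)

DEFAULT_MIN_READS = 4   # "no greater than 3" overlapping reads are excluded


@dataclass
class CleaningReport:
    """Per-profile accounting of the cleaning pipeline.

    Counts are in units of *calls* (per-strand records) for the input and
    depth/non-CpG categories, and in units of *sites* for the single-strand,
    hemi-methylated and kept categories.
    """

    n_input_calls: int = 0
    n_removed_low_depth: int = 0
    n_not_cpg: int = 0
    n_single_strand: int = 0
    n_hemi_methylated: int = 0
    n_sites_kept: int = 0
    coverage_rate: float = 0.0
    methylation_rate: float = float("nan")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def filter_low_depth(calls: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS
                     ) -> pd.DataFrame:
    """Keep calls with ``total_reads >= min_reads`` (default keeps >= 4)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return calls[calls["total_reads"] >= min_reads].reset_index(drop=True)


def merge_strands(calls: pd.DataFrame, genome: GenomeIndex,
                  binarize_threshold: float = 0.5,
                  ) -> tuple[pd.DataFrame, CleaningReport]:
    """Collapse per-strand calls into strand-symmetric CpG site records.

    Expects depth-filtered calls.  Returns ``(records, report)`` where
    records has columns ``chrom, pos, level, total_reads`` (pos = the
    forward-strand C) and the report counts exclusions.  Binarisation is
    strict (level > threshold is methylated), so a strand exactly at the
    threshold counts as unmethylated.
    """
    report = CleaningReport(n_input_calls=int(len(calls)))
    empty = pd.DataFrame({"chrom": pd.Series(dtype=str),
                          "pos": pd.Series(dtype=np.int64),
                          "level": pd.Series(dtype=float),
                          "total_reads": pd.Series(dtype=np.int64)})
    if calls.empty:
        return empty, report
    validate_calls(calls)
    calls = calls.copy()
    if (calls["strand"] == ".").any():
        calls = infer_strands(calls, genome)

    # map each cytosine to its CpG site (forward-strand C position)
    site = np.where(calls["strand"].to_numpy() == "-",
                    calls["pos"].to_numpy() - 1, calls["pos"].to_numpy())
    calls["site"] = site

    # a valid site must be a CG dinucleotide on the forward strand
    ok = np.zeros(len(calls), dtype=bool)
    stranded = calls["strand"].isin(["+", "-"]).to_numpy()
    for chrom, sub in calls.groupby("chrom", sort=False):
        cpg = genome.cpg_positions(chrom)
        if len(cpg) == 0:
            continue
        s = sub["site"].to_numpy()
        i = np.searchsorted(cpg, s)
        hit = (i < len(cpg)) & (cpg[np.minimum(i, len(cpg) - 1)] == s)
        ok[sub.index.to_numpy()] = hit
    ok &= stranded
    report.n_not_cpg = int((~ok).sum())
    calls = calls[ok]
    if calls.empty:
        return empty, report

    piv = calls.pivot_table(index=["chrom", "site"], columns="strand",
                            values=["meth_reads", "total_reads"], aggfunc="sum")
    for col in [("meth_reads", "+"), ("meth_reads", "-"),
                ("total_reads", "+"), ("total_reads", "-")]:
        if col not in piv.columns:
            piv[col] = np.nan
    has_plus = piv[("total_reads", "+")].notna().to_numpy()
    has_minus = piv[("total_reads", "-")].notna().to_numpy()
    both = has_plus & has_minus
    report.n_single_strand = int((has_plus ^ has_minus).sum())

    sub = piv[both]
    mp = sub[("meth_reads", "+")].to_numpy(float)
    mm = sub[("meth_reads", "-")].to_numpy(float)
    tp = sub[("total_reads", "+")].to_numpy(float)
    tm = sub[("total_reads", "-")].to_numpy(float)
    state_p = (mp / tp) > binarize_threshold
    state_m = (mm / tm) > binarize_threshold
    concordant = state_p == state_m
    report.n_hemi_methylated = int((~concordant).sum())

    kept = sub[concordant]
    level = (mp[concordant] + mm[concordant]) / (tp[concordant] + tm[concordant])
    records = pd.DataFrame({
        "chrom": kept.index.get_level_values("chrom"),
        "pos": kept.index.get_level_values("site").astype(np.int64),
        "level": level,
        "total_reads": (tp[concordant] + tm[concordant]).astype(np.int64),
    }).sort_values(["chrom", "pos"]).reset_index(drop=True)
    report.n_sites_kept = int(len(records))
    return records, report


def coverage_rate(profile: MethylomeProfile, genome: GenomeIndex) -> float:
    """Fraction of all genome CpG sites carrying a profiled state."""
    total = genome.n_cpg_sites()
    if total == 0:
        raise ValueError("genome contains no CpG sites")
    return profile.n_sites / total


def methylation_rate(profile: MethylomeProfile, threshold: float = 0.5) -> float:
    """Fraction of covered sites with level strictly above `threshold`."""
    if profile.n_sites == 0:
        raise ValueError("methylation rate undefined for an empty profile")
    return float((profile.records["level"] > threshold).mean())


def clean_calls(call_sets: list[pd.DataFrame], genome: GenomeIndex,
                sample_id: str, role: str = "source",
                min_reads: int = DEFAULT_MIN_READS,
                binarize_threshold: float = 0.5,
                depth_filter_scope: str = "per_strand",
                ) -> tuple[MethylomeProfile, CleaningReport]:
    """Full cleaning pipeline: merge replicates, depth-filter, merge strands.

    ``depth_filter_scope`` selects where the read-depth rule applies:
    ``per_strand`` (default) drops individual strand calls below
    ``min_reads``; ``pooled`` instead requires the strand-pooled site depth
    to reach ``min_reads`` after merging.
    """
    merged = merge_replicates(call_sets)
    n_input = len(merged)
    if depth_filter_scope == "per_strand":
        filtered = filter_low_depth(merged, min_reads)
    elif depth_filter_scope == "pooled":
        filtered = merged
    else:
        raise ValueError(f"unknown depth_filter_scope {depth_filter_scope!r}")
    records, report = merge_strands(filtered, genome, binarize_threshold)
    if depth_filter_scope == "pooled":
        before = len(records)
        records = records[records["total_reads"] >= min_reads].reset_index(drop=True)
        report.n_removed_low_depth = before - len(records)
        report.n_sites_kept = len(records)
    else:
        report.n_removed_low_depth = n_input - len(filtered)
    report.n_input_calls = n_input
    profile = MethylomeProfile(sample_id=sample_id, records=records, role=role)
    report.coverage_rate = coverage_rate(profile, genome)
    if profile.n_sites:
        report.methylation_rate = methylation_rate(profile, binarize_threshold)
    return profile, report
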