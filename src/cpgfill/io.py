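"""Reading and writing methylome data.

Conventions
-----------
* All in-memory coordinates are 1-based inclusive (the Bismark coverage
  convention).  bedGraph-style inputs (0-based half-open) are converted on
  read.
* A CpG *site* is addressed by the position of its forward-strand C; the
  reverse-strand cytosine at ``pos + 1`` belongs to the same site.
* Call sets are pandas DataFrames with columns
  ``chrom, pos, strand, meth_reads, total_reads``; a cleaned profile is a
  DataFrame with ``chrom, pos, level, total_reads`` wrapped in
  :class:`MethylomeProfile`.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "meth_reads", "total_reads"]
PROFILE_COLUMNS = ["chrom", "pos", "level", "total_reads"]

DIALECTS = ("bismark_cov", "bedgraph_counts")


class ParseError(ValueError):
    """A call file row that cannot be interpreted."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "pos": pd.Series(dtype=np.int64),
                         "strand": pd.Series(dtype=str),
                         "meth_reads": pd.Series(dtype=np.int64),
                         "total_reads": pd.Series(dtype=np.int64)})


def read_calls(path, dialect: str = "bismark_cov") -> pd.DataFrame:
    """Read per-cytosine methylation calls.

    ``bismark_cov`` rows are ``chrom, start, end, %meth, n_meth, n_unmeth``
    with 1-based positions and no strand column (strand is inferred from the
    genome later, see :func:`infer_strands`).  ``bedgraph_counts`` rows are
    ``chrom, start, end, n_meth, n_unmeth, strand`` with 0-based half-open
    coordinates.

    Raises :class:`ParseError` (naming the offending line) on malformed rows
    or impossible counts.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                if dialect == "bismark_cov":
                    chrom, start = parts[0], int(parts[1])
                    meth, unmeth = int(parts[4]), int(parts[5])
                    pos, strand = start, "."
                else:
                    chrom, start = parts[0], int(parts[1])
                    meth, unmeth = int(parts[3]), int(parts[4])
                    pos, strand = start + 1, parts[5]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position {pos} < 1")
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, pos, strand, meth, meth + unmeth))
    if not rows:
        logger.warning("no calls read from %s", path)
        return _empty_calls()
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.astype({"pos": np.int64, "meth_reads": np.int64,
                      "total_reads": np.int64})


def validate_calls(calls: pd.DataFrame) -> None:
    if (calls["meth_reads"] > calls["total_reads"]).any():
        bad = calls.index[calls["meth_reads"] > calls["total_reads"]][0]
        raise ParseError(f"call at index {bad}: meth_reads > total_reads")
    if (calls["pos"] < 1).any():
        raise ParseError("call with position < 1")


def merge_replicates(call_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum read counts across replicate call sets per (chrom, pos, strand)."""
    if not call_sets:
        raise ValueError("at least one call set required")
    allc = pd.concat(call_sets, ignore_index=True)
    if allc.empty:
        return _empty_calls()
    merged = (allc.groupby(["chrom", "pos", "strand"], as_index=False, sort=True)
              [["meth_reads", "total_reads"]].sum())
    return merged[CALL_COLUMNS].reset_index(drop=True)


class GenomeIndex:
    """Random access to a FASTA genome plus the catalogue of its CpG sites.

    Positions overlapping ambiguity codes (``N``) are never CpG sites, since
    no methylation call is meaningful there.
    """

    def __init__(self, fasta_path):
        self.path = Path(fasta_path)
        self._fasta = Fasta(str(fasta_path), sequence_always_upper=True)
        self._cpg_cache: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def chrom_len(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Bases for [start, end], 1-based inclusive, clipped to the chromosome."""
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} absent from {self.path}")
        start = max(start, 1)
        end = min(end, self.chrom_len(chrom))
        if end < start:
            return ""
        return str(self._fasta[chrom][start - 1:end])

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """1-based forward-strand C positions of every CG dinucleotide."""
        if chrom not in self._cpg_cache:
            if chrom not in self._fasta:
                raise KeyError(f"chromosome {chrom!r} absent from {self.path}")
            seq = str(self._fasta[chrom][:])
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            self._cpg_cache[chrom] = (hits + 1).astype(np.int64)
        return self._cpg_cache[chrom]

    def n_cpg_sites(self) -> int:
        return int(sum(len(self.cpg_positions(c)) for c in self.chroms))

    def is_cpg(self, chrom: str, pos: int) -> bool:
        p = self.cpg_positions(chrom)
        i = np.searchsorted(p, pos)
        return bool(i < len(p) and p[i] == pos)


def enumerate_cpg_sites(genome: GenomeIndex) -> dict[str, np.ndarray]:
    """All CpG sites per chromosome (ascending 1-based positions)."""
    return {c: genome.cpg_positions(c) for c in genome.chroms}


def infer_strands(calls: pd.DataFrame, genome: GenomeIndex) -> pd.DataFrame:
    """Assign strands from the genome: C at pos -> '+', G at pos -> '-'.

    Calls at positions that are neither C nor G are kept with strand '.'
    and are dropped (with accounting) by the strand-merging step.
    """
    out = calls.copy()
    strands = np.full(len(out), ".", dtype=object)
    for chrom, sub in out.groupby("chrom", sort=False):
        if chrom not in genome.chroms:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        seq = genome.sequence(chrom, 1, genome.chrom_len(chrom))
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = sub["pos"].to_numpy()
        valid = pos <= len(arr)
        base = np.where(valid, arr[np.minimum(pos, len(arr)) - 1], 0)
        s = np.full(len(sub), ".", dtype=object)
        s[base == ord("C")] = "+"
        s[base == ord("G")] = "-"
        strands[sub.index.to_numpy()] = s
    out["strand"] = strands
    return out


@dataclass
class MethylomeProfile:
    """Cleaned per-CpG-site methylation levels for one sample."""

    sample_id: str
    records: pd.DataFrame
    role: str = "source"

    def __post_init__(self):
        df = self.records
        missing = set(PROFILE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"profile records missing columns {sorted(missing)}")
        df = df[PROFILE_COLUMNS].sort_values(["chrom", "pos"]).reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in profile records")
        if len(df) and ((df["level"] < 0) | (df["level"] > 1)).any():
            raise ValueError("methylation level outside [0, 1]")
        self.records = df
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (sorted positions, levels); cached."""
        if self._by_chrom is None:
            self._by_chrom = {
                chrom: (sub["pos"].to_numpy(np.int64),
                        sub["level"].to_numpy(np.float64))
                for chrom, sub in self.records.groupby("chrom", sort=True)
            }
        return self._by_chrom

    def level_at(self, chrom: str, pos: int) -> float | None:
        if chrom not in self.by_chrom():
            return None
        p, lv = self.by_chrom()[chrom]
        i = np.searchsorted(p, pos)
        if i < len(p) and p[i] == pos:
            return float(lv[i])
        return None


def write_profile(profile: MethylomeProfile, path) -> None:
    """Sorted TSV ``chrom  pos  level  total_reads`` with a metadata header."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        fh.write(f"#sample_id={profile.sample_id}\trole={profile.role}\n")
        fh.write("chrom\tpos\tlevel\ttotal_reads\n")
        for row in profile.records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.level:.6f}\t{int(row.total_reads)}\n")


def read_profile(path) -> MethylomeProfile:
    path = Path(path)
    sample_id, role = path.stem, "source"
    with _open_text(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=", 1) for kv in first[1:].strip().split("\t"))
            sample_id = meta.get("sample_id", sample_id)
            role = meta.get("role", role)
            header_line = fh.readline()
        else:
            header_line = first
        names = header_line.strip().split("\t")
        try:
            df = pd.read_csv(fh, sep="\t", names=names)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=names)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                           zip(PROFILE_COLUMNS, [str, np.int64, float, np.int64])})
    return MethylomeProfile(sample_id=sample_id, records=df, role=role)


def write_fasta(sequences: dict[str, str], path, line_len: int = 70) -> None:
    """Write a FASTA file (used by the simulator and tests)."""
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_len):
                fh.write(seq[i:i + line_len] + "\n")
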