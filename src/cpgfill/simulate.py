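"""Synthetic multi-profile methylomes.

The generator produces data with the statistical structure the imputation
method assumes: methylation levels driven by a DNA sequence determinant (a
planted motif raising the methylation log-odds near its occurrences) plus a
spatially autocorrelated latent field (neighbor correlation), observed
through strand-resolved binomial read sampling at a controllable depth and
per-profile coverage.  Source profiles share one spatial field (plus an
independent component), emulating related dense tissues; target profiles
share only the sequence determinant and carry independent fields, the
structure transfer learning exploits.  A configurable fraction of sites is
forced into intermediate levels (0.2, 0.8), mimicking the widespread
intermediate methylation that motivates the KL objective.

Everything is driven by named seeds, so fixtures are regenerable and never
stored.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import GenomeIndex, MethylomeProfile, write_fasta, write_profile
from .preprocess import CleaningReport, clean_calls

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    # genome
    n_chroms: int = 3
    chrom_len: int = 70_000
    gc_content: float = 0.42
    seed: int = 0
    # sequence determinant
    motif: str = "TAGTTGGA"
    motif_density: float = 1.0 / 400.0   # expected planted motifs per bp
    motif_window: int = 50               # bp; "near motif" raises the logit
    effect_size: float = 4.0
    baseline_logit: float = 0.0          # source profiles: mostly methylated
    target_baseline_logit: float = -2.5  # targets: low methylation rate
    # spatial latent field
    spatial_corr_length: float = 2000.0  # bp
    field_sd: float = 1.5
    shared_field_weight: float = 0.7     # source profiles only
    intermediate_fraction: float = 0.3
    # observation model
    mean_depth: float = 10.0             # per strand
    hemi_error_rate: float = 0.0
    # profiles
    n_source: int = 3
    source_coverage: float = 0.3
    n_target: int = 2
    target_coverage: float = 0.02

    def __post_init__(self):
        for r in (self.gc_content, self.source_coverage, self.target_coverage,
                  self.hemi_error_rate, self.intermediate_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if "CG" in self.motif.upper():
            raise ValueError("motif must not itself contain a CpG")


def learnability_benchmark_config(seed: int = 0) -> SimConfig:
    """Conditions under which the prediction mechanism is learnable at desk
    scale: two moderately covered profiles with a strong sequence effect and
    long-range neighbor correlation."""
    return SimConfig(seed=seed, n_target=2, target_coverage=0.4,
                     target_baseline_logit=-1.5, field_sd=2.0,
                     spatial_corr_length=3000.0, mean_depth=20.0)


def transfer_benchmark_config(seed: int = 0) -> SimConfig:
    """Dense sources plus four very sparse hypomethylated targets — the
    regime where subnetwork transfer should help most."""
    return SimConfig(seed=seed, n_target=4)


def intermediate_benchmark_config(seed: int = 0) -> SimConfig:
    """Intermediate-methylation-rich targets at low read depth — the regime
    where the KL objective's use of continuous labels should pay off."""
    return SimConfig(seed=seed, n_target=4, target_coverage=0.05,
                     target_baseline_logit=0.0, intermediate_fraction=0.35,
                     mean_depth=6.0)


def simulate_genome(config: SimConfig
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome at the stated GC content with planted motif instances.

    Returns (sequences, manifest) where the manifest records every planted
    motif start position (1-based).
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    motif = np.frombuffer(config.motif.upper().encode(), dtype=np.uint8)
    seqs: dict[str, str] = {}
    rows = []
    for c in range(1, config.n_chroms + 1):
        chrom = f"chr{c}"
        arr = BASES[rng.choice(4, size=config.chrom_len, p=probs)].copy()
        n_motifs = rng.poisson(config.motif_density * config.chrom_len)
        if len(motif) < config.chrom_len:
            starts = np.sort(rng.integers(
                0, config.chrom_len - len(motif), size=n_motifs))
            for s in starts:
                arr[s:s + len(motif)] = motif
                rows.append((chrom, int(s) + 1))
        seqs[chrom] = arr.tobytes().decode("ascii")
    manifest = pd.DataFrame(rows, columns=["chrom", "pos"])
    return seqs, manifest


def _ou_field(positions: np.ndarray, corr_length: float, sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck (exponential-kernel) field sampled at positions."""
    n = len(positions)
    f = np.zeros(n)
    if n == 0:
        return f
    f[0] = rng.normal(0.0, sd)
    gaps = np.diff(positions).astype(float)
    rho = np.exp(-gaps / corr_length)
    eps = rng.normal(0.0, sd, size=n - 1)
    for k in range(1, n):
        f[k] = rho[k - 1] * f[k - 1] + np.sqrt(1 - rho[k - 1] ** 2) * eps[k - 1]
    return f


def simulate_true_methylome(genome: GenomeIndex, manifest: pd.DataFrame,
                            config: SimConfig, profile_seed: int,
                            shared_fields: dict[str, np.ndarray] | None = None,
                            baseline_logit: float | None = None,
                            ) -> dict[str, np.ndarray]:
    """True per-CpG levels for one profile: chrom -> levels array.

    level = sigmoid(baseline + effect * near_motif + field); if
    ``shared_fields`` is given (source profiles) the field mixes the shared
    component with an independent one at ``shared_field_weight``.  A
    ``intermediate_fraction`` of sites is then squeezed into (0.2, 0.8) by
    the affine map 0.2 + 0.6 * level, preserving the determinants' signal.
    """
    rng = np.random.default_rng(profile_seed)
    w = config.shared_field_weight
    base = config.baseline_logit if baseline_logit is None else baseline_logit
    out = {}
    for chrom in genome.chroms:
        sites = genome.cpg_positions(chrom)
        mpos = np.sort(manifest.loc[manifest["chrom"] == chrom, "pos"]
                       .to_numpy(np.int64))
        if len(mpos):
            i = np.searchsorted(mpos, sites)
            d_right = np.where(i < len(mpos), mpos[np.minimum(i, len(mpos) - 1)]
                               - sites, np.iinfo(np.int64).max)
            d_left = np.where(i > 0, sites - mpos[np.maximum(i - 1, 0)],
                              np.iinfo(np.int64).max)
            near = np.minimum(np.abs(d_left), np.abs(d_right)) <= config.motif_window
        else:
            near = np.zeros(len(sites), dtype=bool)
        own = _ou_field(sites, config.spatial_corr_length, config.field_sd, rng)
        if shared_fields is not None:
            fld = w * shared_fields[chrom] + np.sqrt(1 - w ** 2) * own
        else:
            fld = own
        level = expit(base + config.effect_size * near + fld)
        if config.intermediate_fraction > 0:
            pick = rng.random(len(sites)) < config.intermediate_fraction
            level = np.where(pick, 0.2 + 0.6 * level, level)
        out[chrom] = level
    return out


def simulate_observed_calls(true_levels: dict[str, np.ndarray],
                            genome: GenomeIndex, config: SimConfig,
                            profile_seed: int,
                            coverage_rate: float) -> pd.DataFrame:
    """Strand-resolved binomial read sampling of a true methylome.

    Each CpG site is covered independently with probability
    ``coverage_rate``; each strand of a covered site receives a shifted-
    Poisson depth (>= 1, mean ``mean_depth``) and a binomial methylated-read
    count.  With probability ``hemi_error_rate`` one strand samples from the
    complementary level, planting a hemi-methylated artifact.
    """
    rng = np.random.default_rng(profile_seed + 1_000_003)
    rows = {"chrom": [], "pos": [], "strand": [], "meth_reads": [],
            "total_reads": []}
    for chrom in genome.chroms:
        sites = genome.cpg_positions(chrom)
        lv = true_levels[chrom]
        cov = rng.random(len(sites)) < coverage_rate
        idx = np.flatnonzero(cov)
        if len(idx) == 0:
            continue
        p_plus = lv[idx].copy()
        p_minus = lv[idx].copy()
        hemi = rng.random(len(idx)) < config.hemi_error_rate
        which = rng.random(len(idx)) < 0.5
        p_plus[hemi & which] = 1.0 - p_plus[hemi & which]
        p_minus[hemi & ~which] = 1.0 - p_minus[hemi & ~which]
        for strand, offset, p in (("+", 0, p_plus), ("-", 1, p_minus)):
            depth = 1 + rng.poisson(max(config.mean_depth - 1.0, 0.0),
                                    size=len(idx))
            meth = rng.binomial(depth, p)
            rows["chrom"].extend([chrom] * len(idx))
            rows["pos"].extend((sites[idx] + offset).tolist())
            rows["strand"].extend([strand] * len(idx))
            rows["meth_reads"].extend(meth.tolist())
            rows["total_reads"].extend(depth.tolist())
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "pos": pd.Series(dtype=np.int64),
                           "strand": pd.Series(dtype=str),
                           "meth_reads": pd.Series(dtype=np.int64),
                           "total_reads": pd.Series(dtype=np.int64)})
    else:
        df = df.astype({"pos": np.int64, "meth_reads": np.int64,
                        "total_reads": np.int64})
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _truth_profile(sample_id: str, levels: dict[str, np.ndarray],
                   genome: GenomeIndex) -> MethylomeProfile:
    parts = [pd.DataFrame({"chrom": chrom, "pos": genome.cpg_positions(chrom),
                           "level": levels[chrom], "total_reads": 0})
             for chrom in genome.chroms]
    return MethylomeProfile(sample_id=f"{sample_id}_truth",
                            records=pd.concat(parts, ignore_index=True),
                            role="target")


@dataclass
class Benchmark:
    """A packaged synthetic source->target scenario."""

    genome: GenomeIndex
    manifest: pd.DataFrame
    source_profiles: list[MethylomeProfile]
    target_profiles: list[MethylomeProfile]
    truth: dict[str, MethylomeProfile]       # sample_id -> true levels
    reports: dict[str, CleaningReport]
    config: SimConfig
    directory: Path


def make_benchmark(config: SimConfig, out_dir=None,
                   write_files: bool = True) -> Benchmark:
    """Simulate genome + profiles, run the cleaning pipeline, keep the truth.

    Profiles are named src1.. and tgt1..; the held-out truth at every CpG
    site (including masked/unobserved ones) enables scoring imputation.
    """
    out_dir = Path(tempfile.mkdtemp(prefix="cpgfill_bench_")
                   if out_dir is None else out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, manifest = simulate_genome(config)
    fasta = out_dir / "genome.fa"
    write_fasta(seqs, fasta)
    genome = GenomeIndex(fasta)

    shared = {chrom: _ou_field(genome.cpg_positions(chrom),
                               config.spatial_corr_length, config.field_sd,
                               np.random.default_rng(config.seed + 77))
              for chrom in genome.chroms}

    source, target, truth, reports = [], [], {}, {}
    roster = ([("src", j, config.source_coverage, shared, "source")
             for j in range(1, config.n_source + 1)]
            + [("tgt", j, config.target_coverage, None, "target")
               for j in range(1, config.n_target + 1)])
    for prefix, j, cov, shared_fields, role in roster:
        sample = f"{prefix}{j}"
        pseed = config.seed * 10_007 + (j if prefix == "src" else 5000 + j)
        base = (config.baseline_logit if role == "source"
                else config.target_baseline_logit)
        levels = simulate_true_methylome(genome, manifest, config, pseed,
                                         shared_fields, baseline_logit=base)
        calls = simulate_observed_calls(levels, genome, config, pseed, cov)
        profile, report = clean_calls([calls], genome, sample_id=sample,
                                      role=role)
        (source if role == "source" else target).append(profile)
        truth[sample] = _truth_profile(sample, levels, genome)
        reports[sample] = report
        if write_files:
            _write_cov(calls, out_dir / f"{sample}.cov")
            write_profile(profile, out_dir / f"{sample}.tsv")
            write_profile(truth[sample], out_dir / f"{sample}.truth.tsv")
    if write_files:
        manifest.to_csv(out_dir / "motifs.tsv", sep="\t", index=False)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2)
    return Benchmark(genome=genome, manifest=manifest, source_profiles=source,
                     target_profiles=target, truth=truth, reports=reports,
                     config=config, directory=out_dir)


def _write_cov(calls: pd.DataFrame, path: Path) -> None:
    """Bismark-coverage dialect: chrom, start, end, %meth, n_meth, n_unmeth."""
    with open(path, "w") as fh:
        for r in calls.itertuples(index=False):
            pct = 100.0 * r.meth_reads / r.total_reads if r.total_reads else 0.0
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:.4f}\t"
                     f"{r.meth_reads}\t{r.total_reads - r.meth_reads}\n")
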