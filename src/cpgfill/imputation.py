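"""Completing a sparse profile with confidence-thresholded predictions.

Every genome CpG site absent from the target profile is scored by a
trained model; a prediction is retained only when its methylated-class
probability is confidently high (> tau) or low (< 1 - tau), with tau = 0.8
by default.  Observed sites pass through byte-identical and are never
re-predicted, and neighbor features are always drawn from the originally
observed sites (a single pass, no iterative refinement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import DIST_SCALE, build_examples
from .evaluation import retained
from .io import GenomeIndex, MethylomeProfile, _open_text
from .losses import binarize
from .network import MethylationNetwork
from .preprocess import coverage_rate

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.8


@dataclass
class ImputedProfile:
    """Union of observed records and tau-retained predictions.

    ``records`` columns: chrom, pos, level, origin ('observed'/'imputed'),
    confidence (predicted probability, NaN for observed rows), state
    (binarised level).
    """

    sample_id: str
    records: pd.DataFrame
    tau: float

    @property
    def n_observed(self) -> int:
        return int((self.records["origin"] == "observed").sum())

    @property
    def n_imputed(self) -> int:
        return int((self.records["origin"] == "imputed").sum())

    def sites_with_data(self) -> MethylomeProfile:
        """Observed plus retained-imputed sites as a plain profile."""
        df = self.records[["chrom", "pos", "level"]].copy()
        df["total_reads"] = 0
        return MethylomeProfile(sample_id=f"{self.sample_id}_imputed",
                                records=df, role="target")

    def write(self, path) -> None:
        path = Path(path)
        with _open_text(path, "wt") as fh:
            fh.write(f"#sample_id={self.sample_id}\ttau={self.tau}\n")
            fh.write("chrom\tpos\tlevel\torigin\tconfidence\tstate\n")
            for r in self.records.itertuples(index=False):
                conf = "" if np.isnan(r.confidence) else f"{r.confidence:.6f}"
                fh.write(f"{r.chrom}\t{r.pos}\t{r.level:.6f}\t{r.origin}\t"
                         f"{conf}\t{int(r.state)}\n")

    def write_bedgraph(self, path) -> None:
        with _open_text(Path(path), "wt") as fh:
            for r in self.records.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.level:.6f}\n")


def impute_profile(model: MethylationNetwork, profiles: list[MethylomeProfile],
                   target_id: str, genome: GenomeIndex,
                   tau: float = DEFAULT_TAU,
                   chroms: list[str] | None = None,
                   window_len: int | None = None,
                   k_per_side: int | None = None,
                   dist_scale: float = DIST_SCALE,
                   batch_size: int = 256) -> ImputedProfile:
    """Score every uncovered genome CpG for `target_id` and keep confident calls."""
    if not (0.5 <= tau < 1.0):
        raise ValueError("tau must lie in [0.5, 1)")
    if model.config.n_tasks != len(profiles):
        raise ValueError(f"model has {model.config.n_tasks} task heads but "
                         f"{len(profiles)} profiles were given")
    ids = sorted(p.sample_id for p in profiles)
    if target_id not in ids:
        raise KeyError(f"{target_id!r} not among profiles {ids}")
    target_index = ids.index(target_id)
    target = next(p for p in profiles if p.sample_id == target_id)
    wl = window_len if window_len is not None else model.config.window_len
    k = k_per_side if k_per_side is not None else model.config.k_per_side

    batch = build_examples(profiles, genome, site_selector="imputation",
                           chroms=chroms, window_len=wl, k_per_side=k,
                           dist_scale=dist_scale)
    yhat = model.predict(batch, batch_size=batch_size)[:, target_index]
    observed = batch.label_mask[:, target_index]
    keep = retained(yhat, tau) & ~observed

    imputed = pd.DataFrame({
        "chrom": batch.chrom[keep], "pos": batch.pos[keep],
        "level": yhat[keep], "origin": "imputed",
        "confidence": yhat[keep],
        "state": binarize(yhat[keep]).astype(int)})
    obs_records = target.records
    if chroms is not None:
        obs_records = obs_records[obs_records["chrom"].isin(chroms)]
    obs = pd.DataFrame({
        "chrom": obs_records["chrom"].to_numpy(),
        "pos": obs_records["pos"].to_numpy(),
        "level": obs_records["level"].to_numpy(), "origin": "observed",
        "confidence": np.nan,
        "state": binarize(obs_records["level"].to_numpy()).astype(int)})
    records = (pd.concat([obs, imputed], ignore_index=True)
               .sort_values(["chrom", "pos"]).reset_index(drop=True))
    out = ImputedProfile(sample_id=target_id, records=records, tau=tau)
    logger.info("%s: %d observed + %d imputed sites retained at tau=%.2f",
                target_id, out.n_observed, out.n_imputed, tau)
    return out


def coverage_gain(before: MethylomeProfile, after: ImputedProfile,
                  genome: GenomeIndex) -> dict[str, float]:
    """Genome-wide CpG coverage rate before and after imputation."""
    rate_before = coverage_rate(before, genome)
    rate_after = coverage_rate(after.sites_with_data(), genome)
    return {"rate_before": rate_before, "rate_after": rate_after}


def read_imputed(path) -> ImputedProfile:
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
        meta = dict(kv.split("=", 1) for kv in first[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t")
    if "confidence" in df.columns:
        df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    return ImputedProfile(sample_id=meta.get("sample_id", path.stem),
                          records=df, tau=float(meta.get("tau", DEFAULT_TAU)))
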