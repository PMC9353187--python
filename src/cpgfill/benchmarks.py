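"""Desk-scale training protocols on the synthetic benchmarks.

These functions wire together the simulator, the training engine and the
evaluation exactly as the reproduction script and the acceptance tests use
them: source pretraining follows the Seq -> Met -> Full3 pipeline, target
models are fitted under a named transfer setting with a small
learning-rate grid, and scoring is against the simulator's true methylome
on the held-out test chromosome.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

from .losses import LossConfig
from .model import ImputerResults, MethylomeImputer
from .network import NetworkConfig
from .simulate import Benchmark
from .training import TrainConfig

DESK_TARGET_GRID = (1e-2, 3e-3, 1e-3)
DESK_FINETUNE_GRID = (3e-3, 1e-3)


def pretrain_source_full3(bench: Benchmark, seed: int,
                          workdir=None) -> Path:
    """Train Seq and Met source models, then Full3 from them.

    Returns the Full3 checkpoint directory whose Sequence, Methylation and
    Joint groups are ready for transfer to target models.
    """
    workdir = Path(tempfile.mkdtemp(prefix="cpgfill_src_")
                   if workdir is None else workdir)
    cfg = NetworkConfig.desk(n_tasks=len(bench.source_profiles))
    src = MethylomeImputer(bench.source_profiles, bench.genome, cfg,
                           loss=LossConfig(kind="kl"))
    seq = src.fit("Seq", train_config=TrainConfig(
        learning_rate=1e-2, max_epochs=40, patience=8, seed=seed))
    met = src.fit("Met", train_config=TrainConfig(
        learning_rate=1e-2, max_epochs=15, patience=4, seed=seed))
    ck_seq, ck_met = workdir / "seq", workdir / "met"
    seq.save(ck_seq)
    met.save(ck_met)
    full3 = src.fit("Full3",
                    source_checkpoint={"sequence": ck_seq,
                                       "methylation": ck_met},
                    train_config=TrainConfig(learning_rate=3e-3,
                                             max_epochs=12, patience=4,
                                             seed=seed))
    ck = workdir / "full3"
    full3.save(ck)
    return ck


def fit_target(bench: Benchmark, setting: str, loss_kind: str = "kl",
               source_checkpoint=None, seed: int = 0,
               lr_grid: tuple[float, ...] | None = None,
               max_epochs: int = 25, patience: int = 6) -> ImputerResults:
    """Fit a target model under a transfer setting on a benchmark."""
    if lr_grid is None:
        lr_grid = (DESK_FINETUNE_GRID if setting.endswith("2")
                   and setting not in ("SeqT2", "MetT2") else DESK_TARGET_GRID)
    cfg = NetworkConfig.desk(n_tasks=len(bench.target_profiles))
    imputer = MethylomeImputer(bench.target_profiles, bench.genome, cfg,
                               loss=LossConfig(kind=loss_kind))
    return imputer.fit(setting, source_checkpoint=source_checkpoint,
                       train_config=TrainConfig(max_epochs=max_epochs,
                                                patience=patience, seed=seed),
                       lr_grid=lr_grid)


def truth_f1_on_test_chroms(res: ImputerResults, bench: Benchmark,
                        chroms=("chr2",)) -> float:
    """Mean minor-class F1 against simulated truth on test chromosomes."""
    rep = res.evaluate_against_truth(bench.truth, list(chroms))
    return rep.mean_f1_minor
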