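"""High-level modelling interface.

:class:`MethylomeImputer` bundles the encoding, network, training and
evaluation machinery behind a fit/results API: build the model from cleaned
profiles and a genome, call :meth:`~MethylomeImputer.fit` with a transfer
setting, and receive an :class:`ImputerResults` carrying the fitted
network, its training history, evaluation reports and an
:meth:`~ImputerResults.impute` method for completing a profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import EncodedBatch, build_examples
from .evaluation import EvalReport, evaluate
from .imputation import ImputedProfile, impute_profile
from .io import GenomeIndex, MethylomeProfile
from .losses import LossConfig
from .network import MethylationNetwork, NetworkConfig
from .training import (SplitPlan, TrainConfig, TrainHistory, grid_search_lr,
                       resolve_transfer, split_examples, train_model)


class MethylomeImputer:
    """A multi-task methylation prediction model over a set of profiles.

    Parameters
    ----------
    profiles
        Cleaned profiles; each becomes one prediction task (alphabetical
        ``sample_id`` order).
    genome
        The reference genome the profiles were called against.
    network_config
        Layer sizes; defaults to the full-scale configuration with
        ``n_tasks`` set to the number of profiles.  Use
        ``NetworkConfig.desk(...)`` for CPU-scale work.
    split_plan
        Chromosome-based train/validation/test routing; defaults to the
        standard plan (chr1,4,7,... train; chr3,6,... validation;
        chr2,5,... test) restricted to chromosomes present in the data.
    loss
        The training objective; defaults to KL divergence with
        inverse-class-frequency site weights.
    """

    def __init__(self, profiles: list[MethylomeProfile], genome: GenomeIndex,
                 network_config: NetworkConfig | None = None,
                 split_plan: SplitPlan | None = None,
                 loss: LossConfig | None = None):
        if not profiles:
            raise ValueError("at least one profile required")
        self.profiles = sorted(profiles, key=lambda p: p.sample_id)
        self.genome = genome
        if network_config is None:
            network_config = NetworkConfig(n_tasks=len(profiles))
        if network_config.n_tasks != len(profiles):
            raise ValueError(f"network_config.n_tasks={network_config.n_tasks} "
                             f"but {len(profiles)} profiles given")
        self.config = network_config
        self.split_plan = split_plan or SplitPlan.default()
        self.loss = loss or LossConfig()
        self._splits: dict[str, EncodedBatch] | None = None

    @property
    def task_order(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def splits(self) -> dict[str, EncodedBatch]:
        """Encoded training examples routed by the split plan (cached)."""
        if self._splits is None:
            batch = build_examples(self.profiles, self.genome, "training",
                                   window_len=self.config.window_len,
                                   k_per_side=self.config.k_per_side)
            self._splits = split_examples(batch, self.split_plan)
        return self._splits

    def fit(self, setting: str = "FullN", source_checkpoint=None,
            train_config: TrainConfig | None = None,
            lr_grid: tuple[float, ...] | None = None,
            seed: int = 0) -> "ImputerResults":
        """Train under a named transfer setting and return the results.

        If ``lr_grid`` is given, one model is trained per learning rate and
        the best validation minor-class F1 wins (ties to the smaller rate);
        otherwise the single configured learning rate is used.
        """
        plan = resolve_transfer(setting, source_checkpoint)
        cfg = train_config or TrainConfig(seed=seed)
        sp = self.splits()

        def factory() -> MethylationNetwork:
            return MethylationNetwork(self.config, plan.mode, seed=cfg.seed)

        if lr_grid is not None:
            net, history, table = grid_search_lr(
                factory, sp["train"], sp["val"], cfg, self.loss, plan, lr_grid)
        else:
            net = factory()
            history = train_model(net, sp["train"], sp["val"], cfg, self.loss,
                                  plan)
            table = [{"learning_rate": cfg.learning_rate,
                      "val_f1": history.best_val_f1,
                      "best_epoch": history.best_epoch}]
        return ImputerResults(model=self, network=net, setting=setting,
                              history=history, lr_table=table)


@dataclass
class ImputerResults:
    """A fitted model plus its training history and evaluation helpers."""

    model: MethylomeImputer
    network: MethylationNetwork
    setting: str
    history: TrainHistory
    lr_table: list[dict] = field(default_factory=list)

    def predict(self, batch: EncodedBatch) -> np.ndarray:
        return self.network.predict(batch)

    def evaluate(self, split: str = "test") -> EvalReport:
        """Metrics on the observed labels of a data split."""
        b = self.model.splits()[split]
        return evaluate(self.network.predict(b), b.labels, b.label_mask,
                        self.model.loss.binarize_threshold)

    def evaluate_against_truth(self, truth: dict[str, MethylomeProfile],
                               chroms: list[str]) -> EvalReport:
        """Metrics against known true levels at every CpG of `chroms`.

        Only meaningful on synthetic benchmarks, where the simulator's true
        methylome is available at held-out sites.
        """
        batch = build_examples(self.model.profiles, self.model.genome,
                               "imputation", chroms=chroms,
                               window_len=self.model.config.window_len,
                               k_per_side=self.model.config.k_per_side)
        labels = np.zeros((batch.n_examples, len(self.model.profiles)),
                          dtype=np.float64)
        for j, sid in enumerate(batch.task_order):
            prof = truth[sid]
            for chrom in np.unique(batch.chrom):
                sel = batch.chrom == chrom
                p, lv = prof.by_chrom()[str(chrom)]
                i = np.searchsorted(p, batch.pos[sel])
                labels[sel, j] = lv[i]
        return evaluate(self.network.predict(batch), labels,
                        np.ones_like(labels, dtype=bool),
                        self.model.loss.binarize_threshold)

    def impute(self, target_id: str, tau: float = 0.8,
               chroms: list[str] | None = None) -> ImputedProfile:
        return impute_profile(self.network, self.model.profiles, target_id,
                              self.model.genome, tau=tau, chroms=chroms,
                              k_per_side=self.model.config.k_per_side)

    def save(self, path) -> None:
        self.network.save_parameters(path, meta={
            "setting": self.setting, "task_order": self.model.task_order,
            "best_epoch": self.history.best_epoch,
            "best_val_f1": self.history.best_val_f1,
            "learning_rate": self.history.learning_rate})

    def summary(self) -> str:
        """A fixed-width text summary of the fit."""
        sp = self.model.splits()
        test = self.evaluate()
        lines = [
            "Methylome imputation model",
            "=" * 60,
            f"setting:            {self.setting} (mode={self.network.mode})",
            f"tasks:              {', '.join(self.model.task_order)}",
            f"loss:               {self.model.loss.kind}",
            f"examples:           train={sp['train'].n_examples} "
            f"val={sp['val'].n_examples} test={sp['test'].n_examples}",
            f"best epoch:         {self.history.best_epoch} "
            f"(val F1={self.history.best_val_f1:.4f}, "
            f"lr={self.history.learning_rate:g})",
            "-" * 60,
            f"{'task':<12}{'n_eval':>8}{'minor':>7}{'F1':>9}"
            f"{'prec':>9}{'recall':>9}",
        ]
        for sid, t in zip(self.model.task_order, test.per_task):
            lines.append(f"{sid:<12}{t.n_eval:>8}{t.minor_class:>7}"
                         f"{t.f1_minor:>9.4f}{t.precision:>9.4f}"
                         f"{t.recall:>9.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)
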