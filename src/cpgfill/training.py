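"""Chromosome-based splitting, the training engine, and transfer settings.

Transfer settings name which pretrained feature subnetworks a model loads
and whether each is frozen or fine-tuned.  Source-side settings build the
pretrained models on dense profiles (``Seq``, ``Met``, ``Full1``-``Full3``);
target-side settings (``SeqN`` .. ``FullTA2``) describe every combination
of transferring/freezing the Sequence, Methylation and Joint subnetworks
when training on sparse profiles.  Classification heads are never
transferred: the target task set is new.

Training uses Adam with L2 weight decay, an explicit L1 penalty, mini-
batches of 128 and early stopping on the validation minor-class F1 (best
parameters restored).  All randomness flows from the seed in
:class:`TrainConfig`, so a rerun with identical inputs is bit-identical.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .encoding import EncodedBatch
from .evaluation import evaluate
from .losses import (LossConfig, binarize, multi_task_weight_matrix,
                     per_site_loss, per_site_loss_grad)
from .network import MethylationNetwork
from .nn import Adam

logger = logging.getLogger(__name__)

# chromosome lists of the default split plan
TRAIN_CHROM_NUMBERS = (1, 4, 7, 10, 13, 16, 19, 22, 25, 28)
VAL_CHROM_NUMBERS = (3, 6, 9, 12, 15, 18, 21, 24, 27)
TEST_CHROM_NUMBERS = (2, 5, 8, 11, 14, 17, 20, 23, 26, 29)


@dataclass
class SplitPlan:
    train_chroms: tuple[str, ...]
    val_chroms: tuple[str, ...]
    test_chroms: tuple[str, ...]

    def __post_init__(self):
        sets = [set(self.train_chroms), set(self.val_chroms),
                set(self.test_chroms)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("split chromosome lists must be pairwise disjoint")

    @classmethod
    def default(cls, prefix: str = "chr") -> "SplitPlan":
        return cls(tuple(f"{prefix}{n}" for n in TRAIN_CHROM_NUMBERS),
                   tuple(f"{prefix}{n}" for n in VAL_CHROM_NUMBERS),
                   tuple(f"{prefix}{n}" for n in TEST_CHROM_NUMBERS))

    def assign(self, chrom: str) -> str:
        """Pure chromosome-name -> {train, val, test} routing."""
        if chrom in self.train_chroms:
            return "train"
        if chrom in self.val_chroms:
            return "val"
        if chrom in self.test_chroms:
            return "test"
        raise KeyError(f"chromosome {chrom!r} is in no split list")


def split_examples(batch: EncodedBatch, plan: SplitPlan
                   ) -> dict[str, EncodedBatch]:
    """Route examples by chromosome; raises if a data chromosome is unplanned."""
    roles = {"train": [], "val": [], "test": []}
    for chrom in np.unique(batch.chrom):
        roles[plan.assign(str(chrom))].append(chrom)
    out = {}
    for role, chroms in roles.items():
        idx = np.isin(batch.chrom, chroms) if chroms else np.zeros(
            batch.n_examples, dtype=bool)
        out[role] = batch.subset(idx)
    logger.info("split sizes: train=%d val=%d test=%d",
                out["train"].n_examples, out["val"].n_examples,
                out["test"].n_examples)
    return out


# ---------------------------------------------------------------------------
# transfer settings
# ---------------------------------------------------------------------------

_F = ("sequence", "methylation", "joint")

#: setting -> (mode, transferred groups, frozen groups)
SOURCE_SETTINGS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "Seq": ("seq", (), ()),
    "Met": ("met", (), ()),
    "Full1": ("full", (), ()),
    "Full2": ("full", ("sequence", "methylation"), ("sequence", "methylation")),
    "Full3": ("full", ("sequence", "methylation"), ()),
}

TARGET_SETTINGS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "SeqN": ("seq", (), ()),
    "SeqT1": ("seq", ("sequence",), ("sequence",)),
    "SeqT2": ("seq", ("sequence",), ()),
    "MetN": ("met", (), ()),
    "MetT1": ("met", ("methylation",), ("methylation",)),
    "MetT2": ("met", ("methylation",), ()),
    "FullN": ("full", (), ()),
    "FullTS1": ("full", ("sequence",), ("sequence",)),
    "FullTS2": ("full", ("sequence",), ()),
    "FullTM1": ("full", ("methylation",), ("methylation",)),
    "FullTM2": ("full", ("methylation",), ()),
    "FullTB1": ("full", ("sequence", "methylation"),
                ("sequence", "methylation")),
    "FullTB2": ("full", ("sequence", "methylation"), ()),
    "FullTA1": ("full", _F, _F),
    "FullTA2": ("full", _F, ()),
}

ALL_SETTINGS = {**SOURCE_SETTINGS, **TARGET_SETTINGS}


@dataclass
class TransferPlan:
    setting: str
    mode: str
    transferred_groups: frozenset[str]
    frozen_groups: frozenset[str]
    source_checkpoint: object = None  # path, or {group: path} mapping

    def __post_init__(self):
        if not self.frozen_groups <= self.transferred_groups:
            raise ValueError("frozen groups must be a subset of transferred")


def resolve_transfer(setting: str, source_checkpoint=None) -> TransferPlan:
    """The (mode, transferred, frozen) triple for a named setting."""
    if setting not in ALL_SETTINGS:
        raise KeyError(f"unknown setting {setting!r}; "
                       f"known: {sorted(ALL_SETTINGS)}")
    mode, transferred, frozen = ALL_SETTINGS[setting]
    if transferred and source_checkpoint is None:
        raise ValueError(f"setting {setting!r} transfers {transferred} and "
                         "needs a source checkpoint")
    return TransferPlan(setting=setting, mode=mode,
                        transferred_groups=frozenset(transferred),
                        frozen_groups=frozenset(frozen),
                        source_checkpoint=source_checkpoint)


def apply_transfer(model: MethylationNetwork, plan: TransferPlan) -> None:
    """Load transferred groups into `model` and mark the frozen set."""
    if plan.mode != model.mode:
        raise ValueError(f"setting {plan.setting} expects mode {plan.mode!r}, "
                         f"model is {model.mode!r}")
    if plan.transferred_groups:
        ckpt = plan.source_checkpoint
        if isinstance(ckpt, dict):
            for g in sorted(plan.transferred_groups):
                if g not in ckpt:
                    raise ValueError(f"no checkpoint given for group {g!r}")
                model.load_parameters(ckpt[g], groups=[g])
        else:
            model.load_parameters(ckpt, groups=sorted(plan.transferred_groups))
    model.frozen = frozenset(plan.frozen_groups)


# ---------------------------------------------------------------------------
# training engine
# ---------------------------------------------------------------------------

LR_GRID = (0.1, 0.01, 0.001, 0.0001, 0.00001, 0.000001)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_grid: tuple[float, ...] = LR_GRID
    batch_size: int = 128
    l1_coeff: float = 1e-4
    l2_coeff: float = 1e-4
    patience: int = 5
    max_epochs: int = 50
    seed: int = 0
    shuffle: bool = True


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = float("-inf")
    learning_rate: float = float("nan")

    def append(self, **kw):
        self.epochs.append(kw)


def _profile_class_weights(labels: np.ndarray, mask: np.ndarray,
                           loss_cfg: LossConfig) -> np.ndarray:
    """(2, m) weights per binarised class and task over the training set."""
    m = labels.shape[1]
    w = np.ones((2, m))
    if loss_cfg.sample_weight_scheme == "uniform":
        return w
    yb = binarize(labels, loss_cfg.binarize_threshold)
    for j in range(m):
        mj = mask[:, j]
        nj = int(mj.sum())
        if nj == 0:
            continue
        n1 = int(yb[mj, j].sum())
        n0 = nj - n1
        if n0 and n1:
            w[0, j] = nj / (2.0 * n0)
            w[1, j] = nj / (2.0 * n1)
    return w


def _snapshot(model: MethylationNetwork) -> dict:
    return {g: copy.deepcopy(model._group(g).state_dict())
            for g in model.group_names()}


def _restore(model: MethylationNetwork, snap: dict) -> None:
    for g, state in snap.items():
        model._group(g).load_state_dict(state)


def train_model(model: MethylationNetwork, train_batch: EncodedBatch,
                val_batch: EncodedBatch, train_cfg: TrainConfig,
                loss_cfg: LossConfig,
                transfer_plan: TransferPlan | None = None) -> TrainHistory:
    """Optimise `model` in place; returns the per-epoch history.

    Early stopping monitors the mean validation minor-class F1 and restores
    the best-validation parameters.  Frozen groups (from the transfer plan)
    receive no optimisation step and keep their batch-norm statistics.
    """
    if train_batch.n_examples == 0:
        raise ValueError("empty training stream")
    if transfer_plan is not None:
        apply_transfer(model, transfer_plan)
    frozen = model.frozen
    trainable_groups = [g for g in model.group_names() if g not in frozen]
    params = model.parameters(trainable_groups)
    frozen_before = {g: model._group(g).state_dict() for g in frozen}

    opt = Adam(params, lr=train_cfg.learning_rate,
               weight_decay=train_cfg.l2_coeff)
    rng = np.random.default_rng(train_cfg.seed)
    cw = _profile_class_weights(train_batch.labels, train_batch.label_mask,
                                loss_cfg)
    history = TrainHistory(learning_rate=train_cfg.learning_rate)
    best_snap = _snapshot(model)
    bad_evals = 0
    n = train_batch.n_examples

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        epoch_loss, epoch_obs = 0.0, 0
        for a in range(0, n, train_cfg.batch_size):
            idx = order[a:a + train_cfg.batch_size]
            seq = train_batch.seq[idx].astype(np.float64)
            nbr = train_batch.neighbors[idx].astype(np.float64)
            y = train_batch.labels[idx].astype(np.float64)
            mask = train_batch.label_mask[idx]
            if not mask.any():
                continue
            yhat = model.forward(seq, nbr, training=True)
            L = per_site_loss(loss_cfg.kind, y, yhat.data, loss_cfg.epsilon,
                              loss_cfg.binarize_threshold)
            yb = binarize(y, loss_cfg.binarize_threshold).astype(int)
            beta = np.take_along_axis(cw, yb, axis=0) if cw.shape[0] == 2 else None
            W = multi_task_weight_matrix(L.shape, mask, loss_cfg, weights=beta)
            loss_val = float((W * np.where(mask, L, 0.0)).sum())
            dL = per_site_loss_grad(loss_cfg.kind, y, yhat.data,
                                    loss_cfg.epsilon,
                                    loss_cfg.binarize_threshold)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: loss={loss_val}, "
                    f"yhat range [{yhat.data.min()}, {yhat.data.max()}]")
            opt.zero_grad()
            yhat.backward(seed=W * np.where(mask, dL, 0.0))
            if train_cfg.l1_coeff:
                for p in params:
                    g = train_cfg.l1_coeff * np.sign(p.data)
                    p.grad = g if p.grad is None else p.grad + g
                loss_val += train_cfg.l1_coeff * sum(
                    float(np.abs(p.data).sum()) for p in params)
            opt.step()
            epoch_loss += loss_val * mask.sum()
            epoch_obs += int(mask.sum())

        train_loss = epoch_loss / max(epoch_obs, 1)
        val_loss, val_f1 = _validate(model, val_batch, loss_cfg)
        history.append(epoch=epoch, train_loss=train_loss, val_loss=val_loss,
                       val_f1=val_f1)
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f val_f1=%.4f",
                    epoch, train_loss, val_loss, val_f1)
        if val_f1 > history.best_val_f1:
            history.best_val_f1 = val_f1
            history.best_epoch = epoch
            best_snap = _snapshot(model)
            bad_evals = 0
        else:
            bad_evals += 1
            if bad_evals > train_cfg.patience:
                break

    _restore(model, best_snap)
    for g in frozen:
        after = model._group(g).state_dict()
        for k, v in frozen_before[g].items():
            assert np.array_equal(after[k], v), \
                f"frozen group {g!r} drifted at {k!r}"
    return history


def _validate(model: MethylationNetwork, val_batch: EncodedBatch,
              loss_cfg: LossConfig) -> tuple[float, float]:
    if val_batch.n_examples == 0 or not val_batch.label_mask.any():
        return float("nan"), float("-inf")
    yhat = model.predict(val_batch)
    L = per_site_loss(loss_cfg.kind, val_batch.labels.astype(np.float64),
                      yhat, loss_cfg.epsilon, loss_cfg.binarize_threshold)
    mask = val_batch.label_mask
    val_loss = float(np.where(mask, L, 0.0).sum() / mask.sum())
    rep = evaluate(yhat, val_batch.labels, mask, loss_cfg.binarize_threshold)
    return val_loss, rep.mean_f1_minor


def grid_search_lr(model_factory, train_batch: EncodedBatch,
                   val_batch: EncodedBatch, train_cfg: TrainConfig,
                   loss_cfg: LossConfig,
                   transfer_plan: TransferPlan | None = None,
                   lr_grid: tuple[float, ...] | None = None):
    """One full training per learning rate; select by validation minor-F1.

    ``model_factory()`` must return a freshly initialised model.  Ties are
    broken toward the smaller learning rate.  Returns
    ``(best_model, best_history, table)`` where table has one row per lr.
    """
    grid = tuple(lr_grid if lr_grid is not None else train_cfg.lr_grid)
    if not grid:
        raise ValueError("empty learning-rate grid")
    table = []
    best = None
    for lr in grid:
        cfg = dataclasses.replace(train_cfg, learning_rate=lr)
        model = model_factory()
        hist = train_model(model, train_batch, val_batch, cfg, loss_cfg,
                           transfer_plan)
        table.append({"learning_rate": lr, "val_f1": hist.best_val_f1,
                      "best_epoch": hist.best_epoch})
        if (best is None or hist.best_val_f1 > best[1].best_val_f1
                or (hist.best_val_f1 == best[1].best_val_f1 and lr < best[1].learning_rate)):
            best = (model, hist)
    return best[0], best[1], table
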