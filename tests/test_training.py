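"""Split plans, the transfer-setting table, and training-engine mechanics."""

import numpy as np
import pytest

from cpgfill.encoding import EncodedBatch
from cpgfill.losses import LossConfig
from cpgfill.network import ConvBlockConfig, MethylationNetwork, NetworkConfig
from cpgfill.training import (ALL_SETTINGS, SOURCE_SETTINGS, SplitPlan,
                              TARGET_SETTINGS, TrainConfig, TransferPlan,
                              grid_search_lr, resolve_transfer, split_examples,
                              train_model)

TINY = dict(conv_block_1=ConvBlockConfig(3, 5, 2),
            conv_block_2=ConvBlockConfig(4, 3, 2),
            seq_fc_units=6, gru_hidden_units=4, joint_fc_units=(6, 5),
            head_fc_units=4, window_len=21, k_per_side=2)


def tiny_config(n_tasks=2):
    return NetworkConfig(n_tasks=n_tasks, **TINY)


def synthetic_batch(n=60, m=2, seed=0, chrom="chr1"):
    """A learnable toy batch: label depends on one sequence channel."""
    rng = np.random.default_rng(seed)
    seq = np.zeros((n, 21, 4), dtype=np.float32)
    base = rng.integers(0, 4, size=(n, 21))
    for c in range(4):
        seq[..., c] = base == c
    signal = seq[:, 8:13, 1].sum(axis=1) > 1  # C-richness around centre
    nbr = rng.random((n, m, 8)).astype(np.float32)
    labels = np.tile((0.9 * signal + 0.05)[:, None], (1, m)).astype(np.float32)
    return EncodedBatch(chrom=np.array([chrom] * n),
                        pos=np.arange(1, n + 1, dtype=np.int64),
                        seq=seq, neighbors=nbr,
                        neighbor_mask=np.ones((n, m, 4), bool),
                        labels=labels, label_mask=np.ones((n, m), bool),
                        task_order=[f"t{j}" for j in range(m)])


class TestSplitPlan:
    def test_default_chromosome_routing(self):
        plan = SplitPlan.default()
        assert plan.assign("chr4") == "train"
        assert plan.assign("chr2") == "test"
        assert plan.assign("chr3") == "val"

    def test_unplanned_chromosome_raises(self):
        with pytest.raises(KeyError):
            SplitPlan.default().assign("chrM")

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(("chr1",), ("chr1",), ("chr2",))

    def test_split_examples_routes_and_handles_empty(self):
        b = synthetic_batch(10, chrom="chr1")
        out = split_examples(b, SplitPlan.default())
        assert out["train"].n_examples == 10
        assert out["val"].n_examples == 0 and out["test"].n_examples == 0


# the (mode, transferred, frozen) triples, written out independently from
# the implementation table
EXPECTED = {
    "Seq": ("seq", set(), set()),
    "Met": ("met", set(), set()),
    "Full1": ("full", set(), set()),
    "Full2": ("full", {"sequence", "methylation"}, {"sequence", "methylation"}),
    "Full3": ("full", {"sequence", "methylation"}, set()),
    "SeqN": ("seq", set(), set()),
    "SeqT1": ("seq", {"sequence"}, {"sequence"}),
    "SeqT2": ("seq", {"sequence"}, set()),
    "MetN": ("met", set(), set()),
    "MetT1": ("met", {"methylation"}, {"methylation"}),
    "MetT2": ("met", {"methylation"}, set()),
    "FullN": ("full", set(), set()),
    "FullTS1": ("full", {"sequence"}, {"sequence"}),
    "FullTS2": ("full", {"sequence"}, set()),
    "FullTM1": ("full", {"methylation"}, {"methylation"}),
    "FullTM2": ("full", {"methylation"}, set()),
    "FullTB1": ("full", {"sequence", "methylation"},
                {"sequence", "methylation"}),
    "FullTB2": ("full", {"sequence", "methylation"}, set()),
    "FullTA1": ("full", {"sequence", "methylation", "joint"},
                {"sequence", "methylation", "joint"}),
    "FullTA2": ("full", {"sequence", "methylation", "joint"}, set()),
}


class TestTransferTable:
    def test_all_twenty_settings_known(self):
        assert set(ALL_SETTINGS) == set(EXPECTED)
        assert len(SOURCE_SETTINGS) == 5 and len(TARGET_SETTINGS) == 15

    @pytest.mark.parametrize("setting", sorted(EXPECTED))
    def test_resolved_triple(self, setting):
        mode, transferred, frozen = EXPECTED[setting]
        plan = resolve_transfer(setting,
                                source_checkpoint="ckpt" if transferred else None)
        assert plan.mode == mode
        assert set(plan.transferred_groups) == transferred
        assert set(plan.frozen_groups) == frozen

    def test_transfer_setting_requires_checkpoint(self):
        with pytest.raises(ValueError, match="checkpoint"):
            resolve_transfer("FullTA2")

    def test_unknown_setting_rejected(self):
        with pytest.raises(KeyError):
            resolve_transfer("FullTX9")

    def test_frozen_must_be_transferred(self):
        with pytest.raises(ValueError):
            TransferPlan("x", "full", frozenset(), frozenset({"sequence"}))


def quick_cfg(seed=0, **kw):
    defaults = dict(learning_rate=3e-3, batch_size=16, max_epochs=3,
                    patience=5, l1_coeff=1e-5, l2_coeff=1e-5, seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainModel:
    def test_same_seed_identical_history(self):
        train, val = synthetic_batch(48, seed=1), synthetic_batch(24, seed=2)
        runs = []
        for _ in range(2):
            net = MethylationNetwork(tiny_config(), "full", seed=7)
            h = train_model(net, train, val, quick_cfg(), LossConfig())
            runs.append((h.epochs, net.predict(val)))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_frozen_group_bit_identical_after_training(self, tmp_path):
        donor = MethylationNetwork(tiny_config(), "full", seed=1)
        donor.save_parameters(tmp_path / "src")
        net = MethylationNetwork(tiny_config(), "full", seed=9)
        plan = resolve_transfer("FullTB1", tmp_path / "src")
        train, val = synthetic_batch(48, seed=1), synthetic_batch(24, seed=2)
        train_model(net, train, val, quick_cfg(max_epochs=2), LossConfig(),
                    transfer_plan=plan)
        for group in ("sequence", "methylation"):
            got = net.subnets[group].state_dict()
            want = donor.subnets[group].state_dict()
            for k in want:
                np.testing.assert_array_equal(got[k], want[k])
        # joint was trained from scratch and must have moved
        before = MethylationNetwork(tiny_config(), "full", seed=9)
        moved = any(
            not np.array_equal(net.subnets["joint"].state_dict()[k],
                               before.subnets["joint"].state_dict()[k])
            for k in net.subnets["joint"].state_dict())
        assert moved

    def test_patience_zero_stops_at_first_plateau(self):
        train, val = synthetic_batch(48, seed=1), synthetic_batch(24, seed=2)
        net = MethylationNetwork(tiny_config(), "full", seed=7)
        h = train_model(net, train, val, quick_cfg(patience=0, max_epochs=50),
                        LossConfig())
        # stopped as soon as validation F1 failed to improve once
        assert len(h.epochs) <= h.best_epoch + 2

    def test_all_frozen_head_fit_reduces_loss(self, tmp_path):
        donor = MethylationNetwork(tiny_config(), "full", seed=1)
        donor.save_parameters(tmp_path / "src")
        net = MethylationNetwork(tiny_config(), "full", seed=3)
        plan = resolve_transfer("FullTA1", tmp_path / "src")
        train, val = synthetic_batch(64, seed=4), synthetic_batch(32, seed=5)
        h = train_model(net, train, val,
                        quick_cfg(max_epochs=10, shuffle=False, l1_coeff=0.0),
                        LossConfig(), transfer_plan=plan)
        losses = [e["train_loss"] for e in h.epochs]
        assert losses[-1] < losses[0]

    def test_empty_training_stream_rejected(self):
        net = MethylationNetwork(tiny_config(), "full", seed=7)
        empty = synthetic_batch(0)
        with pytest.raises(ValueError):
            train_model(net, empty, empty, quick_cfg(), LossConfig())


class TestGridSearch:
    def test_one_row_per_lr_and_best_selection(self):
        train, val = synthetic_batch(48, seed=1), synthetic_batch(24, seed=2)

        def factory():
            return MethylationNetwork(tiny_config(), "full", seed=7)

        model, hist, table = grid_search_lr(
            factory, train, val, quick_cfg(max_epochs=2), LossConfig(),
            lr_grid=(1e-2, 1e-3))
        assert len(table) == 2
        assert hist.best_val_f1 == max(r["val_f1"] for r in table)

    def test_single_lr_equals_train_model(self):
        train, val = synthetic_batch(48, seed=1), synthetic_batch(24, seed=2)
        net = MethylationNetwork(tiny_config(), "full", seed=7)
        h = train_model(net, train, val, quick_cfg(max_epochs=2), LossConfig())

        def factory():
            return MethylationNetwork(tiny_config(), "full", seed=7)

        model, hist, table = grid_search_lr(
            factory, train, val, quick_cfg(max_epochs=2), LossConfig(),
            lr_grid=(3e-3,))
        assert hist.epochs == h.epochs
        np.testing.assert_array_equal(model.predict(val), net.predict(val))
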