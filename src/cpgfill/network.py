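"""The multi-task prediction network.

Three feature-extraction subnetworks feed task-specific classification
heads:

* **Sequence** — two convolution blocks (convolution, ReLU, max pooling,
  batch normalisation) over the one-hot DNA window, then a fully connected
  layer with ReLU;
* **Methylation** — a bidirectional GRU consuming one neighbor vector per
  profile (the profile axis is the recurrence axis); its output is the
  concatenation of the two final hidden states;
* **Joint** — two fully connected layers (ReLU, then batch normalisation)
  over the concatenated Sequence and Methylation features.

A model in mode ``seq``/``met``/``full`` routes the corresponding feature
vector into one head per task.  Each head is a hidden fully connected layer
with ReLU followed by a two-logit softmax; the reported probability is that
of the methylated class.  All tasks share the feature subnetworks; heads
are task specific and are never transferred between task sets.

Layer sizes default to the DeepCpG-family scale and every size is
configurable; the ``desk`` preset is a small configuration suitable for
CPU-scale experiments and tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import BatchNorm, BiGRU, Conv1d, Dense, Layer, MaxPool1d, Tensor, concat

MODES = ("seq", "met", "full")
FEATURE_GROUPS = ("sequence", "methylation", "joint")


@dataclass
class ConvBlockConfig:
    n_filters: int
    filter_len: int
    pool_len: int


@dataclass
class NetworkConfig:
    conv_block_1: ConvBlockConfig = field(
        default_factory=lambda: ConvBlockConfig(128, 11, 4))
    conv_block_2: ConvBlockConfig = field(
        default_factory=lambda: ConvBlockConfig(256, 3, 2))
    seq_fc_units: int = 256
    gru_hidden_units: int = 256
    joint_fc_units: tuple[int, int] = (512, 256)
    head_fc_units: int = 128
    n_tasks: int = 1
    use_batch_norm: bool = True
    window_len: int = 1001
    k_per_side: int = 25

    def __post_init__(self):
        if isinstance(self.conv_block_1, dict):
            self.conv_block_1 = ConvBlockConfig(**self.conv_block_1)
        if isinstance(self.conv_block_2, dict):
            self.conv_block_2 = ConvBlockConfig(**self.conv_block_2)
        self.joint_fc_units = tuple(self.joint_fc_units)
        if len(self.joint_fc_units) != 2:
            raise ValueError("joint_fc_units must have exactly two entries")
        sizes = [self.conv_block_1.n_filters, self.conv_block_1.filter_len,
                 self.conv_block_1.pool_len, self.conv_block_2.n_filters,
                 self.conv_block_2.filter_len, self.conv_block_2.pool_len,
                 self.seq_fc_units, self.gru_hidden_units,
                 *self.joint_fc_units, self.head_fc_units, self.n_tasks]
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")

    @property
    def neighbor_dim(self) -> int:
        return 4 * self.k_per_side

    @classmethod
    def desk(cls, n_tasks: int = 1, window_len: int = 121,
             k_per_side: int = 25) -> "NetworkConfig":
        """Small CPU-scale configuration."""
        return cls(conv_block_1=ConvBlockConfig(32, 9, 4),
                   conv_block_2=ConvBlockConfig(32, 3, 2),
                   seq_fc_units=64, gru_hidden_units=32,
                   joint_fc_units=(64, 32), head_fc_units=32,
                   n_tasks=n_tasks, window_len=window_len,
                   k_per_side=k_per_side)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["joint_fc_units"] = tuple(d["joint_fc_units"])
        return cls(**d)


class Subnetwork:
    """An ordered set of named layers with grouped (de)serialisation."""

    def __init__(self):
        self.layers: dict[str, Layer] = {}

    def parameters(self) -> list[Tensor]:
        out = []
        for layer in self.layers.values():
            out.extend(layer.parameters())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self.layers.items():
            for k, v in layer.state_dict().items():
                out[f"{lname}/{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        by_layer: dict[str, dict] = {}
        for k, v in state.items():
            lname, pname = k.split("/", 1)
            by_layer.setdefault(lname, {})[pname] = v
        for lname, sub in by_layer.items():
            if lname not in self.layers:
                raise ValueError(f"unknown layer {lname!r} in checkpoint")
            self.layers[lname].load_state_dict(sub)


class SequenceSubnetwork(Subnetwork):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2 = config.conv_block_1, config.conv_block_2
        w = config.window_len
        l1 = w - c1.filter_len + 1
        if l1 < 1:
            raise ValueError("window shorter than first receptive field")
        l1p = l1 // c1.pool_len
        l2 = l1p - c2.filter_len + 1
        if l2 < 1:
            raise ValueError("pooled length shorter than second receptive field")
        l2p = l2 // c2.pool_len
        if l2p < 1:
            raise ValueError("window too short for the configured conv/pool stack")
        self.use_bn = config.use_batch_norm
        self.layers["conv1"] = Conv1d(rng, 4, c1.n_filters, c1.filter_len)
        self.layers["pool1"] = MaxPool1d(c1.pool_len)
        self.layers["conv2"] = Conv1d(rng, c1.n_filters, c2.n_filters,
                                      c2.filter_len)
        self.layers["pool2"] = MaxPool1d(c2.pool_len)
        if self.use_bn:
            self.layers["bn1"] = BatchNorm(c1.n_filters)
            self.layers["bn2"] = BatchNorm(c2.n_filters)
        self.flat_dim = l2p * c2.n_filters
        self.layers["fc"] = Dense(rng, self.flat_dim, config.seq_fc_units)
        self.out_dim = config.seq_fc_units

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.layers["pool1"].forward(
            self.layers["conv1"].forward(x).relu())
        if self.use_bn:
            h = self.layers["bn1"].forward(h, training)
        h = self.layers["pool2"].forward(
            self.layers["conv2"].forward(h).relu())
        if self.use_bn:
            h = self.layers["bn2"].forward(h, training)
        h = h.reshape(h.data.shape[0], self.flat_dim)
        return self.layers["fc"].forward(h).relu()


class MethylationSubnetwork(Subnetwork):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.layers["bigru"] = BiGRU(rng, config.neighbor_dim,
                                     config.gru_hidden_units)
        self.out_dim = 2 * config.gru_hidden_units

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.ndim != 3 or x.data.shape[1] < 1:
            raise ValueError("neighbor input must be (batch, m >= 1, features)")
        return self.layers["bigru"].forward(x)


class JointSubnetwork(Subnetwork):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 in_dim: int):
        super().__init__()
        j1, j2 = config.joint_fc_units
        self.use_bn = config.use_batch_norm
        self.in_dim = in_dim
        self.layers["fc1"] = Dense(rng, in_dim, j1)
        self.layers["fc2"] = Dense(rng, j1, j2)
        if self.use_bn:
            self.layers["bn1"] = BatchNorm(j1)
            self.layers["bn2"] = BatchNorm(j2)
        self.out_dim = j2

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[-1] != self.in_dim:
            raise ValueError(f"joint subnetwork expects input dim {self.in_dim}, "
                             f"got {x.data.shape[-1]}")
        h = self.layers["fc1"].forward(x).relu()
        if self.use_bn:
            h = self.layers["bn1"].forward(h, training)
        h = self.layers["fc2"].forward(h).relu()
        if self.use_bn:
            h = self.layers["bn2"].forward(h, training)
        return h


class Head(Subnetwork):
    """Task-specific classification head: FC + ReLU, then a 2-logit softmax."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator,
                 in_dim: int):
        super().__init__()
        self.layers["fc"] = Dense(rng, in_dim, config.head_fc_units)
        self.layers["logits"] = Dense(rng, config.head_fc_units, 2)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.layers["fc"].forward(x).relu()
        z = self.layers["logits"].forward(h)
        # softmax over two classes: p(methylated) = sigmoid(z1 - z0)
        return (z[:, 1] - z[:, 0]).sigmoid()


class MethylationNetwork:
    """A Seq-only, Met-only or Full predictor with one head per task."""

    def __init__(self, config: NetworkConfig, mode: str, seed: int = 0):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.config = config
        self.mode = mode
        self.seed = seed
        # groups in `frozen` always run in inference mode (no batch-norm
        # statistic updates) and are skipped by the optimiser
        self.frozen: frozenset[str] = frozenset()
        rng = np.random.default_rng(seed)
        self.subnets: dict[str, Subnetwork] = {}
        if mode in ("seq", "full"):
            self.subnets["sequence"] = SequenceSubnetwork(config, rng)
        if mode in ("met", "full"):
            self.subnets["methylation"] = MethylationSubnetwork(config, rng)
        if mode == "full":
            in_dim = (self.subnets["sequence"].out_dim
                      + self.subnets["methylation"].out_dim)
            self.subnets["joint"] = JointSubnetwork(config, rng, in_dim)
            head_in = self.subnets["joint"].out_dim
        elif mode == "seq":
            head_in = self.subnets["sequence"].out_dim
        else:
            head_in = self.subnets["methylation"].out_dim
        self.heads = [Head(config, rng, head_in) for _ in range(config.n_tasks)]

    # ---- forward --------------------------------------------------------

    def features(self, seq: np.ndarray | None, neighbors: np.ndarray | None,
                 training: bool = False) -> Tensor:
        def tr(group: str) -> bool:
            return training and group not in self.frozen

        if self.mode == "seq":
            return self.subnets["sequence"].forward(Tensor(seq), tr("sequence"))
        if self.mode == "met":
            return self.subnets["methylation"].forward(Tensor(neighbors),
                                                       tr("methylation"))
        f_seq = self.subnets["sequence"].forward(Tensor(seq), tr("sequence"))
        f_met = self.subnets["methylation"].forward(Tensor(neighbors),
                                                    tr("methylation"))
        return self.subnets["joint"].forward(concat([f_seq, f_met], axis=-1),
                                             tr("joint"))

    def forward(self, seq: np.ndarray | None, neighbors: np.ndarray | None,
                training: bool = False) -> Tensor:
        """Probability of the methylated class, shape (batch, n_tasks)."""
        feats = self.features(seq, neighbors, training)
        cols = [h.forward(feats, training).reshape(-1, 1) for h in self.heads]
        return concat(cols, axis=1)

    def predict(self, batch, batch_size: int = 256) -> np.ndarray:
        """Inference over an EncodedBatch, in mini-batches; returns (n, m)."""
        n = batch.n_examples
        out = np.zeros((n, len(self.heads)), dtype=np.float64)
        for a in range(0, n, batch_size):
            b = min(a + batch_size, n)
            yhat = self.forward(batch.seq[a:b].astype(np.float64),
                                batch.neighbors[a:b].astype(np.float64),
                                training=False)
            out[a:b] = yhat.data
        return out

    # ---- parameters -----------------------------------------------------

    def group_names(self) -> list[str]:
        return list(self.subnets.keys()) + [f"head_{j}"
                                            for j in range(len(self.heads))]

    def _group(self, name: str) -> Subnetwork:
        if name in self.subnets:
            return self.subnets[name]
        if name.startswith("head_"):
            return self.heads[int(name.split("_", 1)[1])]
        raise KeyError(f"unknown parameter group {name!r}")

    def parameters(self, groups: list[str] | None = None) -> list[Tensor]:
        names = groups if groups is not None else self.group_names()
        out = []
        for g in names:
            out.extend(self._group(g).parameters())
        return out

    def save_parameters(self, path, meta: dict | None = None) -> None:
        """One .npz per parameter group plus a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for g in self.group_names():
            np.savez(path / f"{g}.npz", **self._group(g).state_dict())
        sidecar = {"config": self.config.to_dict(), "mode": self.mode,
                   "seed": self.seed, "groups": self.group_names()}
        if meta:
            sidecar["meta"] = meta
        with open(path / "model.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)

    def load_parameters(self, path, groups: list[str] | None = None) -> None:
        """Load the named groups (default: all present); others untouched."""
        path = Path(path)
        names = groups if groups is not None else [
            g for g in self.group_names() if (path / f"{g}.npz").exists()]
        for g in names:
            f = path / f"{g}.npz"
            if not f.exists():
                raise FileNotFoundError(f"checkpoint has no group {g!r} ({f})")
            with np.load(f) as npz:
                state = {k: npz[k] for k in npz.files}
            try:
                self._group(g).load_state_dict(state)
            except ValueError as exc:
                raise ValueError(f"group {g!r}: {exc}") from exc


def assemble_model(mode: str, config: NetworkConfig, seed: int = 0
                   ) -> MethylationNetwork:
    return MethylationNetwork(config, mode, seed)
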