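"""Training objectives.

Four per-site losses are supported for the methylated-probability output
``yhat``:

* ``logistic`` — binary cross-entropy on binarised labels,
  ``-y log(yhat) - (1-y) log(1-yhat)`` with ``y in {0, 1}``;
* ``kl`` — the KL divergence between the Bernoulli distribution implied by
  the *continuous* observed level ``y`` and the predicted one,
  ``y log(y/yhat) + (1-y) log((1-y)/(1-yhat))`` with the ``0 log 0 = 0``
  convention, which needs no binarisation and so preserves the information
  in intermediate methylation levels;
* ``mse`` / ``mse_sigmoid`` — squared-error baselines on the raw or
  sigmoid-mapped head score.

For binary ``y`` the KL divergence and the logistic loss coincide exactly
(the entropy term vanishes).  The multi-task objective combines per-site
losses over profiles with task weights ``alpha_j`` and per-site weights
``beta_ij`` derived from each profile's binarised class distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, xlogy

logger = logging.getLogger(__name__)

LOSS_KINDS = ("logistic", "kl", "mse", "mse_sigmoid")
EPSILON = 1e-6


@dataclass
class LossConfig:
    kind: str = "kl"
    task_weights: np.ndarray | None = None        # alpha_j, default all ones
    sample_weight_scheme: str = "inverse_frequency"  # beta_ij scheme
    epsilon: float = EPSILON
    reduction: str = "mean"                        # 'mean' or 'sum'
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not (0.0 < self.epsilon < 0.1):
            raise ValueError("epsilon must lie in (0, 0.1)")
        if self.sample_weight_scheme not in ("uniform", "inverse_frequency"):
            raise ValueError(f"unknown scheme {self.sample_weight_scheme!r}")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def binarize(y, threshold: float = 0.5) -> np.ndarray:
    """Strictly-greater binarisation: a level exactly at the threshold is 0."""
    return (np.asarray(y, dtype=np.float64) > threshold).astype(np.float64)


def _clip(yhat, eps: float) -> np.ndarray:
    return np.clip(np.asarray(yhat, dtype=np.float64), eps, 1.0 - eps)


def logistic_loss(y_binary, yhat, eps: float = EPSILON) -> np.ndarray:
    """Elementwise logistic loss; labels must already be binary."""
    y = np.asarray(y_binary, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic loss requires binary labels; "
                         "binarize() is the caller's explicit step")
    q = _clip(yhat, eps)
    return -y * np.log(q) - (1.0 - y) * np.log(1.0 - q)


def kl_divergence(y, yhat, eps: float = EPSILON) -> np.ndarray:
    """Elementwise KL divergence for continuous labels in [0, 1]."""
    y = np.asarray(y, dtype=np.float64)
    if ((y < 0.0) | (y > 1.0)).any():
        raise ValueError("labels must lie in [0, 1]")
    q = _clip(yhat, eps)
    # xlogy gives the 0 * log 0 = 0 convention for the y terms; writing the
    # cross-entropy part as -y log q makes KL(binary y) identical to the
    # logistic loss down to the last bit
    return (xlogy(y, y) - y * np.log(q)
            + xlogy(1.0 - y, 1.0 - y) - (1.0 - y) * np.log(1.0 - q))


def mse_loss(y, yhat, with_sigmoid: bool = False) -> np.ndarray:
    """Elementwise squared error; optionally squashes the raw score first."""
    y = np.asarray(y, dtype=np.float64)
    q = expit(np.asarray(yhat, dtype=np.float64)) if with_sigmoid else \
        np.asarray(yhat, dtype=np.float64)
    return (y - q) ** 2


def per_site_loss(kind: str, y, yhat, eps: float = EPSILON,
                  binarize_threshold: float = 0.5) -> np.ndarray:
    """Dispatch by loss kind; handles the binarisation logistic needs."""
    if kind == "logistic":
        return logistic_loss(binarize(y, binarize_threshold), yhat, eps)
    if kind == "kl":
        return kl_divergence(y, yhat, eps)
    if kind == "mse":
        return mse_loss(y, yhat, with_sigmoid=False)
    if kind == "mse_sigmoid":
        return mse_loss(y, yhat, with_sigmoid=True)
    raise ValueError(f"unknown loss kind {kind!r}")


def per_site_loss_grad(kind: str, y, yhat, eps: float = EPSILON,
                       binarize_threshold: float = 0.5) -> np.ndarray:
    """Analytic d(loss)/d(yhat); zero where the clipping saturates."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    inside = (yhat > eps) & (yhat < 1.0 - eps)
    q = _clip(yhat, eps)
    if kind in ("logistic", "kl"):
        yy = binarize(y, binarize_threshold) if kind == "logistic" else y
        g = -yy / q + (1.0 - yy) / (1.0 - q)
        return np.where(inside, g, 0.0)
    if kind == "mse":
        return 2.0 * (yhat - y)
    if kind == "mse_sigmoid":
        s = expit(yhat)
        return 2.0 * (s - y) * s * (1.0 - s)
    raise ValueError(f"unknown loss kind {kind!r}")


def sample_weights(labels: np.ndarray, label_mask: np.ndarray,
                   config: LossConfig) -> np.ndarray:
    """Per-site weights beta_ij, shape (n, m).

    ``inverse_frequency`` weights each observed site by the inverse count of
    its binarised class within its profile, normalised so the weights of
    profile j sum to N_j (the profile's observed count).  Binarisation here
    is only for computing weights; it never touches the labels the loss
    sees.  A single-class profile falls back to uniform weights.
    """
    labels = np.asarray(labels, dtype=np.float64)
    mask = np.asarray(label_mask, dtype=bool)
    w = np.zeros_like(labels)
    if config.sample_weight_scheme == "uniform":
        w[mask] = 1.0
        return w
    yb = binarize(labels, config.binarize_threshold)
    for j in range(labels.shape[1]):
        mj = mask[:, j]
        nj = int(mj.sum())
        if nj == 0:
            continue
        n1 = int(yb[mj, j].sum())
        n0 = nj - n1
        if n0 == 0 or n1 == 0:
            w[mj, j] = 1.0
            continue
        # inverse-frequency, normalised: beta = N_j / (2 * n_class)
        w[mj, j] = np.where(yb[mj, j] == 1.0, nj / (2.0 * n1), nj / (2.0 * n0))
    return w


def multi_task_loss(per_site_losses: np.ndarray, label_mask: np.ndarray,
                    config: LossConfig,
                    weights: np.ndarray | None = None) -> float:
    """Weighted multi-task reduction over observed (unmasked) entries.

    ``sum``: sum_j alpha_j sum_i beta_ij * loss_ij.  ``mean`` (default)
    divides by the number of observed entries so that learning rates are
    batch-size independent.
    """
    L = np.asarray(per_site_losses, dtype=np.float64)
    mask = np.asarray(label_mask, dtype=bool)
    if not mask.any():
        logger.warning("multi-task loss over an all-masked batch is zero")
        return 0.0
    w = multi_task_weight_matrix(L.shape, mask, config, weights)
    total = float((w * np.where(mask, L, 0.0)).sum())
    return total


def multi_task_weight_matrix(shape, label_mask: np.ndarray, config: LossConfig,
                             weights: np.ndarray | None = None) -> np.ndarray:
    """The (n, m) matrix W with total loss = sum(W * per_site_losses).

    This is also d(total)/d(per-site loss), used by the training engine to
    seed backpropagation.
    """
    mask = np.asarray(label_mask, dtype=bool)
    n, m = shape
    alpha = (np.ones(m) if config.task_weights is None
             else np.asarray(config.task_weights, dtype=np.float64))
    if (alpha < 0).any():
        raise ValueError("task weights must be non-negative")
    if alpha.shape != (m,):
        raise ValueError(f"expected {m} task weights, got {alpha.shape}")
    beta = np.ones((n, m)) if weights is None else np.asarray(weights, float)
    w = alpha[None, :] * beta * mask
    if config.reduction == "mean":
        w = w / mask.sum()
    return w
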