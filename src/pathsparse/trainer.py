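"""Training: cross-entropy loss, stepped learning-rate schedule, Adam loop.

Deep supervision: every output head receives its own binary cross-entropy
term and the per-head terms are combined with configurable weights, so the
auxiliary heads train rather than being dead parameters.  Gradients are
masked with each layer's connectivity matrix, keeping structurally absent
weights at exactly zero throughout training.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from pathsparse.errors import ConfigurationError, ValidationError
from pathsparse.features import CohortLabels, DataSplit, FeatureMatrix
from pathsparse.model import SparseModel, activation_derivative

logger = logging.getLogger(__name__)

EPS = 1e-7


@dataclass
class TrainingConfig:
    epochs: int = 1000
    base_learning_rate: float = 1e-3
    schedule_period: int = 100
    schedule_factor: float = 0.5
    seed: int = 0
    batch_size: int | None = None  # None -> full batch
    head_loss_weights: list[float] | None = None  # None -> model head weights
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.base_learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if not (0.0 < self.schedule_factor <= 1.0):
            raise ConfigurationError("schedule factor must be in (0, 1]")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def __len__(self) -> int:
        return len(self.train_loss)


def bce_loss(p, y) -> float:
    """Mean binary cross-entropy with probabilities clamped to [eps, 1-eps]."""
    p = np.asarray(p, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def lr_at_epoch(epoch: int, config: TrainingConfig) -> float:
    """Stepped decay: base * factor ** floor(epoch / period)."""
    return config.base_learning_rate * config.schedule_factor ** (epoch // config.schedule_period)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


def _loss_and_grads(model: SparseModel, x: np.ndarray, y: np.ndarray, head_w: np.ndarray, rng):
    """One forward/backward pass in train mode; returns (loss, grads dict)."""
    cache = model.forward_cached(x, train_mode=True, rng=rng)
    n = x.shape[0]
    p = cache["head_p"]  # batch x heads
    loss = float(sum(head_w[j] * bce_loss(p[:, j], y) for j in range(len(model.heads))))

    # d loss / d head pre-activation; clamping only affects the reported value
    d_head_z = head_w[None, :] * (p - y[:, None]) / n  # batch x heads

    grads: dict[str, np.ndarray] = {}
    hidden = model.hidden_layers()
    n_hidden = len(hidden)
    g_a = [None] * n_hidden
    for j, head in enumerate(model.heads):
        grads[f"head_w_{j}"] = cache["a"][j].T @ d_head_z[:, j]
        grads[f"head_b_{j}"] = d_head_z[:, j].sum()
        g_a[j] = np.outer(d_head_z[:, j], head.w)

    for l in range(n_hidden - 1, -1, -1):
        layer = hidden[l]
        g = g_a[l]
        g_z = g * activation_derivative(layer.activation, cache["z"][l])
        u = cache["u"][l]
        if l == 0:
            m, f = layer.n_genes, layer.features_per_gene
            x3 = u.reshape(-1, m, f)
            grads["gene_W"] = np.einsum("bg,bgf->gf", g_z, x3)
            grads["gene_b"] = g_z.sum(axis=0)
        else:
            weff = layer.effective_weight()
            grads[f"W_{l - 1}"] = (g_z.T @ u) * layer.M
            grads[f"b_{l - 1}"] = g_z.sum(axis=0)
            g_a[l - 1] = g_a[l - 1] + (g_z @ weff) * cache["drop"][l - 1]
    return loss, grads


def _parameters(model: SparseModel) -> dict[str, np.ndarray]:
    params = {"gene_W": model.gene_layer.W, "gene_b": model.gene_layer.b}
    for i, layer in enumerate(model.pathway_layers):
        params[f"W_{i}"] = layer.W
        params[f"b_{i}"] = layer.b
    for j, head in enumerate(model.heads):
        params[f"head_w_{j}"] = head.w
        params[f"head_b_{j}"] = head.b  # scalar; handled specially
    return params


def _eval_loss(model: SparseModel, x: np.ndarray, y: np.ndarray, head_w: np.ndarray) -> tuple[float, np.ndarray]:
    cache = model.forward_cached(x, train_mode=False)
    p = cache["head_p"]
    loss = float(sum(head_w[j] * bce_loss(p[:, j], y) for j in range(p.shape[1])))
    return loss, cache["combined"]


def _rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Midrank (Mann-Whitney) AUC; NaN if a class is missing."""
    y = np.asarray(y)
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def train(
    model: SparseModel,
    features: FeatureMatrix,
    labels: CohortLabels,
    split: DataSplit,
    config: TrainingConfig | None = None,
) -> tuple[SparseModel, TrainingHistory]:
    """Adam training loop with deep supervision and best-checkpoint selection.

    The passed-in model is updated in place to the final-epoch state; the
    returned model is a copy holding the best-validation-loss parameters.
    """
    config = config or TrainingConfig()
    if not split.train or not split.validation:
        raise ValidationError("split must have non-empty train and validation partitions")
    rng = np.random.default_rng(config.seed)

    x_train = features.rows_for(split.train)
    y_train = labels.vector_for(split.train)
    x_val = features.rows_for(split.validation)
    y_val = labels.vector_for(split.validation)

    if config.head_loss_weights is not None:
        head_w = np.asarray(config.head_loss_weights, dtype=np.float64)
        if head_w.shape != (len(model.heads),):
            raise ConfigurationError(f"need {len(model.heads)} head loss weights")
    else:
        head_w = model.head_weights.copy()

    # Adam state
    m_state = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in _parameters(model).items()}
    v_state = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in _parameters(model).items()}
    step = 0

    history = TrainingHistory()
    best_state: dict[str, np.ndarray] | None = None
    n_train = len(split.train)
    batch = config.batch_size or n_train

    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        order = rng.permutation(n_train) if batch < n_train else np.arange(n_train)
        epoch_losses = []
        for start in range(0, n_train, batch):
            idx = order[start : start + batch]
            loss, grads = _loss_and_grads(model, x_train[idx], y_train[idx], head_w, rng)
            if not np.isfinite(loss):
                raise ValidationError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
            step += 1
            params = _parameters(model)
            for key, grad in grads.items():
                g = np.asarray(grad, dtype=np.float64)
                m_state[key] = config.adam_beta1 * m_state[key] + (1 - config.adam_beta1) * g
                v_state[key] = config.adam_beta2 * v_state[key] + (1 - config.adam_beta2) * g**2
                m_hat = m_state[key] / (1 - config.adam_beta1**step)
                v_hat = v_state[key] / (1 - config.adam_beta2**step)
                update = lr * m_hat / (np.sqrt(v_hat) + config.adam_eps)
                if key.startswith("head_b_"):
                    j = int(key.split("_")[-1])
                    model.heads[j].b = float(model.heads[j].b - update)
                else:
                    params[key] -= update

        val_loss, val_scores = _eval_loss(model, x_val, y_val, head_w)
        if not np.isfinite(val_loss):
            raise ValidationError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_auc.append(_rank_auc(y_val, val_scores))
        history.learning_rate.append(lr)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = {k: np.copy(np.asarray(v, dtype=np.float64)) for k, v in _parameters(model).items()}
        if epoch % 100 == 0 or epoch == config.epochs - 1:
            logger.info(
                "epoch %d lr %.2e train %.4f val %.4f auc %.3f",
                epoch, lr, history.train_loss[-1], val_loss, history.val_auc[-1],
            )

    best_model = copy.deepcopy(model)
    if best_state is not None:
        best_params = _parameters(best_model)
        for key, value in best_state.items():
            if key.startswith("head_b_"):
                j = int(key.split("_")[-1])
                best_model.heads[j].b = float(value)
            else:
                np.copyto(best_params[key], value)
    return best_model, history
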