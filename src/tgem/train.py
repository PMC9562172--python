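"""Minibatch training of the attention classifier.

Adam on the mean negative log-likelihood, batch size 16 for 50 epochs by
default; after every epoch the training loss and validation accuracy are
recorded and the parameters with the best validation accuracy (earliest
epoch on ties) are kept.  All randomness flows from the config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .functional import backward_batch, forward_batch, nll_loss_and_grad, predict_proba
from .params import TGEMParams, flatten_params, init_params, parameter_count


@dataclass
class TrainConfig:
    n_layers: int = 1
    n_heads: int = 2
    activation: str = "none"
    batch_size: int = 16
    epochs: int = 50
    learning_rate: float = 1e-4
    seed: int = 0
    layer_norm: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _Adam:
    """Standard Adam updates over a flat list of parameter arrays (in place)."""

    def __init__(self, arrays: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _flatten_grads(layer_grads: list[dict], clf_grads: dict) -> list[np.ndarray]:
    arrays: list[np.ndarray] = []
    for g in layer_grads:
        arrays.extend([g["wq"], g["wk"], g["wv"], g["head_mix"], g["ln_gain"], g["ln_bias"]])
    arrays.extend([clf_grads["weight"], clf_grads["bias"]])
    return arrays


def accuracy_of(params: TGEMParams, X: np.ndarray, y: np.ndarray) -> float:
    probs = predict_proba(params, X)
    return float(np.mean(probs.argmax(axis=1) == y))


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    gene_names: list[str],
    class_names: list[str],
    init: TGEMParams | None = None,
) -> tuple[TGEMParams, list[dict]]:
    """Fit the model; returns the best-validation-epoch checkpoint and the log.

    The log holds one record per epoch: ``{epoch, train_loss, val_acc}``.
    """
    params = (
        init.copy()
        if init is not None
        else init_params(
            gene_names,
            class_names,
            n_layers=config.n_layers,
            n_heads=config.n_heads,
            activation=config.activation,
            layer_norm=config.layer_norm,
            seed=config.seed,
        )
    )
    rng = np.random.default_rng(config.seed)
    opt = _Adam(flatten_params(params), lr=config.learning_rate)
    n = X_train.shape[0]
    log: list[dict] = []
    best: tuple[float, int] | None = None
    best_params = params.copy()
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for bi, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start : start + config.batch_size]
            probs, logits, caches = forward_batch(X_train[idx], params)
            loss, dlogits = nll_loss_and_grad(logits, probs, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}"
                )
            layer_grads, clf_grads, _ = backward_batch(params, caches, dlogits)
            opt.step(_flatten_grads(layer_grads, clf_grads))
            losses.append(loss)
        val_acc = accuracy_of(params, X_val, y_val)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc})
        if best is None or val_acc > best[0]:
            best = (val_acc, epoch)
            best_params = params.copy()
    return best_params, log


# Table-style hyperparameter grid: layers 1-4, heads 1-5, and the
# classification-layer activation.
DEFAULT_GRID = {
    "n_layers": (1, 2, 3, 4),
    "n_heads": (1, 2, 3, 4, 5),
    "activation": ("none", "relu", "gelu"),
}


def grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    base_config: TrainConfig,
    gene_names: list[str],
    class_names: list[str],
    grid: dict | None = None,
) -> tuple[TrainConfig, TGEMParams, list[dict], list[dict]]:
    """Train every grid combination; select by validation accuracy.

    Ties prefer fewer parameters, then earlier grid order.  Returns the
    winning config, its fitted parameters and log, and the per-config
    validation table.
    """
    grid = dict(DEFAULT_GRID) if grid is None else grid
    combos = list(
        itertools.product(grid["n_layers"], grid["n_heads"], grid["activation"])
    )
    if not combos:
        raise ValueError("empty hyperparameter grid")
    table: list[dict] = []
    best_key = None
    best_out: tuple[TrainConfig, TGEMParams, list[dict]] | None = None
    for order, (L, H, act) in enumerate(combos):
        cfg = replace(base_config, n_layers=L, n_heads=H, activation=act)
        params, log = train(X_train, y_train, X_val, y_val, cfg, gene_names, class_names)
        val_acc = max(rec["val_acc"] for rec in log)
        n_par = parameter_count(params)
        table.append(
            {"n_layers": L, "n_heads": H, "activation": act,
             "val_acc": val_acc, "n_parameters": n_par}
        )
        key = (-val_acc, n_par, order)
        if best_key is None or key < best_key:
            best_key = key
            best_out = (cfg, params, log)
    assert best_out is not None
    return best_out[0], best_out[1], best_out[2], table
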