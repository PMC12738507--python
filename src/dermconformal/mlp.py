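"""Lightweight MLP classifier head over frozen foundation-model embeddings.

The backbone stays frozen; all learning happens in a small multi-layer
perceptron: ``n_blocks`` blocks, each a fully connected layer with half the
neurons of the previous one, 1D batch normalisation, ReLU and dropout,
followed by a final fully connected layer to the class logits.  Training is
plain minibatch Adam on cross-entropy, with the per-epoch training stream
optionally drawn by the challenge-regulated F1 sampler, and the best state
(highest validation macro-F1) checkpointed and restored.

Implemented directly in numpy: the sampler hooks into the epoch loop, which
off-the-shelf estimators do not expose.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, recall_score, roc_auc_score

from .cohort import EmbeddingRecord
from .sampler import (
    SamplerConfig,
    f1_weights,
    frequency_weights,
    kfold_mean_f1,
    regulate_weights,
    sample_epoch,
)

__all__ = [
    "MLPConfig",
    "MLPHead",
    "classwise_metrics",
    "predict_proba",
    "train_head",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimisation settings for the classifier head.

    Defaults are a scaled-down profile for 64-dimensional synthetic
    embeddings; :meth:`full_scale_preset` gives the full 2048-input, 6-block,
    40-epoch configuration used with real foundation-model embeddings.
    Activation (ReLU), optimiser (Adam) and the 128 / 1e-3 batch size and
    learning rate are package defaults, exposed here.
    """

    input_dim: int = 64
    n_blocks: int = 3
    dropout_rate: float = 0.2
    epochs: int = 40
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    sampler: SamplerConfig | None = field(default_factory=SamplerConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def full_scale_preset(cls, **overrides) -> "MLPConfig":
        """2048 input neurons, 6 halving blocks, 40 epochs."""
        base = cls(input_dim=2048, n_blocks=6, epochs=40)
        return replace(base, **overrides)

    def widths(self, n_classes: int) -> list[int]:
        """Hidden widths (each half the previous) plus the output width."""
        ws = []
        w = self.input_dim
        for _ in range(self.n_blocks):
            w = w // 2
            ws.append(w)
        if min(ws) < n_classes:
            raise ValueError(
                f"hidden widths {ws} fall below n_classes={n_classes}; "
                "reduce n_blocks or raise input_dim"
            )
        return ws + [n_classes]


class MLPHead:
    """The trained (or trainable) numpy MLP.  Use :func:`train_head` to fit."""

    def __init__(self, cfg: MLPConfig, n_classes: int):
        self.cfg = cfg
        self.n_classes = n_classes
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        self.fitted = False
        widths = cfg.widths(n_classes)
        self._dims = [cfg.input_dim] + widths

    # -- parameter plumbing -------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        dims = self._dims
        for i in range(len(dims) - 1):
            fan_in, fan_out = dims[i], dims[i + 1]
            # He initialisation for the ReLU blocks
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            self.params[f"b{i}"] = np.zeros(fan_out)
            if i < len(dims) - 2:  # batch-norm only inside blocks
                self.params[f"gamma{i}"] = np.ones(fan_out)
                self.params[f"beta{i}"] = np.zeros(fan_out)
                self.running[f"mean{i}"] = np.zeros(fan_out)
                self.running[f"var{i}"] = np.ones(fan_out)

    def snapshot(self) -> tuple[dict, dict]:
        return copy.deepcopy(self.params), copy.deepcopy(self.running)

    def restore(self, state: tuple[dict, dict]) -> None:
        self.params, self.running = copy.deepcopy(state[0]), copy.deepcopy(state[1])

    # -- forward / backward -------------------------------------------------
    def _forward_train(self, x: np.ndarray, rng: np.random.Generator):
        cache = []
        h = x
        n_blocks = len(self._dims) - 2
        for i in range(n_blocks):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            bn = self.params[f"gamma{i}"] * zhat + self.params[f"beta{i}"]
            self.running[f"mean{i}"] = (
                _BN_MOMENTUM * self.running[f"mean{i}"] + (1 - _BN_MOMENTUM) * mu
            )
            self.running[f"var{i}"] = (
                _BN_MOMENTUM * self.running[f"var{i}"] + (1 - _BN_MOMENTUM) * var
            )
            relu_mask = bn > 0
            a = bn * relu_mask
            if self.cfg.dropout_rate > 0:
                keep = 1.0 - self.cfg.dropout_rate
                drop_mask = (rng.random(a.shape) < keep) / keep
                out = a * drop_mask
            else:
                drop_mask = None
                out = a
            cache.append((h, zhat, inv_std, relu_mask, drop_mask))
            h = out
        k = n_blocks
        logits = h @ self.params[f"W{k}"] + self.params[f"b{k}"]
        cache.append((h,))
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        n_blocks = len(self._dims) - 2
        (h_last,) = cache[-1]
        k = n_blocks
        grads[f"W{k}"] = h_last.T @ dlogits
        grads[f"b{k}"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params[f"W{k}"].T
        for i in reversed(range(n_blocks)):
            h_in, zhat, inv_std, relu_mask, drop_mask = cache[i]
            if drop_mask is not None:
                dh = dh * drop_mask
            dbn = dh * relu_mask
            grads[f"gamma{i}"] = (dbn * zhat).sum(axis=0)
            grads[f"beta{i}"] = dbn.sum(axis=0)
            dzhat = dbn * self.params[f"gamma{i}"]
            n = zhat.shape[0]
            dz = (inv_std / n) * (
                n * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            grads[f"W{i}"] = h_in.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return grads

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (running BN stats, no dropout)."""
        h = np.asarray(x, dtype=np.float64)
        n_blocks = len(self._dims) - 2
        for i in range(n_blocks):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            zhat = (z - self.running[f"mean{i}"]) / np.sqrt(self.running[f"var{i}"] + _BN_EPS)
            h = np.maximum(self.params[f"gamma{i}"] * zhat + self.params[f"beta{i}"], 0.0)
        k = n_blocks
        return h @ self.params[f"W{k}"] + self.params[f"b{k}"]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not trained; call train_head first")
        logits = self.predict_logits(x)
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=1, keepdims=True)


def _records_to_arrays(
    records: Sequence[EmbeddingRecord], input_dim: int
) -> tuple[np.ndarray, np.ndarray]:
    bad = [r.id for r in records if r.vector.shape != (input_dim,)]
    if bad:
        raise ValueError(
            f"embedding dimension mismatch (expected {input_dim}) for records: "
            + ", ".join(bad[:5])
            + ("..." if len(bad) > 5 else "")
        )
    x = np.stack([r.vector for r in records])
    y = np.array([r.label for r in records], dtype=int)
    return x, y


def train_head(
    train: Sequence[EmbeddingRecord],
    validation: Sequence[EmbeddingRecord],
    cfg: MLPConfig,
    n_classes: int | None = None,
) -> tuple[MLPHead, pd.DataFrame]:
    """Train the head; returns the best-state model and the training log.

    Per epoch, the training stream is drawn by :func:`sample_epoch` when a
    sampler is configured (one draw per training record, with replacement);
    sampler weights start at inverse class frequency and are refreshed from
    the k-fold mean validation F1 every ``refresh_period`` epochs.  The model
    state with the highest validation macro-F1 is kept.  The log has one row
    per epoch: mean training loss, validation macro-F1, and the active
    sampler weights.
    """
    if not train:
        raise ValueError("training set is empty")
    x_train, y_train = _records_to_arrays(train, cfg.input_dim)
    x_val, y_val = _records_to_arrays(validation, cfg.input_dim)
    if n_classes is None:
        n_classes = int(max(y_train.max(), y_val.max(initial=0))) + 1

    model = MLPHead(cfg, n_classes)
    rng = np.random.default_rng(cfg.seed)
    model._init_params(rng)
    model.fitted = True  # allows validation predictions during training

    counts = np.bincount(y_train, minlength=n_classes)
    weights = frequency_weights(np.maximum(counts, 1)) if cfg.sampler else None

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    log_rows = []
    best_f1, best_state = -1.0, None
    class_ids = np.arange(n_classes)

    for epoch in range(cfg.epochs):
        if weights is not None:
            epoch_seed = int(rng.integers(2**31))
            order = sample_epoch(weights, y_train, n_draws=y_train.size, seed=epoch_seed)
        else:
            order = rng.permutation(y_train.size)

        losses = []
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs at least two samples
            xb, yb = x_train[idx], y_train[idx]
            logits, cache = model._forward_train(xb, rng)
            shifted = logits - logits.max(axis=1, keepdims=True)
            logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
            losses.append(-logp[np.arange(yb.size), yb].mean())
            probs = np.exp(logp)
            dlogits = probs
            dlogits[np.arange(yb.size), yb] -= 1.0
            dlogits /= yb.size
            grads = model._backward(dlogits, cache)
            step += 1
            for key, g in grads.items():
                adam_m[key] = b1 * adam_m[key] + (1 - b1) * g
                adam_v[key] = b2 * adam_v[key] + (1 - b2) * g * g
                mhat = adam_m[key] / (1 - b1**step)
                vhat = adam_v[key] / (1 - b2**step)
                model.params[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        val_probs = model.predict_proba(x_val)
        val_f1 = f1_score(
            y_val, val_probs.argmax(axis=1), labels=class_ids, average="macro",
            zero_division=0.0,
        )
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_state = model.snapshot()

        log_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)) if losses else np.nan,
                "val_macro_f1": float(val_f1),
                "sampler_weights": (
                    tuple(np.round(weights.weights, 8)) if weights is not None else None
                ),
            }
        )

        if weights is not None and (epoch + 1) % cfg.sampler.refresh_period == 0:
            refresh_seed = int(rng.integers(2**31))
            mean_f1 = kfold_mean_f1(val_probs, y_val, cfg.sampler.k_folds, refresh_seed)
            raw = f1_weights(mean_f1, cfg.sampler.f1_floor)
            weights = regulate_weights(raw, cfg.sampler)

    if best_state is not None:
        model.restore(best_state)
    return model, pd.DataFrame(log_rows)


def predict_proba(model: MLPHead, records: Sequence[EmbeddingRecord]) -> np.ndarray:
    """Row-normalised class probabilities for each record, in input order."""
    x, _ = _records_to_arrays(records, model.cfg.input_dim)
    return model.predict_proba(x)


def classwise_metrics(truth: Sequence[int], prob_matrix: np.ndarray) -> pd.DataFrame:
    """Per-class accuracy, recall, F1 and one-vs-rest AUC of argmax predictions.

    Per-class "accuracy" follows the classwise-table convention of diagonal
    over row sum, i.e. it equals recall.  Classes absent from the truth get
    NaN metrics (undefined, not zero).
    """
    truth = np.asarray(truth, dtype=int)
    prob_matrix = np.asarray(prob_matrix, dtype=np.float64)
    n_classes = prob_matrix.shape[1]
    preds = prob_matrix.argmax(axis=1)
    class_ids = np.arange(n_classes)

    recall = np.full(n_classes, np.nan)
    f1 = np.full(n_classes, np.nan)
    auc = np.full(n_classes, np.nan)
    present = np.isin(class_ids, truth)
    if present.any():
        recall[present] = recall_score(
            truth, preds, labels=class_ids[present], average=None, zero_division=0.0
        )
        f1[present] = f1_score(
            truth, preds, labels=class_ids[present], average=None, zero_division=0.0
        )
        for c in class_ids[present]:
            binary = (truth == c).astype(int)
            if 0 < binary.sum() < binary.size:
                auc[c] = roc_auc_score(binary, prob_matrix[:, c])
    return pd.DataFrame(
        {
            "class": class_ids,
            "accuracy": recall,  # classwise accuracy == recall by convention
            "recall": recall,
            "f1": f1,
            "auc": auc,
        }
    ).set_index("class")
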