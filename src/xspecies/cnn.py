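"""Sequence CNN for open-chromatin classification, implemented in numpy.

Architecture: a stack of valid (unpadded) 1-D convolutions (ReLU, dropout,
L2 on weights) over one-hot 500-bp windows, one non-overlapping max-pool,
one ReLU fully connected layer and a sigmoid output giving the probability
the sequence is an OCR in the training tissue.

Training protocol: class-weighted binary cross-entropy (each class weighted
by the fraction of examples in the other class), SGD with Nesterov momentum,
He-normal initialization, weights warm-started from a run on a class-balanced
down-sample, and early stopping on recall at 80% precision on the validation
set (or specificity at 80% NPV when validation positives outnumber
negatives) with a patience of three epochs and best-epoch weight restoration.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import reverse_complement_one_hot


@dataclass
class ModelConfig:
    """Hyper-parameters; defaults are the full-scale published protocol."""

    input_len: int = 500
    n_conv_layers: int = 5
    filters_per_layer: int = 300  # 300 single-species, 350 multi-species
    filter_width: int = 7
    conv_stride: int = 1
    dropout: float = 0.2
    l2: float = 1e-5
    pool_width: int = 26
    pool_stride: int = 26
    fc_units: int = 300
    learning_rate: float = 0.001
    momentum: float = 0.99
    nesterov: bool = True
    batch_size: int = 100
    patience_epochs: int = 3
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_conv_layers", "filters_per_layer", "filter_width",
                     "pool_width", "pool_stride", "fc_units", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.conv_stride != 1:
            raise NotImplementedError("only conv stride 1 is supported")

    def conv_output_len(self) -> int:
        return self.input_len - self.n_conv_layers * (self.filter_width - 1)

    def pooled_len(self) -> int:
        return self.conv_output_len() // self.pool_stride


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    metric: list = field(default_factory=list)
    monitor: str = ""
    stopped_epoch: int = 0
    best_epoch: int = 0


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    n, length, c = x.shape
    lout = length - width + 1
    s0, s1, s2 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, lout, width, c), (s0, s1, s1, s2), writeable=False
    )
    return view.reshape(n, lout, width * c)


class SequenceCNN:
    """Trainable CNN; deterministic at inference for fixed weights."""

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        cfg = config
        lconv = cfg.conv_output_len()
        if lconv < cfg.pool_width:
            raise ValueError(
                f"pool width {cfg.pool_width} exceeds post-convolution length "
                f"{lconv} (input {cfg.input_len}, {cfg.n_conv_layers} layers of "
                f"width {cfg.filter_width})"
            )
        self.config = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        self.params: list[dict[str, np.ndarray]] = []
        c_in = 4
        for _ in range(cfg.n_conv_layers):
            fan_in = cfg.filter_width * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(fan_in, cfg.filters_per_layer)).astype(np.float32)
            self.params.append({"W": w, "b": np.zeros(cfg.filters_per_layer, np.float32)})
            c_in = cfg.filters_per_layer
        flat = cfg.pooled_len() * cfg.filters_per_layer
        w1 = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, cfg.fc_units)).astype(np.float32)
        self.params.append({"W": w1, "b": np.zeros(cfg.fc_units, np.float32)})
        w2 = rng.normal(0.0, np.sqrt(2.0 / cfg.fc_units), size=(cfg.fc_units, 1)).astype(np.float32)
        self.params.append({"W": w2, "b": np.zeros(1, np.float32)})

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]):
        cfg = self.config
        cache = {"conv": [], "x_shapes": []}
        h = np.ascontiguousarray(x, dtype=np.float32)
        for li in range(cfg.n_conv_layers):
            cols = _im2col(h, cfg.filter_width)
            z = cols @ self.params[li]["W"] + self.params[li]["b"]
            relu_mask = z > 0
            a = z * relu_mask
            drop_mask = None
            if train and cfg.dropout > 0:
                drop_mask = (rng.random(a.shape) >= cfg.dropout).astype(np.float32)
                a = a * drop_mask / (1.0 - cfg.dropout)
            cache["conv"].append((cols, relu_mask, drop_mask, h.shape))
            h = np.ascontiguousarray(a)
        # non-overlapping max-pool; trailing remainder positions are dropped
        n = h.shape[0]
        nwin = cfg.pooled_len()
        pooled_in = h[:, : nwin * cfg.pool_stride, :].reshape(
            n, nwin, cfg.pool_stride, cfg.filters_per_layer
        )
        argmax = pooled_in.argmax(axis=2)
        pooled = np.take_along_axis(pooled_in, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        cache["pool"] = (argmax, h.shape)
        flat = pooled.reshape(n, -1)
        z1 = flat @ self.params[-2]["W"] + self.params[-2]["b"]
        m1 = z1 > 0
        a1 = z1 * m1
        logits = (a1 @ self.params[-1]["W"] + self.params[-1]["b"])[:, 0]
        cache["fc"] = (flat, m1, a1)
        return logits, cache

    def _backward(self, cache, dlogits: np.ndarray) -> list[dict[str, np.ndarray]]:
        cfg = self.config
        grads = [dict() for _ in self.params]
        flat, m1, a1 = cache["fc"]
        dl = dlogits[:, None].astype(np.float32)
        grads[-1]["W"] = a1.T @ dl
        grads[-1]["b"] = dl.sum(0)
        da1 = dl @ self.params[-1]["W"].T
        dz1 = da1 * m1
        grads[-2]["W"] = flat.T @ dz1
        grads[-2]["b"] = dz1.sum(0)
        dflat = dz1 @ self.params[-2]["W"].T

        argmax, h_shape = cache["pool"]
        n = h_shape[0]
        nwin = cfg.pooled_len()
        dpooled = dflat.reshape(n, nwin, cfg.filters_per_layer)
        dh = np.zeros(h_shape, np.float32)
        dwin = dh[:, : nwin * cfg.pool_stride, :].reshape(
            n, nwin, cfg.pool_stride, cfg.filters_per_layer
        )
        np.put_along_axis(dwin, argmax[:, :, None, :], dpooled[:, :, None, :], axis=2)

        for li in range(cfg.n_conv_layers - 1, -1, -1):
            cols, relu_mask, drop_mask, in_shape = cache["conv"][li]
            da = dh
            if drop_mask is not None:
                da = da * drop_mask / (1.0 - cfg.dropout)
            dz = da * relu_mask
            lout = dz.shape[1]
            grads[li]["W"] = cols.reshape(-1, cols.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
            grads[li]["b"] = dz.sum((0, 1))
            dcols = (dz @ self.params[li]["W"].T).reshape(
                dz.shape[0], lout, cfg.filter_width, in_shape[2]
            )
            dh = np.zeros(in_shape, np.float32)
            for w in range(cfg.filter_width):
                dh[:, w : w + lout, :] += dcols[:, :, w, :]
        return grads

    # -- inference ----------------------------------------------------------

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Probabilities for a batch of one-hot windows ``(N, L, 4)``."""
        out = np.empty(x.shape[0], dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[i : i + batch_size], train=False, rng=None)
            out[i : i + batch_size] = _sigmoid(logits)
        return out

    def get_weights(self):
        return copy.deepcopy(self.params)

    def set_weights(self, params) -> None:
        self.params = copy.deepcopy(params)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.params):
            arrays[f"W{i}"] = layer["W"]
            arrays[f"b{i}"] = layer["b"]
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "SequenceCNN":
        data = np.load(path, allow_pickle=False)
        cfg = ModelConfig(**json.loads(str(data["config"])))
        model = cls(cfg)
        for i in range(len(model.params)):
            model.params[i]["W"] = data[f"W{i}"]
            model.params[i]["b"] = data[f"b{i}"]
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_model(config: ModelConfig) -> SequenceCNN:
    """Untrained model with He-normal initial weights (seeded)."""
    return SequenceCNN(config)


# ---------------------------------------------------------------------------
# threshold-free metrics used for early stopping
# ---------------------------------------------------------------------------

def recall_at_precision(
    scores: Sequence[float], labels: Sequence[int], precision_min: float = 0.80
) -> float:
    """Maximum recall over score thresholds whose precision >= ``precision_min``.

    Thresholds sweep the distinct score values (ties grouped); returns 0 when
    no threshold reaches the required precision.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("labels contain no positive")
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys)
    n_pred = np.arange(1, len(ys) + 1)
    group_ends = np.flatnonzero(np.r_[ss[1:] != ss[:-1], True])
    precision = tp[group_ends] / n_pred[group_ends]
    recall = tp[group_ends] / n_pos
    ok = precision >= precision_min
    return float(recall[ok].max()) if ok.any() else 0.0


def specificity_at_npv(
    scores: Sequence[float], labels: Sequence[int], npv_min: float = 0.80
) -> float:
    """Class-swap identity: recall@precision of the negative class."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if (y == 0).sum() == 0:
        raise ValueError("labels contain no negative")
    return recall_at_precision(1.0 - s, 1 - y, npv_min)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without strict improvement.

    ``update`` returns True when training should halt; ``best_epoch`` is the
    epoch whose weights should be restored.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.n_bad = 0
        self.epoch = 0

    def update(self, metric: float) -> bool:
        self.epoch += 1
        if metric > self.best:
            self.best = metric
            self.best_epoch = self.epoch
            self.n_bad = 0
            return False
        self.n_bad += 1
        return self.n_bad >= self.patience


def _weighted_bce(p, y, w):
    eps = 1e-12
    return float(-np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))


def train(
    model: SequenceCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    class_weight: Optional[dict[int, float]] = None,
    config: Optional[ModelConfig] = None,
    restore_best: bool = True,
) -> TrainingHistory:
    """Class-weighted SGD/Nesterov training with bespoke early stopping.

    The monitored validation metric is recall at 80% precision, switching to
    specificity at 80% NPV when the validation set has more positives than
    negatives.  Training halts after ``patience_epochs`` consecutive epochs
    without strict improvement; the best epoch's weights are restored.
    """
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    y_train = np.asarray(y_train, dtype=np.float32)
    if class_weight is None:
        class_weight = {0: 1.0, 1: 1.0}
    sample_w = np.where(y_train == 1, class_weight[1], class_weight[0]).astype(np.float32)

    n_pos_val = int(np.sum(y_val == 1))
    n_neg_val = int(np.sum(y_val == 0))
    if n_pos_val > n_neg_val:
        monitor, metric_fn = "specificity_at_80pct_npv", specificity_at_npv
    else:
        monitor, metric_fn = "recall_at_80pct_precision", recall_at_precision

    velocity = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in model.params]
    history = TrainingHistory(monitor=monitor)
    stopper = EarlyStopper(cfg.patience_epochs)
    best_weights = model.get_weights()
    n = x_train.shape[0]

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = x_train[idx]
            yb = y_train[idx]
            wb = sample_w[idx]
            logits, cache = model._forward(xb, train=True, rng=rng)
            if not np.all(np.isfinite(logits)):
                raise FloatingPointError(
                    f"non-finite logits at epoch {epoch} batch {n_batches}; "
                    "training diverged (check learning rate)"
                )
            p = _sigmoid(logits)
            loss = _weighted_bce(p, yb, wb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} batch {n_batches}: "
                    f"loss={loss}, logit range=({logits.min()}, {logits.max()})"
                )
            epoch_loss += loss
            n_batches += 1
            dlogits = (wb * (p - yb)).astype(np.float32) / len(yb)
            grads = model._backward(cache, dlogits)
            # L2 penalty on convolutional layer weights only
            for li in range(cfg.n_conv_layers):
                grads[li]["W"] = grads[li]["W"] + 2.0 * cfg.l2 * model.params[li]["W"]
            for layer, vel, g in zip(model.params, velocity, grads):
                for k in layer:
                    gk = g[k].astype(np.float32)
                    vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * gk
                    if cfg.nesterov:
                        layer[k] = layer[k] + cfg.momentum * vel[k] - cfg.learning_rate * gk
                    else:
                        layer[k] = layer[k] + vel[k]
        val_scores = model.predict(x_val)
        metric = metric_fn(val_scores, y_val)
        history.loss.append(epoch_loss / max(n_batches, 1))
        history.metric.append(metric)
        should_stop = stopper.update(metric)
        if stopper.best_epoch == epoch:
            best_weights = model.get_weights()
            history.best_epoch = epoch
        if should_stop:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = cfg.max_epochs
    if restore_best:
        model.set_weights(best_weights)
    return history


def pretrain_balanced(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig,
    seed: int = 0,
    epochs: Optional[int] = None,
):
    """Initial weights from a run on a class-balanced random down-sample.

    The majority class is down-sampled to the size of the minority class
    (whichever class is larger) and the same architecture is trained with
    equal class weights for a fixed epoch budget (default ``max_epochs``);
    the resulting weights seed — and warm-start — the main run, so the main
    run's early stopping operates on an already-competent model.
    """
    y = np.asarray(y_train)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("pre-training requires both classes")
    rng = np.random.default_rng(seed)
    m = min(len(pos_idx), len(neg_idx))
    take_pos = rng.choice(pos_idx, size=m, replace=False)
    take_neg = rng.choice(neg_idx, size=m, replace=False)
    idx = np.sort(np.concatenate([take_pos, take_neg]))
    cfg = copy.deepcopy(config)
    cfg.max_epochs = epochs if epochs is not None else config.max_epochs
    cfg.patience_epochs = cfg.max_epochs  # fixed budget: no early stop here
    model = SequenceCNN(cfg)
    train(model, x_train[idx], y[idx], x_val, y_val, class_weight={0: 0.5, 1: 0.5},
          config=cfg, restore_best=False)
    return model.get_weights(), idx


def predict_strand_averaged(model: SequenceCNN, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Average of forward- and reverse-complement-strand probabilities.

    In one-hot space with column order (A, C, G, T) the reverse complement is
    ``x[..., ::-1, ::-1]``, so the output is invariant to which strand of a
    window is supplied.
    """
    fwd = model.predict(x, batch_size=batch_size)
    rev = model.predict(np.ascontiguousarray(reverse_complement_one_hot(x)), batch_size=batch_size)
    return (fwd + rev) / 2.0
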