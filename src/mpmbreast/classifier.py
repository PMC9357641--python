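"""Trainable tile-level cancer classifier.

The reference training protocol (Adam, 100 epochs, learning rate 0.020,
batch size 128, model selection on a validation split) is kept as the
default :class:`TrainConfig`; the pipeline's desk-scale configuration
(:meth:`TrainConfig.desk_default`) trains a compact convolutional network
implemented in NumPy:

    input (3 x 128 x 128 standardized tile)
      -> per-block summary: 4x4 block mean and block standard deviation
         (6 x 32 x 32); the deviation channels keep the fine-scale texture
         cues (nuclear voids, edge puncta) that mean pooling would erase
      -> conv 3x3, 8 filters, ReLU, 2x2 max-pool
      -> conv 3x3, 16 filters, ReLU, 2x2 max-pool
      -> dense 1024 -> 32, ReLU
      -> dense 32 -> 1, sigmoid

Binary cross-entropy loss; the parameter state with the best validation
accuracy across epochs is returned (ties resolved to the earliest epoch).
The ``inception_v3`` architecture id is reserved for an external
deep-learning backend and is not trainable here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateTrainingError, GeometryError, InvalidConfigError
from .preprocess import Tile

__all__ = ["TrainConfig", "TileClassifierModel", "train", "predict", "predict_batch"]

_POOLED_SIDE = 32
_LABEL_MAP = {"cancer": 1, "no_cancer": 0}


@dataclass(frozen=True)
class TrainConfig:
    architecture: str = "small_cnn"
    epochs: int = 100
    learning_rate: float = 0.020
    batch_size: int = 128
    optimizer: str = "adam"
    balance_classes: bool = True
    positive_cost: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidConfigError("invalid training hyperparameters")
        if self.positive_cost <= 0:
            raise InvalidConfigError("positive_cost must be positive")
        if self.architecture not in ("small_cnn", "inception_v3"):
            raise InvalidConfigError(f"unknown architecture {self.architecture!r}")
        if self.optimizer != "adam":
            raise InvalidConfigError("only the adam optimizer is supported")

    @classmethod
    def desk_default(cls, seed: int = 0) -> "TrainConfig":
        """Desk-scale configuration: fewer epochs and a smaller step size
        suited to the compact network and synthetic cohorts."""
        return cls(epochs=40, learning_rate=0.005, seed=seed)


# ---------------------------------------------------------------------------
# numpy conv-net primitives


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, pad : h + pad, pad : w + pad]


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = r.argmax(axis=-1)
    return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, shape: tuple) -> np.ndarray:
    n, c, h, w = shape
    dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    return dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def tile_features(x: np.ndarray, side: int = _POOLED_SIDE) -> np.ndarray:
    """Block mean + block standard deviation summary of a batch of tiles.

    (n, 3, h, w) -> (n, 6, side, side); h and w must be multiples of side.
    Inputs already in feature form (6 channels at the pooled side) pass
    through unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    if c == 2 * 3 and h == side and w == side:
        return x
    if c != 3 or h % side or w % side:
        raise GeometryError(f"expected 3-channel tiles with sides divisible by {side}")
    fy, fx = h // side, w // side
    blocks = x.reshape(n, c, side, fy, side, fx)
    mean = blocks.mean(axis=(3, 5))
    var = (blocks**2).mean(axis=(3, 5)) - mean**2
    std = np.sqrt(np.clip(var, 0.0, None))
    return np.concatenate([mean, std], axis=1)


def _init_params(rng: np.random.Generator) -> dict[str, np.ndarray]:
    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    return {
        "W1": he((8, 6, 3, 3), 54),
        "b1": np.zeros(8),
        "W2": he((16, 8, 3, 3), 72),
        "b2": np.zeros(16),
        "W3": he((1024, 32), 1024),
        "b3": np.zeros(32),
        # small output-layer init keeps untrained logits near zero
        "W4": 0.05 * he((32, 1), 32),
        "b4": np.zeros(1),
    }


def _forward(params: dict, x: np.ndarray, cache: bool = False):
    n = x.shape[0]
    x = tile_features(x)
    c1 = _im2col(x)  # (n,54,1024)
    z1 = np.einsum("fk,nkp->nfp", params["W1"].reshape(8, -1), c1) + params["b1"][None, :, None]
    z1 = z1.reshape(n, 8, 32, 32)
    a1 = np.maximum(z1, 0.0)
    p1, idx1 = _maxpool2(a1)  # (n,8,16,16)
    c2 = _im2col(p1)  # (n,72,256)
    z2 = np.einsum("fk,nkp->nfp", params["W2"].reshape(16, -1), c2) + params["b2"][None, :, None]
    z2 = z2.reshape(n, 16, 16, 16)
    a2 = np.maximum(z2, 0.0)
    p2, idx2 = _maxpool2(a2)  # (n,16,8,8)
    flat = p2.reshape(n, -1)
    z3 = flat @ params["W3"] + params["b3"]
    a3 = np.maximum(z3, 0.0)
    logits = (a3 @ params["W4"] + params["b4"]).ravel()
    prob = 1.0 / (1.0 + np.exp(-logits))
    if not cache:
        return prob
    return prob, (c1, z1, a1, p1, idx1, c2, z2, a2, p2, idx2, flat, z3, a3)


def _backward(
    params: dict, caches, prob: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> dict:
    c1, z1, a1, p1, idx1, c2, z2, a2, p2, idx2, flat, z3, a3 = caches
    n = len(y)
    if w is None:
        dlogit = (prob - y) / n  # BCE with sigmoid
    else:
        dlogit = w * (prob - y) / w.sum()  # class-weighted BCE
    grads = {}
    grads["W4"] = a3.T @ dlogit[:, None]
    grads["b4"] = np.array([dlogit.sum()])
    da3 = dlogit[:, None] @ params["W4"].T
    dz3 = da3 * (z3 > 0)
    grads["W3"] = flat.T @ dz3
    grads["b3"] = dz3.sum(axis=0)
    dflat = dz3 @ params["W3"].T
    dp2 = dflat.reshape(p2.shape)
    da2 = _maxpool2_backward(dp2, idx2, a2.shape)
    dz2 = da2 * (z2 > 0)
    dz2p = dz2.reshape(n, 16, -1)
    grads["W2"] = np.einsum("nfp,nkp->fk", dz2p, c2).reshape(params["W2"].shape)
    grads["b2"] = dz2p.sum(axis=(0, 2))
    dc2 = np.einsum("fk,nfp->nkp", params["W2"].reshape(16, -1), dz2p)
    dp1 = _col2im(dc2, p1.shape)
    da1 = _maxpool2_backward(dp1, idx1, a1.shape)
    dz1 = da1 * (z1 > 0)
    dz1p = dz1.reshape(n, 8, -1)
    grads["W1"] = np.einsum("nfp,nkp->fk", dz1p, c1).reshape(params["W1"].shape)
    grads["b1"] = dz1p.sum(axis=(0, 2))
    return grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# public model API


@dataclass
class TileClassifierModel:
    architecture: str
    params: dict
    metadata: dict

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return _forward(self.params, x)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = dict(self.metadata, architecture=self.architecture)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TileClassifierModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as data:
            params = {k: data[k] for k in data.files}
        return cls(meta.pop("architecture"), params, meta)


def _coerce_xy(tiles, labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tiles, (list, tuple)) and tiles and isinstance(tiles[0], Tile):
        if any(t.is_blank for t in tiles):
            raise InvalidConfigError("blank tiles must be excluded before training")
        if labels is None:
            labels = [t.truth_label for t in tiles]
        tiles = np.stack([t.pixels for t in tiles])
    x = np.asarray(tiles, dtype=np.float64)
    y = np.asarray([_LABEL_MAP.get(l, l) for l in labels], dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidConfigError("labels must be cancer / no_cancer (1 / 0)")
    return x, y


def _fingerprint(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x[: min(len(x), 64)]).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def new_model(config: TrainConfig) -> TileClassifierModel:
    """An untrained (randomly initialized, seeded) model."""
    if config.architecture != "small_cnn":
        raise InvalidConfigError(
            "inception_v3 requires an external deep-learning backend; "
            "use architecture='small_cnn'"
        )
    rng = np.random.default_rng(config.seed)
    return TileClassifierModel("small_cnn", _init_params(rng), {"config": asdict(config)})


def train(
    train_tiles,
    train_labels,
    val_tiles,
    val_labels,
    config: TrainConfig | None = None,
) -> TileClassifierModel:
    """Train the tile classifier and return the best-validation-epoch model."""
    config = config or TrainConfig.desk_default()
    x_tr, y_tr = _coerce_xy(train_tiles, train_labels)
    x_va, y_va = _coerce_xy(val_tiles, val_labels)
    if len(np.unique(y_tr)) < 2:
        raise DegenerateTrainingError("training set contains a single class")

    model = new_model(config)
    params = model.params
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    weights = None
    if config.balance_classes:
        # inverse-frequency balance times the clinical cost asymmetry:
        # a missed cancer tile costs more than a false alarm
        pos_w = config.positive_cost * float((y_tr == 0).sum()) / float((y_tr == 1).sum())
        weights = np.where(y_tr == 1, pos_w, 1.0)

    best_metric, best_acc, best_epoch, best_params = -1.0, -1.0, -1, None
    history = []
    n = len(x_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            wb = None if weights is None else weights[idx]
            prob, caches = _forward(params, xb, cache=True)
            eps = 1e-12
            bce = -(yb * np.log(prob + eps) + (1 - yb) * np.log(1 - prob + eps))
            losses.append(
                float(np.mean(bce) if wb is None else np.sum(wb * bce) / np.sum(wb))
            )
            grads = _backward(params, caches, prob, yb, wb)
            opt.step(params, grads)
        val_prob = _predict_in_batches(params, x_va)
        pred = val_prob >= 0.5
        val_acc = float(np.mean(pred == y_va))
        n_pos, n_neg = int((y_va == 1).sum()), int((y_va == 0).sum())
        if n_pos and n_neg:
            val_bacc = 0.5 * (
                float((pred & (y_va == 1)).sum()) / n_pos
                + float((~pred & (y_va == 0)).sum()) / n_neg
            )
        else:
            val_bacc = val_acc
        # selection metric matches the training objective: balanced accuracy
        # under class weighting, plain accuracy otherwise
        metric = val_bacc if config.balance_classes else val_acc
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_acc": val_acc,
                "val_balanced_acc": val_bacc,
            }
        )
        if metric > best_metric:  # strict: ties keep the earliest epoch
            best_metric, best_epoch = metric, epoch
            best_acc = val_acc
            best_params = {k: v.copy() for k, v in params.items()}

    model.params = best_params
    model.metadata.update(
        {
            "validation_accuracy": best_acc,
            "validation_metric": best_metric,
            "selection_metric": "balanced_accuracy" if config.balance_classes else "accuracy",
            "best_epoch": best_epoch,
            "history": history,
            "data_fingerprint": _fingerprint(x_tr, y_tr),
        }
    )
    return model


def _predict_in_batches(params: dict, x: np.ndarray, batch: int = 512) -> np.ndarray:
    return np.concatenate(
        [_forward(params, x[i : i + batch]) for i in range(0, len(x), batch)]
    )


def predict(model: TileClassifierModel, tile) -> float:
    """Probability of cancer in [0, 1] for one nonblank standardized tile."""
    if isinstance(tile, Tile):
        if tile.is_blank:
            raise InvalidConfigError("blank tiles are excluded from classification")
        tile = tile.pixels
    return float(model.predict_proba(tile)[0])


def predict_batch(model: TileClassifierModel, tiles) -> np.ndarray:
    """Vectorized :func:`predict` over an array or list of nonblank tiles."""
    if isinstance(tiles, (list, tuple)) and tiles and isinstance(tiles[0], Tile):
        if any(t.is_blank for t in tiles):
            raise InvalidConfigError("blank tiles are excluded from classification")
        tiles = np.stack([t.pixels for t in tiles])
    return _predict_in_batches(model.params, np.asarray(tiles, dtype=np.float64))
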