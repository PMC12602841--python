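"""Trainable age predictors and evaluation utilities.

A compact numpy predictor family stands in for a full-scale imaging network
while honoring the same training contract: MSE loss, Adam (or plain gradient
descent), Xavier initialization, inverse-time learning-rate decay, dropout in
the last hidden layer, and the participant's sex concatenated at the final
dense layer. Three kinds are available:

``linear``
    features (+ sex) -> age, a single dense layer.
``mlp``
    one or more ReLU hidden layers; dropout applied to the last hidden layer
    during training; sex concatenated to the final dense layer's input.
``cnn3d_small``
    one 3x3x3 convolution block (4 filters, ReLU, global average pooling)
    over the generator's 16x16x16 volumes, then the dense head as above.

Each predictor doubles as a federation :class:`~fedbioage.federation.ModelAdapter`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import BRAIN_COLS, VOLUME_SHAPE, VOX_COLS
from .federation import ParamVector

CONV_FILTERS = 4
CONV_KERNEL = 3


@dataclass(frozen=True)
class PredictorConfig:
    kind: str = "linear"  # linear | mlp | cnn3d_small
    feature_cols: tuple[str, ...] = tuple(BRAIN_COLS)
    hidden_sizes: tuple[int, ...] = (16,)
    dropout_last: float = 0.0
    learning_rate: float = 1e-3
    lr_decay: float = 1e-2  # inverse-time decay: lr / (1 + decay * epoch)
    optimizer: str = "adam"  # adam | sgd
    sex_concat: bool = True
    output_bias_init: float = 0.0  # e.g. the pooled mean age, to center the head

    def validate(self) -> None:
        if self.kind not in ("linear", "mlp", "cnn3d_small"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if not 0.0 <= self.dropout_last < 1.0:
            raise ValueError("dropout_last must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class AgePredictor:
    """Numpy implementation of the configurable predictor.

    Parameters live in a flat :class:`ParamVector` whose layout names each
    weight/bias group, so the same vectors flow through the federation engine.
    """

    def __init__(self, config: PredictorConfig):
        config.validate()
        self.config = config
        self._build_layout()

    # ---- layout ---------------------------------------------------------
    def _dense_dims(self) -> list[tuple[int, int]]:
        cfg = self.config
        if cfg.kind == "linear":
            d_in = len(cfg.feature_cols) + (1 if cfg.sex_concat else 0)
            return [(d_in, 1)]
        if cfg.kind == "mlp":
            sizes = [len(cfg.feature_cols), *cfg.hidden_sizes]
        else:  # cnn3d_small: conv block output is one value per filter
            sizes = [CONV_FILTERS, *cfg.hidden_sizes]
        dims = [(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
        dims.append((sizes[-1] + (1 if cfg.sex_concat else 0), 1))
        return dims

    def _build_layout(self) -> None:
        layout: dict[str, tuple[int, int]] = {}
        pos = 0

        def seg(name, size):
            nonlocal pos
            layout[name] = (pos, pos + size)
            pos += size

        if self.config.kind == "cnn3d_small":
            seg("conv_w", CONV_FILTERS * CONV_KERNEL**3)
            seg("conv_b", CONV_FILTERS)
        for i, (d_in, d_out) in enumerate(self._dense_dims()):
            seg(f"W{i}", d_in * d_out)
            seg(f"b{i}", d_out)
        self.layout = layout
        self.n_params = pos

    def init_params(self, seed: int) -> ParamVector:
        rng = np.random.default_rng(seed)
        values = np.zeros(self.n_params)
        pv = ParamVector(values, self.layout)
        if self.config.kind == "cnn3d_small":
            fan_in = CONV_KERNEL**3
            values[slice(*self.layout["conv_w"])] = _xavier(
                rng, fan_in, CONV_FILTERS, CONV_FILTERS * CONV_KERNEL**3
            )
        dims = self._dense_dims()
        for i, (d_in, d_out) in enumerate(dims):
            values[slice(*self.layout[f"W{i}"])] = _xavier(rng, d_in, d_out, d_in * d_out)
        values[slice(*self.layout[f"b{len(dims) - 1}"])] = self.config.output_bias_init
        return pv

    # ---- data access ----------------------------------------------------
    def _inputs(self, data: pd.DataFrame):
        if self.config.kind == "cnn3d_small":
            X = data[VOX_COLS].to_numpy(dtype=float).reshape((len(data),) + VOLUME_SHAPE)
        else:
            X = data[list(self.config.feature_cols)].to_numpy(dtype=float)
        sex = data["sex"].to_numpy(dtype=float) if self.config.sex_concat else None
        y = data["age"].to_numpy(dtype=float)
        return X, sex, y

    # ---- forward / backward ---------------------------------------------
    def _conv_forward(self, params: ParamVector, vol: np.ndarray):
        """3-D valid convolution, ReLU, global average pool -> (n, filters)."""
        k = CONV_KERNEL
        W = params.get("conv_w").reshape(CONV_FILTERS, k, k, k)
        b = params.get("conv_b")
        windows = np.lib.stride_tricks.sliding_window_view(vol, (k, k, k), axis=(1, 2, 3))
        pre = np.einsum("nxyzijk,fijk->nxyzf", windows, W) + b
        act = np.maximum(pre, 0.0)
        pooled = act.mean(axis=(1, 2, 3))
        cache = (windows, pre, act)
        return pooled, cache

    def _forward(self, params: ParamVector, X, sex, dropout_rng=None):
        """Returns predictions and a cache for backprop.

        ``dropout_rng`` enables training-mode dropout on the last hidden layer;
        inference is deterministic (inverted dropout, no rescaling at eval).
        """
        cfg = self.config
        caches: dict = {}
        if cfg.kind == "cnn3d_small":
            h, caches["conv"] = self._conv_forward(params, X)
        else:
            h = X
        dims = self._dense_dims()
        acts = [h]
        for i, (d_in, d_out) in enumerate(dims):
            last = i == len(dims) - 1
            if last:
                if cfg.dropout_last > 0 and dropout_rng is not None:
                    mask = (dropout_rng.random(h.shape) >= cfg.dropout_last) / (1 - cfg.dropout_last)
                    h = h * mask
                    caches["dropout_mask"] = mask
                if cfg.sex_concat:
                    h = np.column_stack([h, sex])
            W = params.get(f"W{i}").reshape(d_in, d_out)
            b = params.get(f"b{i}")
            z = h @ W + b
            if not last:
                h = np.maximum(z, 0.0)
                acts.append(h)
            else:
                caches["head_in"] = h
            caches[f"z{i}"] = z
        caches["acts"] = acts
        return z[:, 0], caches

    def predict(self, params: ParamVector, data: pd.DataFrame) -> np.ndarray:
        X, sex, _ = self._inputs(data)
        pred, _ = self._forward(params, X, sex, dropout_rng=None)
        return pred

    def loss(self, params: ParamVector, data: pd.DataFrame) -> float:
        X, sex, y = self._inputs(data)
        pred, _ = self._forward(params, X, sex)
        return float(np.mean((pred - y) ** 2))

    def val_mae(self, params: ParamVector, data: pd.DataFrame) -> float:
        return mae(self.predict(params, data), data["age"].to_numpy(dtype=float))

    def _gradient(self, params: ParamVector, X, sex, y, dropout_rng=None):
        """MSE gradient d/dtheta mean((pred - y)^2) via backprop."""
        cfg = self.config
        n = y.shape[0]
        pred, caches = self._forward(params, X, sex, dropout_rng=dropout_rng)
        grad = np.zeros(self.n_params)
        dz = (2.0 / n) * (pred - y)[:, None]  # (n, 1)
        dims = self._dense_dims()
        acts = caches["acts"]
        # backward through dense stack
        d_h = None
        for i in reversed(range(len(dims))):
            d_in, d_out = dims[i]
            last = i == len(dims) - 1
            h_in = caches["head_in"] if last else acts[i]
            W = params.get(f"W{i}").reshape(d_in, d_out)
            grad[slice(*self.layout[f"W{i}"])] = (h_in.T @ dz).ravel()
            grad[slice(*self.layout[f"b{i}"])] = dz.sum(axis=0)
            d_h = dz @ W.T
            if last:
                if cfg.sex_concat:
                    d_h = d_h[:, :-1]
                if cfg.dropout_last > 0 and dropout_rng is not None:
                    d_h = d_h * caches["dropout_mask"]
            if i > 0:
                dz = d_h * (caches[f"z{i-1}"] > 0)
        if cfg.kind == "cnn3d_small":
            windows, pre, act = caches["conv"]
            n_pos = np.prod(pre.shape[1:4])
            d_pooled = d_h  # (n, filters)
            d_act = (d_pooled[:, None, None, None, :] / n_pos) * np.ones_like(pre)
            d_pre = d_act * (pre > 0)
            grad[slice(*self.layout["conv_w"])] = np.einsum(
                "nxyzf,nxyzijk->fijk", d_pre, windows
            ).ravel()
            grad[slice(*self.layout["conv_b"])] = d_pre.sum(axis=(0, 1, 2, 3))
        return grad, float(np.mean((pred - y) ** 2))

    # ---- training -------------------------------------------------------
    def train(
        self,
        params: ParamVector,
        data: pd.DataFrame,
        epochs: int,
        batch_size: int | None,
        seed: int = 0,
        val: pd.DataFrame | None = None,
    ) -> tuple[ParamVector, float]:
        """Local training for ``epochs`` passes; returns (new params, last loss).

        ``batch_size = None`` (or >= n) is full batch. Optimizer state is
        local to the call, so every federated round restarts Adam's moments —
        the standard federated-averaging convention. If ``val`` is given, the
        returned parameters are the checkpoint with the lowest validation MSE
        across epochs instead of the final iterate.
        """
        if len(data) == 0:
            raise ValueError("train: empty data")
        cfg = self.config
        rng = np.random.default_rng(seed)
        X, sex, y = self._inputs(data)
        n = len(y)
        theta = params.values.copy()
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        step = 0
        last_loss = self.loss(params, data)
        best_theta, best_val = theta.copy(), np.inf if val is None else self.loss(params, val)
        bs = n if batch_size is None else min(batch_size, n)
        for epoch in range(epochs):
            lr = cfg.learning_rate / (1.0 + cfg.lr_decay * epoch)
            order = rng.permutation(n) if bs < n else np.arange(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                drop_rng = rng if cfg.dropout_last > 0 else None
                g, last_loss = self._gradient(
                    self._pv(theta), X[idx], None if sex is None else sex[idx], y[idx], drop_rng
                )
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError("non-finite gradient during training")
                step += 1
                if cfg.optimizer == "adam":
                    b1, b2, eps = 0.9, 0.999, 1e-8
                    m = b1 * m + (1 - b1) * g
                    v = b2 * v + (1 - b2) * g**2
                    mhat = m / (1 - b1**step)
                    vhat = v / (1 - b2**step)
                    theta = theta - lr * mhat / (np.sqrt(vhat) + eps)
                else:
                    theta = theta - lr * g
            if val is not None:
                val_mse = self.loss(self._pv(theta), val)
                if val_mse < best_val:
                    best_theta, best_val = theta.copy(), val_mse
        if val is not None:
            theta = best_theta
        return self._pv(theta), last_loss

    def _pv(self, values: np.ndarray) -> ParamVector:
        return ParamVector(values, self.layout)


# ---- module-level operations --------------------------------------------


def train_predictor(
    train: pd.DataFrame,
    val: pd.DataFrame,
    config: PredictorConfig,
    epochs: int,
    seed: int = 0,
    batch_size: int | None = 8,
) -> ParamVector:
    """Train on ``train`` and return the checkpoint with lowest validation MSE.

    The model is evaluated on the validation table after every epoch and the
    best-scoring parameter vector is kept, so extra epochs never degrade the
    returned model. Deterministic per seed.
    """
    model = AgePredictor(config)
    params = model.init_params(seed)
    if epochs == 0:
        return params
    params, loss = model.train(params, train, epochs, batch_size, seed=seed + 1, val=val)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    return params


def predict_age(params: ParamVector, table: pd.DataFrame, config: PredictorConfig) -> np.ndarray:
    """Per-row predicted age in years."""
    model = AgePredictor(config)
    if params.layout != model.layout:
        raise ValueError("parameter layout does not match the predictor config")
    return model.predict(params, table)


def mae(pred: np.ndarray, age: np.ndarray) -> float:
    """Mean absolute error in years."""
    pred = np.asarray(pred, dtype=float)
    age = np.asarray(age, dtype=float)
    if pred.shape != age.shape or pred.size == 0:
        raise ValueError("mae: inputs must be equal-length and non-empty")
    return float(np.mean(np.abs(pred - age)))


def bootstrap_ci_mae(
    pred: np.ndarray, age: np.ndarray, resamples: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the MAE, reproducible per seed."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    err = np.abs(np.asarray(pred, dtype=float) - np.asarray(age, dtype=float))
    rng = np.random.default_rng(seed)
    n = err.size
    idx = rng.integers(0, n, size=(resamples, n))
    stats = err[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))


def kfold_cv(table: pd.DataFrame, k: int, trainer, seed: int = 0) -> list[float]:
    """K-fold cross-validated MAEs with folds disjoint by participant_id.

    ``trainer(train_table)`` must return a callable mapping a table to
    predicted ages.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = table["participant_id"].unique()
    if k > len(ids):
        raise ValueError("k exceeds the number of participants")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    maes = []
    for fold in folds:
        fold_ids = set(ids[fold])
        test_mask = table["participant_id"].isin(fold_ids)
        predict_fn = trainer(table.loc[~test_mask])
        test = table.loc[test_mask]
        maes.append(mae(predict_fn(test), test["age"].to_numpy(dtype=float)))
    return maes
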