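"""A compact 1-D convolutional network for spectral regression, in numpy.

Architecture: a stack of (Conv1D -> ReLU -> MaxPool) blocks over the
wavelength axis, flattened into a ReLU dense layer with dropout, and a
linear output head.  Training uses Adam with mean-squared-error loss, L2
weight decay, a step learning-rate schedule, and early stopping on a
held-out validation fraction of the training data with best-weight restore.
All randomness flows from a single seed, so fits are reproducible.

The implementation favors clarity over throughput; spectra matrices in the
hundreds of samples by hundreds of bands train in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CNNSpec", "CNNRegressor"]


@dataclass(frozen=True)
class CNNSpec:
    """Hyperparameters; numeric defaults follow common spectral-CNN practice
    (small two-block stack, Adam 1e-4 with a long step decay, dropout 0.5,
    light L2, patience-20 early stopping)."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 5, 2), (32, 5, 2))
    dense_width: int = 64
    learning_rate: float = 1e-4
    lr_drop_period: int = 600
    lr_drop_factor: float = 0.1
    dropout: float = 0.5
    l2: float = 1e-5
    patience: int = 20
    min_delta: float = 1e-3
    max_epochs: int = 800
    batch_size: int = 32
    val_fraction: float = 0.15
    n_restarts: int = 1   # independent seeded fits; best validation loss wins
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.l2 < 0:
            raise ValueError("learning_rate must be > 0 and l2 >= 0")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        for f, k, pool in self.conv_blocks:
            if f < 1 or k < 1 or pool < 1:
                raise ValueError("conv block (filters, kernel, pool) must be positive")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (n, C, L) -> (n, C*k, L-k+1)
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (n, C, L_out, k)
    n, c, l_out, _ = win.shape
    return win.transpose(0, 1, 3, 2).reshape(n, c * k, l_out)


class _Conv1D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))  # He init for ReLU stacks
        self.W = rng.standard_normal((c_out, c_in * k)) * scale
        self.b = np.zeros(c_out)
        self.k, self.c_in = k, c_in

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        return np.einsum("fk,nkl->nfl", self.W, self._cols) + self.b[None, :, None]

    def backward(self, dout):
        self.dW = np.einsum("nfl,nkl->fk", dout, self._cols)
        self.db = dout.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", self.W, dout)
        n, _, l_out = dcols.shape
        dcols = dcols.reshape(n, self.c_in, self.k, l_out)
        dx = np.zeros(self._x_shape)
        for j in range(self.k):
            dx[:, :, j:j + l_out] += dcols[:, :, j, :]
        return dx

    @property
    def params(self):
        return [("W", True), ("b", False)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [("W", True), ("b", False)]


class _MaxPool:
    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        n, c, l = x.shape
        l_out = l // self.size
        self._in_len = l
        xr = x[:, :, : l_out * self.size].reshape(n, c, l_out, self.size)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dout):
        n, c, l_out = dout.shape
        dx = np.zeros((n, c, self._in_len))
        base = np.arange(l_out) * self.size
        idx = base[None, None, :] + self._arg
        np.put_along_axis(
            dx, idx.reshape(n, c, l_out), dout, axis=2
        )
        return dx


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, layers, l2: float, lr: float):
        self.t += 1
        for li, layer in enumerate(layers):
            if not hasattr(layer, "params"):
                continue
            for name, decay in layer.params:
                g = getattr(layer, "d" + name).copy()
                if decay and l2 > 0:
                    g += 2.0 * l2 * getattr(layer, name)
                key = (li, name)
                self.m[key] = self.b1 * self.m.get(key, 0.0) + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v.get(key, 0.0) + (1 - self.b2) * g**2
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                p = getattr(layer, name)
                setattr(layer, name, p - lr * mhat / (np.sqrt(vhat) + self.eps))


class CNNRegressor:
    """Seeded numpy CNN with the fit/predict contract of a sklearn regressor."""

    def __init__(self, spec: CNNSpec):
        self.spec = spec
        self.history_: dict[str, list[float]] = {"loss": [], "val_loss": [], "lr": []}
        self.stopped_epoch_: int | None = None

    # ---------------- architecture

    def _build(self, n_features: int, rng: np.random.Generator):
        self._convs = []
        self._pools = []
        c, l = 1, n_features
        if l < 2 and self.spec.conv_blocks:
            raise ValueError(f"feature width {l} too narrow for a convolutional stack")
        for f, k, pool in self.spec.conv_blocks:
            k_eff = min(k, l)  # narrow feature subsets: shrink kernel, keep block
            self._convs.append(_Conv1D(c, f, k_eff, rng))
            l = l - k_eff + 1
            if l >= pool * 2:
                self._pools.append(_MaxPool(pool))
                l = l // pool
            else:
                self._pools.append(_MaxPool(1))
            c = f
        self._flat_dim = c * l
        if self.spec.dense_width > 0:
            self._hidden = _Dense(self._flat_dim, self.spec.dense_width, rng)
            self._out = _Dense(self.spec.dense_width, 1, rng)
        else:
            self._hidden = None
            self._out = _Dense(self._flat_dim, 1, rng)

    def _layers(self):
        layers = list(self._convs)
        if self._hidden is not None:
            layers.append(self._hidden)
        layers.append(self._out)
        return layers

    def _forward(self, x2d, rng=None):
        """x2d: (n, p) standardized. rng enables dropout (training mode)."""
        h = x2d[:, None, :]
        self._relu_masks = []
        for conv, pool in zip(self._convs, self._pools):
            h = conv.forward(h)
            mask = h > 0
            self._relu_masks.append(mask)
            h = h * mask
            h = pool.forward(h)
        n = h.shape[0]
        self._pre_flat_shape = h.shape
        h = h.reshape(n, -1)
        if self._hidden is not None:
            h = self._hidden.forward(h)
            self._hidden_mask = h > 0
            h = h * self._hidden_mask
            if rng is not None and self.spec.dropout > 0:
                keep = 1.0 - self.spec.dropout
                self._drop_mask = (rng.uniform(size=h.shape) < keep) / keep
                h = h * self._drop_mask
            else:
                self._drop_mask = None
        return self._out.forward(h).ravel()

    def _backward(self, dloss):
        d = self._out.backward(dloss[:, None])
        if self._hidden is not None:
            if self._drop_mask is not None:
                d = d * self._drop_mask
            d = d * self._hidden_mask
            d = self._hidden.backward(d)
        d = d.reshape(self._pre_flat_shape)
        for conv, pool, mask in zip(
            reversed(self._convs), reversed(self._pools), reversed(self._relu_masks)
        ):
            d = pool.backward(d)
            d = d * mask
            d = conv.backward(d)

    # ---------------- training

    def fit(self, X, y):
        """Fit with ``n_restarts`` independent initializations, keeping the
        restart whose best validation loss is lowest."""
        spec = self.spec
        if spec.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        best = None
        for k in range(spec.n_restarts):
            trial = CNNRegressor(
                spec if spec.n_restarts == 1 else
                replace(spec, n_restarts=1, seed=(spec.seed + 1000003 * k) % 2**31)
            )
            trial._fit_single(X, y)
            score = min(trial.history_["val_loss"])
            if best is None or score < best[0]:
                best = (score, trial)
        chosen = best[1]
        self.__dict__.update(chosen.__dict__)
        self.spec = spec
        return self

    def _fit_single(self, X, y):
        spec = self.spec
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise FloatingPointError("non-finite values in training data")
        rng = np.random.default_rng(spec.seed)
        self._x_mean = X.mean(0)
        sd = X.std(0)
        self._x_sd = np.where(sd > 0, sd, 1.0)
        self._y_mean = y.mean()
        self._y_sd = y.std() if y.std() > 0 else 1.0
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd

        n = X.shape[0]
        n_val = max(1, int(round(spec.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size < 2:
            raise ValueError("too few samples after validation split")
        Xtr, ytr = Xs[tr_idx], ys[tr_idx]
        Xval, yval = Xs[val_idx], ys[val_idx]

        self._build(X.shape[1], rng)
        opt = _Adam(spec.learning_rate)
        best_val = np.inf
        best_state = None
        wait = 0
        for epoch in range(spec.max_epochs):
            lr = spec.learning_rate * spec.lr_drop_factor ** (epoch // spec.lr_drop_period)
            order = rng.permutation(tr_idx.size)
            epoch_loss = 0.0
            for start in range(0, tr_idx.size, spec.batch_size):
                batch = order[start:start + spec.batch_size]
                pred = self._forward(Xtr[batch], rng=rng)
                err = pred - ytr[batch]
                if not np.all(np.isfinite(err)):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce learning rate or check inputs"
                    )
                epoch_loss += float((err**2).sum())
                self._backward(2.0 * err / batch.size)
                opt.step(self._layers(), spec.l2, lr)
            val_pred = self._forward(Xval)
            val_loss = float(np.mean((val_pred - yval) ** 2))
            self.history_["loss"].append(epoch_loss / tr_idx.size)
            self.history_["val_loss"].append(val_loss)
            self.history_["lr"].append(lr)
            if best_val - val_loss > spec.min_delta:
                best_val = val_loss
                best_state = self._snapshot()
                wait = 0
            else:
                wait += 1
                if wait >= spec.patience:
                    self.stopped_epoch_ = epoch
                    break
        if best_state is not None:
            self._restore(best_state)
        self.n_features_in_ = X.shape[1]
        return self

    def _snapshot(self):
        return [
            {name: getattr(layer, name).copy() for name, _ in layer.params}
            for layer in self._layers()
        ]

    def _restore(self, state):
        for layer, saved in zip(self._layers(), state):
            for name, arr in saved.items():
                setattr(layer, name, arr.copy())

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        Xs = (X - self._x_mean) / self._x_sd
        pred = self._forward(Xs)  # inference mode: no dropout
        return pred * self._y_sd + self._y_mean
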