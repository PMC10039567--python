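"""A compact 1-D convolutional network regressor on fingerprint vectors.

The fingerprint bit vector is treated as a single-channel 1-D signal.
Two strided convolution layers extract local bit-pattern features; the
resulting feature map is flattened — *not* globally pooled — and a small
dense head produces the wavelength.  Position must be preserved because
hashed fingerprint bits are position-coded: a translation-invariant
readout (global pooling) cannot tell two isolated set bits apart and
degenerates to popcount statistics.  Implemented directly on NumPy
(im2col convolutions as BLAS matmuls, Adam, early stopping on a held-out
validation split), so CPU training on datasets of a few thousand
records is practical.

Architecture (defaults): conv(32 filters, kernel 7, stride 2) - ReLU -
conv(64, kernel 7, stride 2) - ReLU - flatten - dense 128 - ReLU -
linear output.  Loss is the mean squared error on z-scored targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["CNNRegressor"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CNNRegressor(BaseEstimator, RegressorMixin):
    """1-D CNN regression on a fixed-length numeric vector.

    Parameters
    ----------
    channels : (int, int)
        Filters in the two convolution layers.
    kernel_size, stride : int
        Shared by both convolution layers.
    dense_units : int
        Width of the dense layer before the linear output.
    epochs, batch_size, lr : training schedule (Adam).
    val_fraction : float
        Fraction of the training rows held out for early stopping.
    patience : int
        Epochs without validation improvement before stopping.
    random_state : int
        Seeds initialization, shuffling and the validation split.
    """

    def __init__(
        self,
        channels: tuple[int, int] = (32, 64),
        kernel_size: int = 7,
        stride: int = 2,
        dense_units: int = 128,
        epochs: int = 60,
        batch_size: int = 32,
        lr: float = 1e-3,
        val_fraction: float = 0.1,
        patience: int = 8,
        random_state: int = 0,
    ):
        self.channels = channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    # ---------------- internals

    def _windows(self, length: int) -> np.ndarray:
        n_out = (length - self.kernel_size) // self.stride + 1
        if n_out < 1:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel_size}"
            )
        return n_out

    def _forward(self, X: np.ndarray, keep: bool = False):
        # BLAS-friendly: windows flattened to 2-D and pushed through matmul.
        k, s = self.kernel_size, self.stride
        c1, c2 = self.channels
        n = X.shape[0]
        X_col = np.ascontiguousarray(sliding_window_view(X, k, axis=1)[:, ::s, :])
        W1len = X_col.shape[1]
        z1 = X_col.reshape(n * W1len, k) @ self.W1_.T  # (n*W1, c1)
        z1 = z1.reshape(n, W1len, c1) + self.b1_
        a1 = _relu(z1)
        A_col = sliding_window_view(a1, k, axis=1)[:, ::s]  # (n, W2, c1, k)
        A_col = np.ascontiguousarray(np.swapaxes(A_col, 2, 3))  # (n, W2, k, c1)
        W2len = A_col.shape[1]
        z2 = A_col.reshape(n * W2len, k * c1) @ self.W2_.reshape(c2, k * c1).T
        z2 = z2.reshape(n, W2len, c2) + self.b2_
        a2 = _relu(z2)
        g = a2.reshape(n, W2len * c2)  # flatten, position preserved
        zd = g @ self.Wd_ + self.bd_
        h = _relu(zd)
        out = (h @ self.Wo_ + self.bo_).ravel()
        if keep:
            return out, (X_col, z1, a1, A_col, z2, g, zd, h)
        return out

    def _backward(self, cache, dout: np.ndarray) -> list[np.ndarray]:
        X_col, z1, a1, A_col, z2, g, zd, h = cache
        n = dout.shape[0]
        k, s = self.kernel_size, self.stride
        c1, c2 = self.channels
        W1len, W2len = z1.shape[1], z2.shape[1]
        dout = dout.astype(np.float32)
        dWo = h.T @ dout[:, None]
        dbo = dout.sum(keepdims=True)
        dh = dout[:, None] @ self.Wo_.T
        dzd = dh * (zd > 0)
        dWd = g.T @ dzd
        dbd = dzd.sum(axis=0)
        dg = dzd @ self.Wd_.T
        dz2 = dg.reshape(n, W2len, c2) * (z2 > 0)
        dz2f = dz2.reshape(n * W2len, c2)
        A_colf = A_col.reshape(n * W2len, k * c1)
        dW2 = (dz2f.T @ A_colf).reshape(c2, k, c1)
        db2 = dz2f.sum(axis=0)
        dA_col = (dz2f @ self.W2_.reshape(c2, k * c1)).reshape(n, W2len, k, c1)
        # scatter window gradients back onto conv1 activations; for a fixed
        # in-window offset j the target positions j, j+s, ... are distinct,
        # so a fancy-indexed += is safe.
        da1 = np.zeros_like(a1)
        pos = s * np.arange(W2len)
        for j in range(k):
            da1[:, pos + j, :] += dA_col[:, :, j, :]
        dz1 = da1 * (z1 > 0)
        dW1 = dz1.reshape(n * W1len, c1).T @ X_col.reshape(n * W1len, k)
        db1 = dz1.reshape(n * W1len, c1).sum(axis=0)
        return [grad / n for grad in (dW1, db1, dW2, db2, dWd, dbd, dWo, dbo)]

    def _params(self) -> list[np.ndarray]:
        return [self.W1_, self.b1_, self.W2_, self.b2_, self.Wd_, self.bd_, self.Wo_, self.bo_]

    # ---------------- API

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, L = X.shape
        rng = np.random.default_rng(self.random_state)
        k = self.kernel_size
        c1, c2 = self.channels
        W1len = self._windows(L)
        W2len = self._windows(W1len)

        self.y_mean_, self.y_std_ = y.mean(), y.std()
        if self.y_std_ == 0:
            self.y_std_ = 1.0
        yz = (y - self.y_mean_) / self.y_std_

        # He initialization, float32 throughout
        f32 = np.float32
        self.W1_ = rng.normal(0, np.sqrt(2.0 / k), (c1, k)).astype(f32)
        self.b1_ = np.zeros(c1, dtype=f32)
        self.W2_ = rng.normal(0, np.sqrt(2.0 / (k * c1)), (c2, k, c1)).astype(f32)
        self.b2_ = np.zeros(c2, dtype=f32)
        flat = W2len * c2
        self.Wd_ = rng.normal(0, np.sqrt(2.0 / flat), (flat, self.dense_units)).astype(f32)
        self.bd_ = np.zeros(self.dense_units, dtype=f32)
        self.Wo_ = rng.normal(0, np.sqrt(2.0 / self.dense_units), (self.dense_units, 1)).astype(f32)
        self.bo_ = np.zeros(1, dtype=f32)

        # validation split for early stopping
        perm = rng.permutation(n)
        n_val = int(round(n * self.val_fraction))
        n_val = min(max(n_val, 1 if n >= 20 else 0), n - 1)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], yz[tr_idx]
        Xval, yval = X[val_idx], yz[val_idx]

        opt = _Adam(self._params(), self.lr)
        best_val = np.inf
        best = [p.copy() for p in self._params()]
        stale = 0
        for _ in range(self.epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                b = order[start : start + self.batch_size]
                out, cache = self._forward(Xtr[b], keep=True)
                dout = 2.0 * (out - ytr[b])
                grads = self._backward(cache, dout)
                opt.step(self._params(), grads)
            if len(Xval):
                val_mse = float(np.mean((self._forward(Xval) - yval) ** 2))
            else:
                val_mse = float(np.mean((self._forward(Xtr) - ytr) ** 2))
            if val_mse < best_val - 1e-6:
                best_val = val_mse
                best = [p.copy() for p in self._params()]
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.W1_, self.b1_, self.W2_, self.b2_, self.Wd_, self.bd_, self.Wo_, self.bo_ = best
        self.n_features_in_ = L
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        outs = []
        for start in range(0, X.shape[0], 256):
            outs.append(self._forward(X[start : start + 256]))
        return np.concatenate(outs) * self.y_std_ + self.y_mean_
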