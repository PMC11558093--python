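"""Compact numpy neural regressors: 1-D CNN and LSTM.

Both treat the per-array gene-expression vector as a 1-D sequence ordered by
genome coordinate.  The CNN applies valid 1-D convolutions with ReLU and
global average pooling; the LSTM consumes the vector as chunked
subsequences and regresses on the final hidden state.  Training is
full-batch Adam on mean-squared error, with the target standardized
internally; all initialization is drawn from a seeded generator so fits are
deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNNRegressor", "LSTMRegressor"]


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class CNNRegressor:
    """1-D convolution → ReLU → global average pool → linear head.

    A position-wise linear skip path feeds the input directly into the head
    (a 1×1-style residual), so position-specific signals are not lost to the
    pooling average."""

    def __init__(self, n_filters: int = 8, kernel_size: int = 5,
                 lr: float = 1e-2, epochs: int = 60, seed: int = 0):
        self.n_filters = int(n_filters)
        self.kernel_size = int(kernel_size)
        self.lr = float(lr)
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.loss_history_: list[float] = []

    def _init(self, n_features: int):
        rng = np.random.default_rng(self.seed)
        k, w = self.n_filters, min(self.kernel_size, n_features)
        self.kernel_size_ = w
        scale = 1.0 / np.sqrt(w)
        self.params_ = {
            "W": rng.normal(0, scale, size=(k, w)),
            "b": np.zeros(k),
            "v": rng.normal(0, 1.0 / np.sqrt(k), size=k),
            "u": np.zeros(n_features),  # linear skip path
            "c": np.zeros(1),
        }

    def _forward(self, X):
        P = self.params_
        windows = np.lib.stride_tricks.sliding_window_view(
            X, self.kernel_size_, axis=1
        )  # (n, Pw, w)
        z = windows @ P["W"].T + P["b"]  # (n, Pw, k)
        a = np.maximum(z, 0.0)
        pooled = a.mean(axis=1)  # (n, k)
        yhat = pooled @ P["v"] + X @ P["u"] + P["c"][0]
        return yhat, (windows, z, pooled)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.y_mean_, self.y_std_ = y.mean(), max(y.std(), 1e-12)
        t = (y - self.y_mean_) / self.y_std_
        self._init(X.shape[1])
        opt = _Adam(self.params_, self.lr)
        self.loss_history_ = []
        n = X.shape[0]
        for _ in range(self.epochs):
            yhat, (windows, z, pooled) = self._forward(X)
            resid = yhat - t
            self.loss_history_.append(float(np.mean(resid**2)))
            d_yhat = 2.0 * resid / n
            grads = {
                "v": pooled.T @ d_yhat,
                "u": X.T @ d_yhat,
                "c": np.array([d_yhat.sum()]),
            }
            dp = np.outer(d_yhat, self.params_["v"])  # (n, k)
            da = dp[:, None, :] / z.shape[1]
            dz = da * (z > 0)
            grads["W"] = np.einsum("npk,npw->kw", dz, windows)
            grads["b"] = dz.sum(axis=(0, 1))
            opt.step(self.params_, grads)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        yhat, _ = self._forward(X)
        return yhat * self.y_std_ + self.y_mean_


class LSTMRegressor:
    """Chunked-sequence LSTM with a linear head on the final hidden state.

    As in the CNN, a position-wise linear skip path feeds the (unchunked)
    input straight into the head alongside the recurrent summary."""

    def __init__(self, hidden_size: int = 16, chunk_size: int = 16,
                 lr: float = 1e-2, epochs: int = 60, seed: int = 0):
        self.hidden_size = int(hidden_size)
        self.chunk_size = int(chunk_size)
        self.lr = float(lr)
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.loss_history_: list[float] = []

    def _chunk(self, X):
        n, F = X.shape
        d = min(self.chunk_size, F)
        T = int(np.ceil(F / d))
        pad = T * d - F
        if pad:
            X = np.concatenate([X, np.zeros((n, pad))], axis=1)
        return X.reshape(n, T, d)

    def _init(self, d: int, n_features: int):
        rng = np.random.default_rng(self.seed)
        H = self.hidden_size
        self.params_ = {
            "Wx": rng.normal(0, 1.0 / np.sqrt(d), size=(4 * H, d)),
            "Wh": rng.normal(0, 1.0 / np.sqrt(H), size=(4 * H, H)),
            "b": np.zeros(4 * H),
            "v": rng.normal(0, 1.0 / np.sqrt(H), size=H),
            "u": np.zeros(n_features),  # linear skip path
            "c": np.zeros(1),
        }
        # forget-gate bias starts positive (standard recipe)
        self.params_["b"][H : 2 * H] = 1.0

    def _forward(self, Xc, X):
        P = self.params_
        n, T, d = Xc.shape
        H = self.hidden_size
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        for t in range(T):
            z = Xc[:, t] @ P["Wx"].T + h @ P["Wh"].T + P["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            o = _sigmoid(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((h, c, i, f, o, g, tanh_c))
            h, c = h_new, c_new
        yhat = h @ P["v"] + X @ P["u"] + P["c"][0]
        return yhat, h, cache

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.y_mean_, self.y_std_ = y.mean(), max(y.std(), 1e-12)
        t_target = (y - self.y_mean_) / self.y_std_
        Xc = self._chunk(X)
        n, T, d = Xc.shape
        self._init(d, X.shape[1])
        H = self.hidden_size
        opt = _Adam(self.params_, self.lr)
        self.loss_history_ = []
        for _ in range(self.epochs):
            P = self.params_
            yhat, h_last, cache = self._forward(Xc, X)
            resid = yhat - t_target
            self.loss_history_.append(float(np.mean(resid**2)))
            d_yhat = 2.0 * resid / n
            grads = {k: np.zeros_like(v) for k, v in P.items()}
            grads["v"] = h_last.T @ d_yhat
            grads["u"] = X.T @ d_yhat
            grads["c"] = np.array([d_yhat.sum()])
            dh = np.outer(d_yhat, P["v"])
            dc = np.zeros((n, H))
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, o, g, tanh_c = cache[t]
                do = dh * tanh_c
                dc = dc + dh * o * (1 - tanh_c**2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        do * o * (1 - o),
                        dg * (1 - g**2),
                    ],
                    axis=1,
                )
                grads["Wx"] += dz.T @ Xc[:, t]
                grads["Wh"] += dz.T @ h_prev
                grads["b"] += dz.sum(axis=0)
                dh = dz @ P["Wh"]
                dc = dc * f
            opt.step(P, grads)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        yhat, _, _ = self._forward(self._chunk(X), X)
        return yhat * self.y_std_ + self.y_mean_
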