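"""Minimal NumPy neural-network core used by the sequence model.

Implements exactly the pieces the hybrid convolutional/recurrent PSI
predictor needs — 1-D convolution (same padding), ReLU, max pooling, a GRU
scanned over positions with full backpropagation through time, dense
layers, a sigmoid/BCE head and Adam — with hand-written forward/backward
passes.  Arrays are (batch, length, channels) float32.  Layers cache their
forward activations, so forward/backward pairs must be called sequentially
on the same instance.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class Layer:
    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution; width must be odd."""

    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        if width % 2 == 0:
            raise ValueError("conv width must be odd")
        self.width, self.c_in, self.c_out = width, c_in, c_out
        scale = np.sqrt(2.0 / (width * c_in))
        self.W = rng.normal(0.0, scale, size=(width * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, xp, L):
        cols = np.stack([xp[:, k : k + L, :] for k in range(self.width)], axis=2)
        return cols.reshape(xp.shape[0], L, self.width * self.c_in)

    def forward(self, x):
        B, L, _ = x.shape
        p = (self.width - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._cols, self._shape = self._im2col(xp, L), (B, L, p)
        return self._cols @ self.W + self.b

    def backward(self, dy):
        B, L, p = self._shape
        self.dW += self._cols.reshape(-1, self.W.shape[0]).T @ dy.reshape(-1, self.c_out)
        self.db += dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.T).reshape(B, L, self.width, self.c_in)
        dxp = np.zeros((B, L + 2 * p, self.c_in), dtype=dy.dtype)
        for k in range(self.width):
            dxp[:, k : k + L, :] += dcols[:, :, k, :]
        return dxp[:, p : p + L, :]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = pool); trailing remainder dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x):
        B, L, C = x.shape
        Lp = L // self.pool
        xr = x[:, : Lp * self.pool, :].reshape(B, Lp, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._shape = (B, L, C)
        return xr.max(axis=2)

    def backward(self, dy):
        B, L, C = self._shape
        Lp = dy.shape[1]
        dxr = np.zeros((B, Lp, self.pool, C), dtype=dy.dtype)
        bi, li, ci = np.ogrid[:B, :Lp, :C]
        dxr[bi, li, self._arg, ci] = dy
        dx = np.zeros((B, L, C), dtype=dy.dtype)
        dx[:, : Lp * self.pool, :] = dxr.reshape(B, Lp * self.pool, C)
        return dx


class GRU(Layer):
    """GRU scanned over the length axis; returns all hidden states (B, L, H)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.c_in, self.H = c_in, hidden
        sx = np.sqrt(1.0 / c_in)
        sh = np.sqrt(1.0 / hidden)
        self.Wx = rng.normal(0.0, sx, size=(c_in, 3 * hidden)).astype(np.float32)
        self.Uh = rng.normal(0.0, sh, size=(hidden, 3 * hidden)).astype(np.float32)
        self.bx = np.zeros(3 * hidden, dtype=np.float32)
        self.dWx = np.zeros_like(self.Wx)
        self.dUh = np.zeros_like(self.Uh)
        self.dbx = np.zeros_like(self.bx)

    def params(self):
        return [(self.Wx, self.dWx), (self.Uh, self.dUh), (self.bx, self.dbx)]

    def forward(self, x):
        B, L, _ = x.shape
        H = self.H
        self._x = x
        Xp = x @ self.Wx + self.bx  # (B, L, 3H)
        h = np.zeros((B, H), dtype=x.dtype)
        zs, rs, ns, hs = [], [], [], []
        Uz, Ur, Un = self.Uh[:, :H], self.Uh[:, H : 2 * H], self.Uh[:, 2 * H :]
        out = np.empty((B, L, H), dtype=x.dtype)
        for t in range(L):
            hs.append(h)
            z = sigmoid(Xp[:, t, :H] + h @ Uz)
            r = sigmoid(Xp[:, t, H : 2 * H] + h @ Ur)
            n = np.tanh(Xp[:, t, 2 * H :] + (r * h) @ Un)
            h = (1 - z) * n + z * h
            out[:, t] = h
            zs.append(z)
            rs.append(r)
            ns.append(n)
        self._cache = (zs, rs, ns, hs, L)
        return out

    def backward(self, dH):
        zs, rs, ns, hs, L = self._cache
        B, _L, H = dH.shape
        Uz, Ur, Un = self.Uh[:, :H], self.Uh[:, H : 2 * H], self.Uh[:, 2 * H :]
        dXp = np.zeros((B, L, 3 * H), dtype=dH.dtype)
        dUz = np.zeros_like(Uz)
        dUr = np.zeros_like(Ur)
        dUn = np.zeros_like(Un)
        dh = np.zeros((B, H), dtype=dH.dtype)
        for t in range(L - 1, -1, -1):
            z, r, n, h_prev = zs[t], rs[t], ns[t], hs[t]
            dh = dh + dH[:, t]
            dz = dh * (h_prev - n)
            dn = dh * (1 - z)
            dh_prev = dh * z
            da_n = dn * (1 - n * n)
            dXp[:, t, 2 * H :] = da_n
            dUn += (r * h_prev).T @ da_n
            drh = da_n @ Un.T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            da_z = dz * z * (1 - z)
            dXp[:, t, :H] = da_z
            dUz += h_prev.T @ da_z
            dh_prev = dh_prev + da_z @ Uz.T
            da_r = dr * r * (1 - r)
            dXp[:, t, H : 2 * H] = da_r
            dUr += h_prev.T @ da_r
            dh_prev = dh_prev + da_r @ Ur.T
            dh = dh_prev
        self.dUh += np.concatenate([dUz, dUr, dUn], axis=1)
        self.dWx += self._x.reshape(-1, self.c_in).T @ dXp.reshape(-1, 3 * H)
        self.dbx += dXp.sum(axis=(0, 1))
        return dXp @ self.Wx.T


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> tuple:
    """Binary cross-entropy with continuous targets.

    Returns (mean loss, gradient w.r.t. the pre-sigmoid logit) — the usual
    (p - y)/n shortcut.
    """
    p = np.clip(p, eps, 1 - eps)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    dlogit = (p - y) / len(y)
    return loss, dlogit


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _g in self.params]
        self.v = [np.zeros_like(w) for w, _g in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (w, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _w, g in self.params:
            g[...] = 0.0


class SGD:
    def __init__(self, params, lr=0.005):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for w, g in self.params:
            w -= self.lr * g

    def zero_grad(self):
        for _w, g in self.params:
            g[...] = 0.0
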