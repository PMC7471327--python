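"""Minimal NumPy neural-network core: temporal convolution blocks, dense
layers, the BP-MLL pairwise ranking loss, and the Adam optimizer.

Everything is float64-agnostic (arrays keep the caller's dtype, float32 by
default in the models), fully seeded, and exposes explicit
``forward``/``backward`` passes so the pairwise multi-label loss can drive
training without an autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def same_pad_widths(s: int) -> tuple[int, int]:
    """Zero-padding (left, right) for a length-``s`` kernel with "same"
    output length; for even ``s`` the extra pad element goes at the end."""
    left = (s - 1) // 2
    return left, s - 1 - left


class ConvSumPool:
    """One kernel-size branch of a temporal block.

    ``n_filters`` 1D convolutions span ``s`` time steps and all ``d``
    feature columns ("same" zero padding), pass through tanh, are pooled
    over non-overlapping windows of 2 time steps (max or average), and the
    pooled filter outputs are summed elementwise into a single
    ``t/2``-vector.
    """

    def __init__(self, s: int, d: int, n_filters: int, pool: str,
                 rng: np.random.Generator, activation: str = "tanh"):
        if pool not in ("max", "avg"):
            raise ValueError(f"pool must be 'max' or 'avg', got {pool!r}")
        self.s, self.d, self.n_filters, self.pool = s, d, n_filters, pool
        self.activation = activation
        self.W = glorot_uniform(rng, s * d, n_filters, (s * d, n_filters))
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        N, t, d = X.shape
        if d != self.d:
            raise ValueError(f"expected {self.d} feature columns, got {d}")
        if t % 2:
            raise ValueError("time length must be even for 2x1 pooling")
        left, right = same_pad_widths(self.s)
        Xp = np.pad(X, ((0, 0), (left, right), (0, 0)))
        # patches[n, i, c, j] = Xp[n, i + j, c]
        patches = sliding_window_view(Xp, self.s, axis=1)
        patches = patches.reshape(N, t, d * self.s)
        Z = patches @ self.W + self.b                     # (N, t, nf)
        A = np.tanh(Z) if self.activation == "tanh" else Z
        Ar = A.reshape(N, t // 2, 2, self.n_filters)
        if self.pool == "max":
            amax = Ar.argmax(axis=2)                      # (N, t/2, nf)
            pooled = np.take_along_axis(Ar, amax[:, :, None, :], axis=2)[:, :, 0, :]
        else:
            amax = None
            pooled = Ar.mean(axis=2)
        out = pooled.sum(axis=2)                          # (N, t/2)
        self._cache = (patches, A, amax, X.shape)
        return out

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        patches, A, amax, x_shape = self._cache
        N, t, d = x_shape
        g_pooled = np.broadcast_to(
            g_out[:, :, None], (N, t // 2, self.n_filters))
        dAr = np.zeros((N, t // 2, 2, self.n_filters), dtype=A.dtype)
        if self.pool == "max":
            np.put_along_axis(dAr, amax[:, :, None, :],
                              g_pooled[:, :, None, :], axis=2)
        else:
            dAr += g_pooled[:, :, None, :] / 2.0
        dA = dAr.reshape(N, t, self.n_filters)
        dZ = dA * (1.0 - A * A) if self.activation == "tanh" else dA
        self.grads[0][...] = (
            patches.reshape(N * t, -1).T @ dZ.reshape(N * t, -1))
        self.grads[1][...] = dZ.sum(axis=(0, 1))
        dpatch = (dZ @ self.W.T).reshape(N, t, d, self.s)
        left, right = same_pad_widths(self.s)
        dXp = np.zeros((N, t + self.s - 1, d), dtype=A.dtype)
        for j in range(self.s):
            dXp[:, j:j + t, :] += dpatch[:, :, :, j]
        return dXp[:, left:left + t, :]


class Dense:
    """Fully connected layer with optional tanh activation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = "tanh"):
        self.activation = activation
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z = X @ self.W + self.b
        A = np.tanh(Z) if self.activation == "tanh" else Z
        self._cache = (X, A)
        return A

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        X, A = self._cache
        dZ = g_out * (1.0 - A * A) if self.activation == "tanh" else g_out
        self.grads[0][...] = X.T @ dZ
        self.grads[1][...] = dZ.sum(axis=0)
        return dZ @ self.W.T


def bpmll_loss(c: np.ndarray, y: np.ndarray) -> float:
    """Pairwise exponential ranking loss for multi-label outputs.

    For one sample with relevant set ``Y`` and irrelevant set ``Ybar``::

        loss = (1 / (|Y| * |Ybar|)) * sum_{k in Y} sum_{l in Ybar}
               exp(-(c_k - c_l))

    For a batch, the mean over samples with both sets non-empty; samples
    with an all-ones (or all-zeros) label vector carry no ranking
    information and are excluded.
    """
    loss, _, _ = bpmll_loss_grad(np.atleast_2d(c), np.atleast_2d(y))
    return loss


def bpmll_loss_grad(
    C: np.ndarray, Y: np.ndarray
) -> tuple[float, np.ndarray, int]:
    """Batch BP-MLL loss, its gradient w.r.t. ``C``, and the number of
    samples excluded for having no (relevant, irrelevant) label pairs."""
    C = np.asarray(C, dtype=np.float64)
    pos = np.asarray(Y, dtype=np.float64)
    neg = 1.0 - pos
    n_pos = pos.sum(axis=1)
    n_neg = neg.sum(axis=1)
    include = (n_pos > 0) & (n_neg > 0)
    n_excluded = int((~include).sum())
    n_inc = int(include.sum())
    grad = np.zeros_like(C)
    if n_inc == 0:
        return 0.0, grad, n_excluded

    Ci, pi, ni = C[include], pos[include], neg[include]
    sz = (n_pos[include] * n_neg[include])
    # M[n, k, l] = exp(-(c_k - c_l))
    M = np.exp(Ci[:, None, :] - Ci[:, :, None])
    pair = pi[:, :, None] * ni[:, None, :]
    per_sample = (M * pair).sum(axis=(1, 2)) / sz
    loss = float(per_sample.mean())

    # d loss_n / d c_j = (1/sz) * (neg_j * sum_k pos_k M[k,j]
    #                              - pos_j * sum_l neg_l M[j,l])
    as_neg = np.einsum("nk,nkj->nj", pi, M) * ni
    as_pos = np.einsum("nl,njl->nj", ni, M) * pi
    g = (as_neg - as_pos) / sz[:, None] / n_inc
    grad[include] = g
    return loss, grad, n_excluded


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)
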