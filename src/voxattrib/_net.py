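"""Minimal 3D convolutional network in numpy with exact manual backprop.

Written by hand because the attribution method needs d(output)/d(input) at
arbitrary interpolated inputs, and training needs weight gradients — both are
implemented as the reverse pass of an im2col convolution stack.  Compute is
dominated by BLAS matmuls, so a desk-scale net trains in minutes on one CPU.

Parameters are stored in float32; the forward/backward pass runs in the dtype
of the input array, so float64 inputs yield float64 gradients (used where
quadrature diagnostics need tight arithmetic).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv3D:
    """3^3 convolution with padding 1 and configurable stride."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator, k: int = 3):
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        fan_in = c_in * k ** 3
        self.W = (rng.standard_normal((fan_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        B, C, D, H, Wd = x.shape
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]
        Do, Ho, Wo = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(B * Do * Ho * Wo, C * k ** 3)
        out = cols @ self.W.astype(x.dtype) + self.b.astype(x.dtype)
        self._cache = (cols, x.shape, (Do, Ho, Wo), x.dtype)
        return out.reshape(B, Do, Ho, Wo, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        cols, x_shape, (Do, Ho, Wo), dtype = self._cache
        k, s = self.k, self.stride
        B, C, D, H, Wd = x_shape
        dcols_flat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        if need_param_grads:
            self.dW[...] = (cols.T @ dcols_flat).astype(np.float32)
            self.db[...] = dcols_flat.sum(axis=0).astype(np.float32)
        dcols = (dcols_flat @ self.W.astype(dtype).T).reshape(
            B, Do, Ho, Wo, C, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        p = (k - 1) // 2
        dxp = np.zeros((B, C, D + 2 * p, H + 2 * p, Wd + 2 * p), dtype=dtype)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    dxp[:, :, a:a + s * Do:s, bb:bb + s * Ho:s, c:c + s * Wo:s] \
                        += dcols[:, :, :, :, :, a, bb, c]
        return dxp[:, :, p:p + D, p:p + H, p:p + Wd]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        return dout * self._mask


class Softplus:
    """softplus_b(x) = log(1 + exp(b x)) / b — a smooth rectifier.

    With sharpness b=4 it tracks ReLU closely while keeping the network C^1
    in its input, so the attribution path integral converges quadratically
    in the number of quadrature steps instead of the O(1/n) of a piecewise
    linear net.
    """

    def __init__(self, beta: float = 4.0):
        self.beta = beta
        self._sig = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        bx = self.beta * x
        e = np.exp(-np.abs(bx))
        out = (np.maximum(bx, 0) + np.log1p(e)) / self.beta
        self._sig = np.where(bx >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        return out

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        return dout * self._sig


class BatchNorm:
    """Per-channel batch normalization for (B, C, ...) activations.

    Training mode normalizes by batch statistics and tracks running moments;
    evaluation mode (used for scoring and attribution) is a fixed affine map,
    so outputs and input-gradients are deterministic.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.training = False
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma),
                ("beta", self.beta, self.dbeta)]

    def state(self):
        return [("running_mean", self.running_mean),
                ("running_var", self.running_var)]

    def _expand(self, v: np.ndarray, ndim: int, dtype) -> np.ndarray:
        shape = (1, -1) + (1,) * (ndim - 2)
        return v.astype(dtype).reshape(shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim, x.dtype)) \
            * self._expand(inv, x.ndim, x.dtype)
        self._cache = (xhat, inv, axes, x.dtype)
        return self._expand(self.gamma, x.ndim, x.dtype) * xhat \
            + self._expand(self.beta, x.ndim, x.dtype)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        xhat, inv, axes, dtype = self._cache
        if need_param_grads:
            self.dgamma[...] = (dout * xhat).sum(axis=axes).astype(np.float32)
            self.dbeta[...] = dout.sum(axis=axes).astype(np.float32)
        g = self._expand(self.gamma, dout.ndim, dtype) \
            * self._expand(inv, dout.ndim, dtype)
        if not self.training:
            return dout * g
        n = dout.size // dout.shape[1]
        dxhat = dout * self._expand(self.gamma, dout.ndim, dtype)
        term = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return term * self._expand(inv, dout.ndim, dtype)


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        B, C, D, H, W = self._shape
        scale = 1.0 / (D * H * W)
        return np.broadcast_to(
            (dout * scale)[:, :, None, None, None], self._shape).astype(dout.dtype)


class GlobalMaxPool:
    def __init__(self):
        self._shape = None
        self._arg = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        flat = x.reshape(x.shape[0], x.shape[1], -1)
        self._arg = flat.argmax(axis=2)
        return flat.max(axis=2)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        B, C = dout.shape
        dx = np.zeros(self._shape, dtype=dout.dtype).reshape(B, C, -1)
        b, c = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        dx[b, c, self._arg] = dout
        return dx.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.astype(x.dtype) + self.b.astype(x.dtype)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        if need_param_grads:
            self.dW[...] = (self._x.T @ dout).astype(np.float32)
            self.db[...] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.W.astype(dout.dtype).T


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        return dout.reshape(self._shape)


#: (channel_a, channel_b, threshold) triples that prime the pointwise
#: interaction branch: a unit fires at voxels where the two channels' values
#: sum beyond the threshold — steric protein/ligand occupancy overlap, and
#: the two hydrogen-bond donor/acceptor contact combinations.
CONTACT_PRIME_PAIRS = ((7, 15, 1.9), (2, 11, 1.6), (3, 10, 1.6))


class Conv3DNet:
    """Two-branch 3D CNN: an interaction-count branch plus a conv stack.

    The *count branch* is a pointwise (1^3) stride-1 convolution at full grid
    resolution whose units are initialized as protein-ligand coincidence
    detectors (CONTACT_PRIME_PAIRS), followed by ReLU and a global spatial
    sum — i.e. a differentiable, refinable count of interaction voxels.
    Gradient descent is far too slow at discovering such narrow AND-gates
    from scratch, but given the primed start it refines them readily; their
    head weights start at zero so correlated counts cannot cancel.

    The *spatial branch* is two batch-normalized stride-2 3^3 conv blocks
    whose output maps are flattened into a dense layer.  The grid is
    ligand-centered, so spatial position is meaningful and flattening (rather
    than global pooling) lets the head see where density sits in the box.

    Both branches feed one dense layer producing the scalar output (logit or
    regression value).
    """

    def __init__(self, in_channels: int = 16,
                 conv_channels: Sequence[int] = (16, 32),
                 strides: Sequence[int] = (2, 2),
                 hidden: int = 32, grid_size: int = 24,
                 prime_contacts: bool = True, count_scale: float = 5.0,
                 activation_beta: float = 4.0, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = dict(in_channels=in_channels,
                           conv_channels=tuple(conv_channels),
                           strides=tuple(strides), hidden=hidden,
                           grid_size=grid_size, prime_contacts=prime_contacts,
                           count_scale=count_scale,
                           activation_beta=activation_beta, seed=seed)
        self.count_scale = count_scale
        self.n_count = len(CONTACT_PRIME_PAIRS)
        self.conv_point = Conv3D(in_channels, self.n_count, 1, rng, k=1)
        if prime_contacts and in_channels == 16:
            self._prime(self.conv_point)
        self.relu_point = Softplus(activation_beta)

        self.blocks: list = []
        c = in_channels
        size = grid_size
        for c_out, s in zip(conv_channels, strides):
            self.blocks += [Conv3D(c, c_out, s, rng), BatchNorm(c_out),
                            Softplus(activation_beta)]
            c = c_out
            size = (size + s - 1) // s
        self.flatten = Flatten()
        self.dense_a = Dense(size ** 3 * c, hidden, rng)
        self.relu_a = Softplus(activation_beta)
        self.dense_out = Dense(hidden + self.n_count, 1, rng)
        self.dense_out.W[:self.n_count, 0] = 0.0

        self._param_layers = ([self.conv_point] + self.blocks
                              + [self.dense_a, self.dense_out])

    @staticmethod
    def _prime(conv: Conv3D, gain: float = 4.0) -> None:
        for j, (ca, cb, thr) in enumerate(CONTACT_PRIME_PAIRS):
            conv.W[:, j] = 0.0
            conv.W[ca, j] = gain
            conv.W[cb, j] = gain
            conv.b[j] = -thr * gain

    def train_mode(self, flag: bool) -> None:
        for layer in self.blocks:
            if isinstance(layer, BatchNorm):
                layer.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        hp = self.relu_point.forward(self.conv_point.forward(x))
        self._hp_shape = hp.shape
        counts = hp.sum(axis=(2, 3, 4)) * self.count_scale
        h = x
        for layer in self.blocks:
            h = layer.forward(h)
        spatial = self.relu_a.forward(self.dense_a.forward(self.flatten.forward(h)))
        features = np.concatenate([counts, spatial], axis=1)
        return self.dense_out.forward(features)[:, 0]

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        dfeat = self.dense_out.backward(dout[:, None], need_param_grads)
        dcounts = dfeat[:, :self.n_count] * self.count_scale
        dspatial = dfeat[:, self.n_count:]
        dh = self.flatten.backward(self.dense_a.backward(
            self.relu_a.backward(dspatial), need_param_grads))
        for layer in reversed(self.blocks):
            dh = layer.backward(dh, need_param_grads=need_param_grads)
        dhp = np.broadcast_to(
            dcounts[:, :, None, None, None], self._hp_shape).astype(dout.dtype).copy()
        dx = self.conv_point.backward(self.relu_point.backward(dhp),
                                      need_param_grads)
        return dh + dx

    def input_gradients(self, x: np.ndarray) -> np.ndarray:
        """d(output_i)/d(x_i) for every sample in the batch."""
        out = self.forward(x)
        return self.backward(np.ones_like(out), need_param_grads=False)

    def parameters(self):
        for layer in self._param_layers:
            yield from layer.params()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._param_layers):
            for name, arr, _ in layer.params():
                out[f"layer{i}_{name}"] = arr
            for name, arr in getattr(layer, "state", lambda: [])():
                out[f"layer{i}_{name}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._param_layers):
            for name, arr, _ in layer.params():
                arr[...] = state[f"layer{i}_{name}"]
            for name, arr in getattr(layer, "state", lambda: [])():
                arr[...] = state[f"layer{i}_{name}"]


class Adam:
    def __init__(self, net: Conv3DNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(arr) for _, arr, _ in net.parameters()]
        self.v = [np.zeros_like(arr) for _, arr, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (_, arr, grad), m, v in zip(self.net.parameters(), self.m, self.v):
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Stable binary cross-entropy on logits; returns (mean loss, dloss/dz)."""
    e = np.exp(-np.abs(z))
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(e))
    sig = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    grad = (sig - y) / len(z)
    return float(loss), grad


def mse(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = z - y
    return float(np.mean(diff ** 2)), 2.0 * diff / len(z)
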