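"""Minimal 1-D convolutional network core (NumPy, CPU).

Layers operate on batches shaped ``(n, length, channels)`` in float32 with
'valid' padding.  Two GEMM strategies are used depending on layer width:

* tap loop — one matmul per kernel tap; avoids materialising an im2col
  buffer, efficient when both channel counts are large;
* fused — a single big matmul against an explicit patch buffer, used when
  ``kernel * channels`` on the narrow side is small (the 1-channel input and
  output layers), where per-tap matmuls degenerate to outer products.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

#: switch to the fused (im2col-style) path when kernel*channels on the
#: narrow side is at most this (keeps patch buffers ~tens of MB)
FUSE_LIMIT = 512

#: also fuse whenever the whole patch buffer fits in this many bytes —
#: at small batch sizes one big GEMM beats 53 slim ones
FUSE_BYTES = 96 * 2**20


def elu(z: np.ndarray) -> np.ndarray:
    out = np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    return out.astype(z.dtype, copy=False)


def elu_grad_from_act(act: np.ndarray, z: np.ndarray) -> np.ndarray:
    # d elu/dz = 1 for z>0, exp(z) = act+1 otherwise
    return np.where(z > 0, 1.0, act + 1.0).astype(act.dtype, copy=False)


class _Layer:
    """Shared parameter/optimizer plumbing for both convolution kinds."""

    kind: str

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, activation: str):
        if activation not in ("elu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.activation = activation
        self.W = np.zeros((kernel, c_in, c_out), dtype=DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._cache = None
        self._z = self._a = None
        self._adam_state = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def init_weights(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.c_in
        fan_out = self.kernel * self.c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, self.W.shape).astype(DTYPE)
        self.b = np.zeros(self.c_out, dtype=DTYPE)

    def _activate(self, z: np.ndarray, train: bool):
        a = elu(z) if self.activation == "elu" else z
        if train:
            self._z, self._a = z, a
        return a

    def _act_backward(self, grad: np.ndarray) -> np.ndarray:
        if self.activation == "elu":
            grad = grad * elu_grad_from_act(self._a, self._z)
        self._z = self._a = None
        return grad

    def adam_step(self, dW, db, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mW": np.zeros_like(self.W), "vW": np.zeros_like(self.W),
                "mb": np.zeros_like(self.b), "vb": np.zeros_like(self.b),
            }
        s = self._adam_state
        s["t"] += 1
        for p, g, m, v in ((self.W, dW, s["mW"], s["vW"]), (self.b, db, s["mb"], s["vb"])):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** s["t"])
            vhat = v / (1 - beta2 ** s["t"])
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(DTYPE)


class Conv1D(_Layer):
    kind = "conv"

    def out_length(self, length: int) -> int:
        if length < self.kernel:
            raise ValueError(f"conv: length underflow ({length} < kernel {self.kernel})")
        return (length - self.kernel) // self.stride + 1

    def _fuse(self, n: int, l_out: int) -> bool:
        width = self.kernel * self.c_in
        return width <= FUSE_LIMIT or n * l_out * width * 4 <= FUSE_BYTES

    def _gather(self, x: np.ndarray, l_out: int) -> np.ndarray:
        n = x.shape[0]
        s = self.stride
        patches = np.empty((n, l_out, self.kernel * self.c_in), dtype=DTYPE)
        for j in range(self.kernel):
            patches[:, :, j * self.c_in : (j + 1) * self.c_in] = x[:, j : j + s * l_out : s, :]
        return patches

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, _ = x.shape
        l_out = self.out_length(length)
        s = self.stride
        if self._fuse(n, l_out):
            patches = self._gather(x, l_out)
            z = patches.reshape(-1, self.kernel * self.c_in) @ self.W.reshape(-1, self.c_out)
            z = z.reshape(n, l_out, self.c_out) + self.b
            if train:
                self._cache = ("fused", patches, (n, length))
        else:
            z = np.broadcast_to(self.b, (n, l_out, self.c_out)).astype(DTYPE).copy()
            for j in range(self.kernel):
                xs = x[:, j : j + s * l_out : s, :]
                z += (xs.reshape(-1, self.c_in) @ self.W[j]).reshape(n, l_out, self.c_out)
            if train:
                self._cache = ("taps", x, (n, length))
        return self._activate(z, train)

    def backward(self, grad: np.ndarray, need_dx: bool = True):
        grad = self._act_backward(grad)
        mode, stored, (n, length) = self._cache
        l_out = grad.shape[1]
        s = self.stride
        g2 = grad.reshape(-1, self.c_out)
        db = g2.sum(axis=0)
        dx = np.zeros((n, length, self.c_in), dtype=DTYPE) if need_dx else None
        if mode == "fused":
            p2 = stored.reshape(-1, self.kernel * self.c_in)
            dW = (p2.T @ g2).reshape(self.kernel, self.c_in, self.c_out)
            if need_dx:
                dp = (g2 @ self.W.reshape(-1, self.c_out).T).reshape(
                    n, l_out, self.kernel, self.c_in
                )
                for j in range(self.kernel):
                    dx[:, j : j + s * l_out : s, :] += dp[:, :, j, :]
        else:
            x = stored
            dW = np.empty_like(self.W)
            for j in range(self.kernel):
                xs = x[:, j : j + s * l_out : s, :].reshape(-1, self.c_in)
                dW[j] = xs.T @ g2
                if need_dx:
                    dx[:, j : j + s * l_out : s, :] += (g2 @ self.W[j].T).reshape(
                        n, l_out, self.c_in
                    )
        self._cache = None
        return dx, dW, db


class ConvTranspose1D(_Layer):
    kind = "transposed_conv"

    def out_length(self, length: int) -> int:
        return (length - 1) * self.stride + self.kernel

    def _fuse(self, n: int, length: int) -> bool:
        width = self.kernel * self.c_out
        return width <= FUSE_LIMIT or n * length * width * 4 <= FUSE_BYTES

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, _ = x.shape
        l_out = self.out_length(length)
        s = self.stride
        z = np.zeros((n, l_out, self.c_out), dtype=DTYPE)
        x2 = np.ascontiguousarray(x).reshape(-1, self.c_in)
        if self._fuse(n, length):
            wr = self.W.transpose(1, 0, 2).reshape(self.c_in, -1)  # (c_in, k*c_out)
            p = (x2 @ wr).reshape(n, length, self.kernel, self.c_out)
            for j in range(self.kernel):
                z[:, j : j + s * length : s, :] += p[:, :, j, :]
        else:
            for j in range(self.kernel):
                z[:, j : j + s * length : s, :] += (x2 @ self.W[j]).reshape(
                    n, length, self.c_out
                )
        z += self.b
        if train:
            self._cache = (x2, (n, length))
        return self._activate(z, train)

    def backward(self, grad: np.ndarray, need_dx: bool = True):
        grad = self._act_backward(grad)
        x2, (n, length) = self._cache
        s = self.stride
        db = grad.reshape(-1, self.c_out).sum(axis=0)
        if self._fuse(n, length):
            g = np.empty((n, length, self.kernel, self.c_out), dtype=DTYPE)
            for j in range(self.kernel):
                g[:, :, j, :] = grad[:, j : j + s * length : s, :]
            g2 = g.reshape(-1, self.kernel * self.c_out)
            dW = (x2.T @ g2).reshape(self.c_in, self.kernel, self.c_out).transpose(1, 0, 2)
            dx = (g2 @ self.W.transpose(1, 0, 2).reshape(self.c_in, -1).T).reshape(
                n, length, self.c_in
            ) if need_dx else None
        else:
            dW = np.empty_like(self.W)
            dx = np.zeros((n, length, self.c_in), dtype=DTYPE) if need_dx else None
            for j in range(self.kernel):
                gs = grad[:, j : j + s * length : s, :].reshape(-1, self.c_out)
                dW[j] = x2.T @ gs
                if need_dx:
                    dx += (gs @ self.W[j].T).reshape(n, length, self.c_in)
        self._cache = None
        return dx, np.ascontiguousarray(dW), db


class Network:
    """A plain sequence of layers with joint forward/backward passes."""

    def __init__(self, layers: list[_Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train=train)
        return x

    def backward_and_step(self, grad_out: np.ndarray, lr: float, eps: float = 1e-7) -> None:
        grad = grad_out
        updates = []
        for i, layer in reversed(list(enumerate(self.layers))):
            grad, dW, db = layer.backward(grad, need_dx=(i > 0))
            updates.append((layer, dW, db))
        for layer, dW, db in updates:
            layer.adam_step(dW, db, lr, eps=eps)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            layer.W = np.asarray(next(it), dtype=DTYPE).copy()
            layer.b = np.asarray(next(it), dtype=DTYPE).copy()
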