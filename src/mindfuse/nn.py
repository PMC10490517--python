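"""Minimal NumPy neural-network engine for the fusion ConvNets.

Implements exactly the layer set the two architectures need — valid 2-D
convolution (stride 1), batch normalization with trainable affine, ELU,
temporal max-pooling (size 2, stride 2, floor), inverted dropout, dense
layers with optional L2 weight penalty, and softmax cross-entropy — plus
the Adam optimizer.  Arrays are laid out channels-last,
(batch, time, height, maps), which keeps every convolution a single large
GEMM with no layout transposes; all randomness (initialization, dropout,
shuffling) flows through one ``numpy.random.Generator`` per network, so
training is reproducible under a seed.
"""

from __future__ import annotations

import numpy as np


class ArchitectureError(ValueError):
    """Layer stack is inconsistent with the input shape."""


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` with matching
    arrays and implement forward/backward."""

    name = "layer"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, mode: str,
                rng: np.random.Generator) -> np.ndarray:
        """``mode`` is one of 'train' (batch statistics, dropout active,
        caches for backward), 'eval' (deterministic inference) or 'calib'
        (batch statistics without dropout, used to estimate the inference
        batch-norm statistics and to monitor validation loss)."""
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def reg_loss(self) -> float:
        return 0.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Layer):
    """Valid 2-D convolution, stride 1, kernel (kt, kh) over (time, height).

    Supports the two kernel shapes the architectures use: temporal (kt, 1)
    kernels run as one GEMM over a time-only im2col; spatial (1, kh)
    kernels spanning the full height collapse to a plain matmul on the
    channels-last layout with no data movement at all.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: tuple[int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        kt, kh = kernel
        if kt != 1 and kh != 1:
            raise ArchitectureError(
                "kernels must be temporal (k, 1) or spatial (1, k)")
        self.kernel = kernel
        self.name = f"conv{kt}x{kh}_{out_maps}"
        fan_in, fan_out = in_maps * kt * kh, out_maps * kt * kh
        self.w = _glorot(rng, (out_maps, in_maps, kt, kh), fan_in, fan_out)
        self.b = np.zeros(out_maps, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def forward(self, x, mode, rng):
        kt, kh = self.kernel
        n, t, h, ci = x.shape
        to, ho = t - kt + 1, h - kh + 1
        if to <= 0 or ho <= 0:
            raise ArchitectureError(
                f"input ({t}, {h}) too small for kernel {self.kernel}")
        co = self.w.shape[0]
        if kh == 1:
            # temporal: im2col over time, (height, batch) ride along
            win = np.lib.stride_tricks.sliding_window_view(x, kt, axis=1)
            cols = win.reshape(n * to * h, ci * kt)       # (.., c*kt+a)
            wmat = self.w[:, :, :, 0].reshape(co, ci * kt)
            out = (cols @ wmat.T + self.b).reshape(n, to, h, co)
        else:
            if kh != h:
                raise ArchitectureError(
                    f"spatial kernel height {kh} must span input height {h}")
            # spatial: channels-last makes this a plain matmul
            cols = x.reshape(n * t, h * ci)
            wmat = self.w[:, :, 0, :].transpose(0, 2, 1).reshape(
                co, kh * ci)
            out = (cols @ wmat.T + self.b).reshape(n, t, 1, co)
        self._cols = cols if mode == "train" else None
        self._x_shape = x.shape
        return out

    def backward(self, grad):
        kt, kh = self.kernel
        n, to, ho, co = grad.shape
        _, t, h, ci = self._x_shape
        if kh == 1:
            g2 = grad.reshape(n * to * h, co)
            self.grads[0][...] = (g2.T @ self._cols).reshape(
                co, ci, kt)[:, :, :, None]
            self.grads[1][...] = g2.sum(axis=0)
            wmat = self.w[:, :, :, 0].reshape(co, ci * kt)
            dcols = (g2 @ wmat).reshape(n, to, h, ci, kt)
            dx = np.zeros((n, t, h, ci), dtype=grad.dtype)
            for a in range(kt):                            # col2im
                dx[:, a: a + to] += dcols[..., a]
        else:
            g2 = grad.reshape(n * t, co)                   # ho == 1
            self.grads[0][...] = (g2.T @ self._cols).reshape(
                co, kh, ci).transpose(0, 2, 1)[:, :, None, :]
            self.grads[1][...] = g2.sum(axis=0)
            wmat = self.w[:, :, 0, :].transpose(0, 2, 1).reshape(
                co, kh * ci)
            dx = (g2 @ wmat).reshape(n, t, h, ci)
        self._cols = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over feature maps with trainable scale/shift.

    'train' and 'calib' modes normalize with the current batch statistics;
    'eval' uses fixed inference statistics (not trainable), which are set
    exactly — not by a running average — via :func:`collect_bn_statistics`
    after training.  A momentum-style running estimate needs far more
    optimizer steps than small training sets provide before inference-mode
    outputs match training behavior.
    """

    def __init__(self, maps: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.name = f"batchnorm_{maps}"
        self.gamma = np.ones(maps, dtype=np.float32)
        self.beta = np.zeros(maps, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(maps, dtype=np.float32)
        self.running_var = np.ones(maps, dtype=np.float32)
        self.eps = eps
        self.collecting = False
        self._acc = None

    def forward(self, x, mode, rng):
        axes = (0, 1, 2)
        if mode == "eval":
            mean, var = self.running_mean, self.running_var
        else:
            mean = x.mean(axis=axes)
            var = np.maximum((x * x).mean(axis=axes) - mean * mean, 0.0)
            if self.collecting:
                m = x.shape[0] * x.shape[1] * x.shape[2]
                if self._acc is None:
                    self._acc = [0, np.zeros_like(mean, dtype=np.float64),
                                 np.zeros_like(mean, dtype=np.float64)]
                self._acc[0] += m
                self._acc[1] += m * mean.astype(np.float64)
                self._acc[2] += m * (var + mean * mean).astype(np.float64)
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def finish_collection(self) -> None:
        n, s, ssq = self._acc
        mean = s / n
        self.running_mean = mean.astype(np.float32)
        self.running_var = np.maximum(ssq / n - mean * mean,
                                      0.0).astype(np.float32)
        self._acc = None
        self.collecting = False

    def backward(self, grad):
        axes = (0, 1, 2)
        dy_xhat = grad * self._xhat
        self.grads[0][...] = dy_xhat.sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        g = self.gamma / self._std
        dx = g * (grad - grad.mean(axis=axes)
                  - self._xhat * dy_xhat.mean(axis=axes))
        self._xhat = None
        return dx.astype(np.float32, copy=False)


class Elu(Layer):
    name = "elu"

    def forward(self, x, mode, rng):
        self._y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        return self._y

    def backward(self, grad):
        return grad * np.where(self._y > 0, 1.0, self._y + 1.0)


class Relu(Layer):
    name = "relu"

    def forward(self, x, mode, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPoolTime(Layer):
    """Max-pool size 2, stride 2 along time; odd lengths floor."""

    name = "maxpool2"

    def forward(self, x, mode, rng):
        n, t, h, c = x.shape
        to = t // 2
        if to == 0:
            raise ArchitectureError(f"time length {t} too short to pool")
        self._t_in = t
        a, b = x[:, 0: 2 * to: 2], x[:, 1: 2 * to: 2]
        self._first = a >= b          # ties take the earlier sample
        return np.where(self._first, a, b)

    def backward(self, grad):
        n, to, h, c = grad.shape
        dx = np.zeros((n, self._t_in, h, c), dtype=grad.dtype)
        dx[:, 0: 2 * to: 2] = np.where(self._first, grad, 0.0)
        dx[:, 1: 2 * to: 2] = np.where(self._first, 0.0, grad)
        return dx


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p
        self.name = f"dropout_{p}"

    def forward(self, x, mode, rng):
        if mode != "train" or self.p == 0.0:
            self._mask = None
            return x
        keep = rng.random(x.shape, dtype=np.float32) >= self.p
        self._mask = keep.astype(np.float32) / np.float32(1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(np.float32, copy=False)


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, mode, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; ``l2`` adds l2*||W||^2 to the loss (weights
    only, not biases)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 l2: float = 0.0) -> None:
        super().__init__()
        self.name = f"dense_{n_out}"
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.l2 = l2
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, mode, rng):
        self._x = x if mode == "train" else None
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad + 2.0 * self.l2 * self.w
        self.grads[1][...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx

    def reg_loss(self) -> float:
        return float(self.l2 * np.sum(self.w.astype(np.float64) ** 2))


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, mode: str,
                rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, mode, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_pairs(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def reg_loss(self) -> float:
        return sum(layer.reg_loss() for layer in self.layers)

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    def inventory(self) -> list[dict]:
        return [{"layer": lyr.name, "trainable_parameters": lyr.param_count}
                for lyr in self.layers]


class BranchedNet:
    """Several parallel Sequential branches whose flattened outputs are
    concatenated and fed to a Sequential head."""

    def __init__(self, branches: list[Sequential], head: Sequential) -> None:
        self.branches = branches
        self.head = head

    def forward(self, inputs: list[np.ndarray], mode: str,
                rng: np.random.Generator) -> np.ndarray:
        outs = [b.forward(x, mode, rng)
                for b, x in zip(self.branches, inputs, strict=True)]
        self._widths = [o.shape[1] for o in outs]
        return self.head.forward(np.concatenate(outs, axis=1), mode, rng)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        offset = 0
        for branch, width in zip(self.branches, self._widths):
            branch.backward(g[:, offset: offset + width])
            offset += width

    def param_pairs(self):
        for branch in self.branches:
            yield from branch.param_pairs()
        yield from self.head.param_pairs()

    def reg_loss(self) -> float:
        return sum(b.reg_loss() for b in self.branches) \
            + self.head.reg_loss()

    @property
    def param_count(self) -> int:
        return sum(b.param_count for b in self.branches) \
            + self.head.param_count

    def inventory(self) -> list[dict]:
        inv = []
        for i, branch in enumerate(self.branches):
            for entry in branch.inventory():
                inv.append({**entry, "branch": i})
        inv.extend(self.head.inventory())
        return inv


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray,
                  labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, param_pairs, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.pairs = list(param_pairs)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _bn_layers(net) -> list[BatchNorm]:
    if isinstance(net, BranchedNet):
        stacks = [*net.branches, net.head]
    else:
        stacks = [net]
    return [lyr for stack in stacks for lyr in stack.layers
            if isinstance(lyr, BatchNorm)]


def collect_bn_statistics(net, batches, rng) -> None:
    """Set every batch-norm layer's inference statistics to the exact
    feature-map mean/variance over ``batches`` (an iterable of forward
    inputs), evaluated with dropout disabled."""
    layers = _bn_layers(net)
    for lyr in layers:
        lyr.collecting = True
        lyr._acc = None
    for batch in batches:
        net.forward(batch, "calib", rng)
    for lyr in layers:
        lyr.finish_collection()


def get_state(net) -> list[np.ndarray]:
    return [p.copy() for p, _ in net.param_pairs()]


def set_state(net, state: list[np.ndarray]) -> None:
    for (p, _), saved in zip(net.param_pairs(), state, strict=True):
        p[...] = saved
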