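"""Minimal NumPy neural-network engine.

Implements exactly the pieces the AC-GAN and its baselines need: dense,
strided convolution and transposed convolution (via im2col/col2im), batch
normalization, leaky-ReLU/ReLU/tanh activations, the Adam optimizer, and
spectral normalization of weight matrices by power iteration.  Layers cache
their forward inputs and implement explicit backward passes; gradients
accumulate into ``Parameter.grad``.

Data layout is NCHW throughout.  ``DTYPE`` (float32 by default, for CPU
throughput) is read at layer construction and input casting; setting it to
float64 makes the analytic gradients checkable against finite differences
to ~1e-9.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: forward caches whatever backward needs."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def set_training(self, flag: bool) -> None:
        self.training = flag


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad, need_input_grad: bool = True):
        for i, layer in enumerate(reversed(self.layers)):
            if not need_input_grad and i == len(self.layers) - 1 and isinstance(layer, Conv2d):
                return layer.backward(grad, need_input_grad=False)
            grad = layer.backward(grad)
        return grad

    def set_training(self, flag):
        for layer in self.layers:
            layer.set_training(flag)


# ---------------------------------------------------------------------------
# Spectral normalization

def power_iteration_sigma(w_mat: np.ndarray, u: np.ndarray, n_iter: int = 1):
    """Largest singular value of ``w_mat`` estimated by power iteration.

    Returns ``(sigma, u, v)`` with the updated left singular vector ``u``
    for warm-started reuse across training steps.
    """
    eps = 1e-12
    v = None
    for _ in range(n_iter):
        v = w_mat.T @ u
        v = v / (np.linalg.norm(v) + eps)
        u = w_mat @ v
        u = u / (np.linalg.norm(u) + eps)
    sigma = float(u @ (w_mat @ v))
    return sigma, u, v


def spectral_normalize(weight: np.ndarray, n_iter: int = 5000, tol: float = 1e-12,
                       seed: int = 0) -> np.ndarray:
    """Divide a weight tensor by its largest singular value.

    The tensor is flattened to a ``(shape[0], -1)`` matrix, its spectral
    norm estimated by power iteration (converged to relative tolerance
    ``tol`` or ``n_iter`` sweeps), and the original tensor rescaled so the
    flattened matrix has unit spectral norm.
    """
    w = np.asarray(weight, dtype=DTYPE)
    mat = w.reshape(w.shape[0], -1)
    norm = np.linalg.norm(mat)
    if norm == 0:
        raise ValueError("cannot spectral-normalize an all-zero weight")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(mat.shape[0])
    u /= np.linalg.norm(u)
    sigma_prev = 0.0
    for _ in range(n_iter):
        sigma, u, _ = power_iteration_sigma(mat, u, n_iter=1)
        if abs(sigma - sigma_prev) <= tol * max(sigma, 1e-30):
            break
        sigma_prev = sigma
    return w / sigma


class _SpectralNormMixin:
    """Per-step spectral normalization for a layer weight (one power
    iteration per training forward, warm-started; cached sigma in eval).

    The backward pass propagates through sigma = u^T W v (u, v held fixed
    per Danskin): d(W/sigma) contributes a rank-1 correction
    -(sum(G .* W_bar)/sigma) u v^T on top of G/sigma.
    """

    def _init_sn(self, out_dim: int, rng: np.random.Generator):
        self._sn_u = rng.standard_normal(out_dim)
        self._sn_u /= np.linalg.norm(self._sn_u)
        self._sn_v = None
        self._sn_sigma = 1.0

    def _sn_weight(self, w: np.ndarray) -> np.ndarray:
        mat = w.reshape(w.shape[0], -1)
        if self.training:
            sigma, self._sn_u, self._sn_v = power_iteration_sigma(mat, self._sn_u, n_iter=1)
            self._sn_sigma = max(sigma, 1e-12)
        elif self._sn_v is None:
            # eval before any training forward: derive v from the cached u
            v = mat.T @ self._sn_u
            self._sn_v = v / (np.linalg.norm(v) + 1e-12)
        return w / self._sn_sigma

    def _sn_grad(self, grad_eff: np.ndarray, w_eff: np.ndarray) -> np.ndarray:
        """Map the gradient w.r.t. the normalized weight onto the raw weight."""
        g = grad_eff / self._sn_sigma
        coeff = float(np.sum(grad_eff * w_eff)) / self._sn_sigma
        rank1 = np.outer(self._sn_u, self._sn_v).reshape(w_eff.shape)
        return g - coeff * rank1


# ---------------------------------------------------------------------------
# Dense

class Dense(Layer, _SpectralNormMixin):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 spectral_norm: bool = False, init_std: float = 0.02):
        self.W = Parameter(rng.normal(0.0, init_std, size=(n_out, n_in)))
        self.b = Parameter(np.zeros(n_out))
        self.spectral_norm = spectral_norm
        if spectral_norm:
            self._init_sn(n_out, rng)

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        w = self._sn_weight(self.W.value) if self.spectral_norm else self.W.value
        self._w_eff = w
        return x @ w.T + self.b.value

    def backward(self, grad):
        dW = grad.T @ self._x
        self.W.grad += self._sn_grad(dW, self._w_eff) if self.spectral_norm else dW
        self.b.grad += grad.sum(axis=0)
        return grad @ self._w_eff


# ---------------------------------------------------------------------------
# Convolutions via im2col / col2im

def _out_size(length: int, k: int, stride: int, pad: int) -> int:
    return (length + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold NCHW input into rows of receptive fields.

    Returns ``(cols, (oh, ow))`` with ``cols`` of shape
    ``(N*oh*ow, C*k*k)``.
    """
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad > 0 else x
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (n, c, oh, ow, k, k)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * oh * ow, c * k * k), (oh, ow)


def col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    """Fold receptive-field rows back into NCHW, summing overlaps."""
    n, c, h, w = x_shape
    # contiguous (k, k, n, c, oh, ow) first: the k*k strided adds then read
    # from contiguous memory, which is much faster than strided gathers
    cols6 = np.ascontiguousarray(
        cols.reshape(n, oh, ow, c, k, k).transpose(4, 5, 0, 3, 1, 2)
    )
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[i, j]
    return xp[:, :, pad : pad + h, pad : pad + w] if pad > 0 else xp


class Conv2d(Layer, _SpectralNormMixin):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, spectral_norm: bool = False,
                 init_std: float = 0.02):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.W = Parameter(rng.normal(0.0, init_std, size=(c_out, c_in * k * k)))
        self.b = Parameter(np.zeros(c_out))
        self.spectral_norm = spectral_norm
        if spectral_norm:
            self._init_sn(c_out, rng)

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x_shape = x.shape
        cols, (oh, ow) = im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        w = self._sn_weight(self.W.value) if self.spectral_norm else self.W.value
        self._w_eff = w
        y = cols @ w.T + self.b.value
        n = x.shape[0]
        return y.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad, need_input_grad: bool = True):
        n = grad.shape[0]
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * self._oh * self._ow, self.c_out)
        dW = g2.T @ self._cols
        self.W.grad += self._sn_grad(dW, self._w_eff) if self.spectral_norm else dW
        self.b.grad += g2.sum(axis=0)
        if not need_input_grad:
            return None
        dcols = g2 @ self._w_eff
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad, self._oh, self._ow)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution (the adjoint of Conv2d).

    When ``k == stride`` and ``pad == 0`` the receptive fields do not
    overlap and the operation reduces to one matmul plus a pixel-shuffle
    reshape — much faster on CPU than the generic scatter-add, with
    identical semantics.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, init_std: float = 0.02):
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.W = Parameter(rng.normal(0.0, init_std, size=(c_in, c_out * k * k)))
        self.b = Parameter(np.zeros(c_out))
        self._disjoint = k == stride and pad == 0

    def parameters(self):
        return [self.W, self.b]

    def out_shape(self, h: int, w: int):
        return ((h - 1) * self.stride - 2 * self.pad + self.k,
                (w - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        ho, wo = self.out_shape(h, w)
        x_flat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self._x_flat = x_flat
        cols = x_flat @ self.W.value
        k = self.k
        if self._disjoint:
            y = cols.reshape(n, h, w, self.c_out, k, k)
            y = np.ascontiguousarray(y.transpose(0, 3, 1, 4, 2, 5)).reshape(n, self.c_out, ho, wo)
        else:
            y = col2im(cols, (n, self.c_out, ho, wo), k, self.stride, self.pad, h, w)
        return y + self.b.value[None, :, None, None]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        k = self.k
        if self._disjoint:
            g = grad.reshape(n, self.c_out, h, k, w, k)
            gcols = np.ascontiguousarray(g.transpose(0, 2, 4, 1, 3, 5)).reshape(
                n * h * w, self.c_out * k * k
            )
        else:
            gcols, _ = im2col(grad, k, self.stride, self.pad)
        self.W.grad += self._x_flat.T @ gcols
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dx = gcols @ self.W.value.T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


# ---------------------------------------------------------------------------
# Batch normalization

class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=self.gamma.value.dtype)
        self.running_var = np.ones(c, dtype=self.gamma.value.dtype)

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self.training:
            return grad * g * self._inv_std[None, :, None, None]
        n, _, h, w = grad.shape
        m = n * h * w
        dxhat = grad * g
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (self._inv_std[None, :, None, None] / m) * (m * dxhat - s1 - self._xhat * s2)


# ---------------------------------------------------------------------------
# Activations & shape

class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._slope = np.where(x >= 0, x.dtype.type(1), x.dtype.type(self.alpha))
        return x * self._slope

    def backward(self, grad):
        return grad * self._slope


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = tuple(shape)  # per-sample shape

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


# ---------------------------------------------------------------------------
# Optimizer

class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Numerical utilities shared by the models

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def get_state(params: list[Parameter]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Parameter], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s
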