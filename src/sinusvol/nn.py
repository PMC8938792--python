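"""Minimal CPU neural-network engine used by the segmentation model.

Implements exactly the primitives the encoder–decoder needs — 2D
convolution (with stride, dilation and depthwise grouping), batch
normalization, Mish/ReLU/sigmoid activations, bilinear resizing, global
average pooling and fully-connected layers — each as a module with an
explicit, hand-derived backward pass, plus an Adam optimizer and a
masked softmax cross-entropy loss.  Tensors are plain numpy arrays in
``(batch, channel, height, width)`` layout.

The implementation favours clarity and small-image throughput:
convolutions are evaluated as a loop over the k*k kernel taps, each tap
a single BLAS-backed ``einsum``, which is fast for the 3x3 kernels and
<=128 px slices this package trains on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Mish",
    "Sigmoid",
    "Identity",
    "Sequential",
    "Linear",
    "BilinearResize",
    "mish",
    "mish_grad",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def mish(x: np.ndarray) -> np.ndarray:
    """Mish activation, x * tanh(softplus(x)), numerically stable.

    softplus is evaluated as ``logaddexp(0, x)`` so neither tail
    overflows; for large x the result approaches x, for large -x it
    approaches 0.
    """
    return x * np.tanh(np.logaddexp(0.0, x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def mish_grad(x: np.ndarray) -> np.ndarray:
    """d/dx of mish: tanh(sp(x)) + x * sech^2(sp(x)) * sigmoid(x)."""
    t = np.tanh(np.logaddexp(0.0, x))
    return t + x * (1.0 - t * t) * _sigmoid(x)


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: children discovered by attribute scan."""

    training: bool = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def params(self) -> list[Param]:
        seen: list[Param] = []
        ids = set()
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Param) and id(v) not in ids:
                    ids.add(id(v))
                    seen.append(v)
        return seen

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _buffers(self) -> list[tuple["Module", str]]:
        out = []
        for m in self.modules():
            for name in getattr(m, "buffer_names", ()):
                out.append((m, name))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for i, (m, name) in enumerate(self._buffers()):
            state[f"b{i}"] = getattr(m, name)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        buffers = self._buffers()
        if len(state) != len(params) + len(buffers):
            raise ValueError(
                f"state has {len(state)} arrays, model expects "
                f"{len(params)} params + {len(buffers)} buffers")
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for param {i}")
            p.value[...] = arr
        for i, (m, name) in enumerate(buffers):
            setattr(m, name, state[f"b{i}"].copy())


def _out_size(n: int, k: int, stride: int, dilation: int) -> int:
    # 'same'-style padding with ceil division: output = ceil(n / stride)
    return -(-n // stride)


def _same_pad(n: int, k: int, stride: int, dilation: int) -> tuple[int, int]:
    eff = dilation * (k - 1) + 1
    out = _out_size(n, k, stride, dilation)
    total = max((out - 1) * stride + eff - n, 0)
    return total // 2, total - total // 2


class Conv2d(Module):
    """2D convolution with 'same' padding, stride, dilation and groups.

    groups must be 1 (dense) or in_channels (depthwise).  Weight layout
    is (out_channels, in_channels // groups, k, k).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        if groups not in (1, in_channels):
            raise ValueError("groups must be 1 or in_channels")
        if groups == in_channels and out_channels % in_channels:
            raise ValueError("depthwise conv needs out_channels % in_channels == 0")
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.stride, self.dilation, self.groups = stride, dilation, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels // groups, kernel_size, kernel_size))
        self.weight = Param(w.astype(dtype), "conv.weight")
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "conv.bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        s, d, k = self.stride, self.dilation, self.k
        ph = _same_pad(h, k, s, d)
        pw = _same_pad(w, k, s, d)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw)) if (k > 1 or max(ph + pw) > 0) else x
        oh, ow = _out_size(h, k, s, d), _out_size(w, k, s, d)
        wt = self.weight.value
        out = np.zeros((b, self.cout, oh, ow), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki * d: ki * d + (oh - 1) * s + 1: s,
                        kj * d: kj * d + (ow - 1) * s + 1: s]
                if self.groups == 1:
                    out += np.einsum("oc,bchw->bohw", wt[:, :, ki, kj], xs, optimize=True)
                else:
                    # depthwise: weight (C*mult, 1, k, k); mult usually 1
                    wtap = wt[:, 0, ki, kj]
                    if self.cout == self.cin:
                        out += wtap[None, :, None, None] * xs
                    else:
                        mult = self.cout // self.cin
                        out += (wtap.reshape(self.cin, mult)[None, :, :, None, None]
                                * xs[:, :, None]).reshape(b, self.cout, oh, ow)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        self._cache = (xp, x.shape, ph, pw, oh, ow)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, xshape, ph, pw, oh, ow = self._cache
        s, d, k = self.stride, self.dilation, self.k
        wt = self.weight.value
        gxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                sl_h = slice(ki * d, ki * d + (oh - 1) * s + 1, s)
                sl_w = slice(kj * d, kj * d + (ow - 1) * s + 1, s)
                xs = xp[:, :, sl_h, sl_w]
                if self.groups == 1:
                    self.weight.grad[:, :, ki, kj] += np.einsum(
                        "bohw,bchw->oc", grad, xs, optimize=True)
                    gxp[:, :, sl_h, sl_w] += np.einsum(
                        "oc,bohw->bchw", wt[:, :, ki, kj], grad, optimize=True)
                else:
                    if self.cout == self.cin:
                        self.weight.grad[:, 0, ki, kj] += np.einsum(
                            "bchw,bchw->c", grad, xs, optimize=True)
                        gxp[:, :, sl_h, sl_w] += wt[:, 0, ki, kj][None, :, None, None] * grad
                    else:
                        mult = self.cout // self.cin
                        g5 = grad.reshape(grad.shape[0], self.cin, mult, oh, ow)
                        self.weight.grad[:, 0, ki, kj] += np.einsum(
                            "bcmhw,bchw->cm", g5, xs, optimize=True).reshape(-1)
                        wtap = wt[:, 0, ki, kj].reshape(self.cin, mult)
                        gxp[:, :, sl_h, sl_w] += np.einsum(
                            "cm,bcmhw->bchw", wtap, g5, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        b, c, h, w = xshape
        return gxp[:, :, ph[0]: ph[0] + h, pw[0]: pw[0] + w]


class BatchNorm2d(Module):
    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += np.einsum("bchw,bchw->c", grad, xhat, optimize=True)
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        gm = g.mean(axis=(0, 2, 3))
        gx = np.einsum("bchw,bchw->c", g, xhat, optimize=True) / n
        return inv[None, :, None, None] * (
            g - gm[None, :, None, None] - xhat * gx[None, :, None, None])


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Mish(Module):
    def forward(self, x):
        self._x = x
        return mish(x)

    def backward(self, grad):
        return grad * mish_grad(self._x)


class Sigmoid(Module):
    def forward(self, x):
        self._y = _sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Identity(Module):
    def forward(self, x):
        return x

    def backward(self, grad):
        return grad


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in))
        self.weight = Param(w.astype(dtype), "fc.weight")
        self.bias = Param(np.zeros(n_out, dtype=dtype), "fc.bias")

    def forward(self, x):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


def _interp_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1 or n_out == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearResize(Module):
    """Resize feature maps to a target (H, W) by separable bilinear
    interpolation; the backward pass is the exact adjoint."""

    def __init__(self, size: tuple[int, int] | None = None):
        self.size = size
        self._mats: dict[tuple[int, int], np.ndarray] = {}

    def _mat(self, n_out, n_in, dtype):
        key = (n_out, n_in)
        if key not in self._mats:
            self._mats[key] = _interp_matrix(n_out, n_in).astype(dtype)
        return self._mats[key]

    def forward(self, x, size: tuple[int, int] | None = None):
        size = size or self.size
        if size is None:
            raise ValueError("target size not set")
        h_in, w_in = x.shape[2], x.shape[3]
        self._in_hw = (h_in, w_in)
        self._out_hw = size
        if size == (h_in, w_in):
            self._noop = True
            return x
        self._noop = False
        wr = self._mat(size[0], h_in, x.dtype)
        wc = self._mat(size[1], w_in, x.dtype)
        tmp = np.einsum("Oh,bchw->bcOw", wr, x, optimize=True)
        return np.einsum("Ww,bchw->bchW", wc, tmp, optimize=True)

    def backward(self, grad):
        if self._noop:
            return grad
        wr = self._mat(self._out_hw[0], self._in_hw[0], grad.dtype)
        wc = self._mat(self._out_hw[1], self._in_hw[1], grad.dtype)
        tmp = np.einsum("Oh,bcOw->bchw", wr, grad, optimize=True)
        return np.einsum("Ww,bchW->bchw", wc, tmp, optimize=True)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    ignore_index: int = -1,
    per_sample: bool = False,
    class_weights: np.ndarray | None = None,
):
    """Weighted mean pixelwise cross-entropy, ignoring masked pixels.

    ``class_weights`` (length n_classes) rescales each pixel's
    contribution by the weight of its reference class — used to keep
    rare foreground classes from being swamped by background.  Returns
    (loss, dlogits) and, with per_sample=True, also the per-sample
    mean losses (shape (batch,)).
    """
    b, k = logits.shape[0], logits.shape[1]
    p = softmax(logits, axis=1)
    valid = labels != ignore_index
    safe_labels = np.where(valid, labels, 0)
    if class_weights is None:
        pix_w = valid.astype(p.dtype)
    else:
        pix_w = np.asarray(class_weights, dtype=p.dtype)[safe_labels] * valid
    w_total = float(pix_w.sum())
    idx_b, idx_h, idx_w = np.meshgrid(
        np.arange(b), np.arange(logits.shape[2]), np.arange(logits.shape[3]),
        indexing="ij")
    p_true = p[idx_b, safe_labels, idx_h, idx_w]
    nll = -np.log(np.maximum(p_true, 1e-12)) * pix_w
    loss = float(nll.sum() / max(w_total, 1e-12))
    onehot_grad = p.copy()
    np.subtract.at(onehot_grad, (idx_b, safe_labels, idx_h, idx_w), 1.0)
    onehot_grad *= pix_w[:, None, :, :]
    dlogits = onehot_grad / max(w_total, 1e-12)
    if per_sample:
        per = nll.sum(axis=(1, 2)) / np.maximum(pix_w.sum(axis=(1, 2)), 1e-12)
        return loss, dlogits.astype(logits.dtype), per
    return loss, dlogits.astype(logits.dtype)


def median_frequency_weights(labels: np.ndarray, n_classes: int,
                             ignore_index: int = -1,
                             cap: float = 10.0,
                             power: float = 0.5) -> np.ndarray:
    """Class-balancing weights from reference label frequencies.

    w_c = (median(freq) / freq_c) ** power over classes present,
    capped at ``cap`` and renormalised to mean 1; ``power`` < 1 softens
    the rebalancing (0.5 by default), which keeps rare classes visible
    without letting them dominate the gradient.  Absent classes get the
    cap (they contribute nothing anyway).
    """
    valid = labels[labels != ignore_index]
    counts = np.bincount(valid.ravel(), minlength=n_classes).astype(np.float64)
    present = counts > 0
    freqs = counts / counts.sum()
    med = np.median(freqs[present])
    w = np.full(n_classes, cap)
    w[present] = np.minimum((med / freqs[present]) ** power, cap)
    return w / w.mean()


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
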