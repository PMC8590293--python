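"""Neural network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor, softmax


class Module:
    """Container with named parameters; supports train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for mname, mod in self._modules.items():
            for pname, p in mod.parameters().items():
                out[f"{mname}.{pname}"] = p
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.W = _glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = Tensor(rng.normal(0.0, 0.02, size=(n_vocab, dim)), requires_grad=True)

    def __call__(self, indices) -> Tensor:
        return self.W.take(np.asarray(indices).reshape(-1)).reshape(
            *np.asarray(indices).shape, self.W.shape[1])


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.g + self.b


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * Tensor(keep)


class GRUCell(Module):
    """Standard gated recurrent unit.

    r = sigmoid(x W_r + h U_r + b_r); z = sigmoid(x W_z + h U_z + b_z);
    n = tanh(x W_n + r * (h U_n) + b_n); h' = (1 - z) * n + z * h.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.Wx = _glorot(rng, in_dim, 3 * hidden, (in_dim, 3 * hidden))
        self.Wh = _glorot(rng, hidden, 3 * hidden, (hidden, 3 * hidden))
        self.b = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.hidden = hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.hidden
        gx = x @ self.Wx + self.b
        gh = h @ self.Wh
        gx_r, gx_z, gx_n = _narrow3(gx, d)
        gh_r, gh_z, gh_n = _narrow3(gh, d)
        r = (gx_r + gh_r).sigmoid()
        z = (gx_z + gh_z).sigmoid()
        n = (gx_n + r * gh_n).tanh()
        return (1.0 - z) * n + z * h


_NARROW_CACHE: dict[int, tuple] = {}


def _narrow3(t: Tensor, d: int) -> tuple[Tensor, Tensor, Tensor]:
    """Split the last axis of `t` (size 3d) into three d-sized slices."""
    if d not in _NARROW_CACHE:
        eye = np.eye(d, dtype=DTYPE)
        mats = []
        for block in range(3):
            W = np.zeros((3 * d, d), dtype=DTYPE)
            W[block * d:(block + 1) * d, :] = eye
            mats.append(Tensor(W))
        _NARROW_CACHE[d] = tuple(mats)
    W0, W1, W2 = _NARROW_CACHE[d]
    return t @ W0, t @ W1, t @ W2


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, d_k: int,
                         mask: np.ndarray | None = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with optional additive mask.

    `mask` is boolean with True = *blocked* position; blocked positions get
    zero attention weight. Shapes broadcast over any leading (batch, head)
    axes; q: (..., Tq, d_k), k: (..., Tk, d_k), v: (..., Tk, dv).
    """
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
              ) * (1.0 / float(np.sqrt(d_k)))
    if mask is not None:
        scores = scores + Tensor(np.where(mask, np.float32(-1e9), np.float32(0.0)))
    return softmax(scores, axis=-1) @ v


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("model width must be divisible by head count")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        b, tq, d = q.shape
        qh, kh, vh = self._split(self.wq(q)), self._split(self.wk(k)), self._split(self.wv(v))
        if mask is not None and mask.ndim == 3:  # (b, Tq, Tk) -> add head axis
            mask = mask[:, None, :, :]
        out = scaled_dot_attention(qh, kh, vh, self.d_head, mask)
        out = out.transpose(0, 2, 1, 3).reshape(b, tq, d)
        return self.wo(out)


class FeedForward(Module):
    """Position-wise FFN with ReLU activation."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.w1 = Linear(dim, hidden, rng)
        self.w2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(self.drop(self.w1(x).relu()))


def sinusoidal_positions(n: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encodings, shape (n, dim)."""
    pos = np.arange(n)[:, None].astype(np.float64)
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(DTYPE)
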