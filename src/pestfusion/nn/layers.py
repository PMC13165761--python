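"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, conv1d, conv2d, softmax

__all__ = ["Module", "Linear", "Conv2d", "Conv1d", "LayerNorm", "Dropout",
           "MultiHeadAttention", "FeedForward"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = False

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, t in own.items():
            arr = np.asarray(state[k])
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {t.data.shape}")
            t.data = arr.astype(t.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(
            _glorot(rng, fan_in, c_out, (c_out, c_in, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = c_in * kernel
        self.weight = Tensor(_glorot(rng, fan_in, c_out, (c_out, c_in, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    """Normalization over the trailing axis with learned gain and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode, seeded externally."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * mask


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` parallel subspaces.

    Queries may come from a different token set than keys/values
    (cross-attention).  The attention weights of the last forward pass are
    kept on ``self.last_weights`` (shape B x heads x Nq x Nk) as a
    diagnostic.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 scaled: bool = True):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError(f"embedding dim {d} not divisible by "
                             f"{n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.scaled = scaled
        self.w_q = Linear(d, d, rng, bias=False)
        self.w_k = Linear(d, d, rng, bias=False)
        self.w_v = Linear(d, d, rng, bias=False)
        self.w_o = Linear(d, d, rng, bias=False)
        self.last_weights: np.ndarray | None = None

    def _split(self, t: Tensor, batch: int, n: int) -> Tensor:
        # (B, N, d) -> (B, H, N, d_head)
        return t.reshape(batch, n, self.n_heads, self.d_head).transpose(
            0, 2, 1, 3)

    def forward(self, query: Tensor, keyvalue: Tensor) -> Tensor:
        b, nq, _ = query.shape
        nk = keyvalue.shape[1]
        q = self._split(self.w_q(query), b, nq)
        k = self._split(self.w_k(keyvalue), b, nk)
        v = self._split(self.w_v(keyvalue), b, nk)
        logits = q @ k.swapaxes(-1, -2)
        if self.scaled:
            logits = logits * (1.0 / np.sqrt(self.d_head))
        weights = softmax(logits, axis=-1)
        self.last_weights = weights.data
        mixed = weights @ v  # (B, H, Nq, d_head)
        merged = mixed.transpose(0, 2, 1, 3).reshape(b, nq, self.d)
        return self.w_o(merged)


class FeedForward(Module):
    """Two-layer position-wise feed-forward block."""

    def __init__(self, d: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())
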