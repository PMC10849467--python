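"""Transformer building blocks on top of the autodiff core.

Initialization follows common deep-learning defaults for this architecture:
plain linear layers use Kaiming-uniform weights, attention projections use
Xavier-uniform weights, and all biases start at zero.  Blocks use the
original post-norm encoder ordering with ReLU feedforward.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, dropout, layer_norm, relu, softmax


def kaiming_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Module:
    """Tiny parameter-registry base class (named tensors, ordered)."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def register(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        tensor.name = name
        self._params[name] = tensor
        return tensor

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, init: str = "kaiming"):
        super().__init__()
        fn = kaiming_uniform if init == "kaiming" else xavier_uniform
        self.w = self.register("w", Tensor(fn(rng, d_in, d_out)))
        self.b = self.register("b", Tensor(np.zeros(d_out)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, d_model: int, n_heads: int, p_drop: float):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.p_drop = p_drop
        for name in ("q", "k", "v", "o"):
            self.add_child(name, Linear(rng, d_model, d_model, init="xavier"))

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(z: Tensor) -> Tensor:                     # (b, h, t, dh)
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q = split(self._children["q"](x))
        k = split(self._children["k"](x))
        v = split(self._children["v"](x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        attn = dropout(attn, self.p_drop, rng, training)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self._children["o"](ctx)


class EncoderBlock(Module):
    """Post-norm transformer encoder block with ReLU feedforward."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int,
                 p_drop: float, ln_eps: float):
        super().__init__()
        self.p_drop = p_drop
        self.ln_eps = ln_eps
        self.add_child("attn", MultiHeadSelfAttention(rng, d_model, n_heads, p_drop))
        self.add_child("ff1", Linear(rng, d_model, d_ff))
        self.add_child("ff2", Linear(rng, d_ff, d_model))
        self.ln1_w = self.register("ln1_w", Tensor(np.ones(d_model)))
        self.ln1_b = self.register("ln1_b", Tensor(np.zeros(d_model)))
        self.ln2_w = self.register("ln2_w", Tensor(np.ones(d_model)))
        self.ln2_b = self.register("ln2_b", Tensor(np.zeros(d_model)))

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        a = self._children["attn"](x, training, rng)
        x = layer_norm(x + dropout(a, self.p_drop, rng, training),
                       self.ln1_w, self.ln1_b, self.ln_eps)
        f = self._children["ff2"](
            dropout(relu(self._children["ff1"](x)), self.p_drop, rng, training)
        )
        x = layer_norm(x + dropout(f, self.p_drop, rng, training),
                       self.ln2_w, self.ln2_b, self.ln_eps)
        return x


def sinusoidal_positions(n_positions: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal positional code (base 10000), shape (n, d)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((n_positions, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe
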