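"""Network building blocks over the :mod:`nodulegp.tensor` engine."""

from __future__ import annotations

import numpy as np

from ..tensor import Tensor, conv2d, leaky_relu, relu, sigmoid

__all__ = ["Conv2d", "Linear", "InstanceNorm2d", "Module",
           "he_init", "leaky_relu", "relu", "sigmoid"]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Module:
    """Barebones parameter container."""

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
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int,
                 kernel: int = 3, stride: int = 1, pad: int = 1,
                 dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(he_init(rng, (out_ch, in_ch, kernel, kernel),
                                     fan_in, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_features: int,
                 out_features: int, dtype=np.float32):
        self.weight = Tensor(he_init(rng, (out_features, in_features),
                                     in_features, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, F) @ (F, O) + b
        return x @ _transpose(self.weight) + self.bias


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, t.requires_grad)
    if out.requires_grad:
        out._parents = (t,)
        out._backward = lambda g: t._accumulate(g.T)
    return out


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype),
                           requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta
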