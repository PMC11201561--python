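"""Predictor (U-Net-style) and Wasserstein critic networks.

The growth predictor maps a baseline 64x64 nodule patch to its predicted
1-year follow-up appearance (a "GP-nodule"). It is an encoder-decoder with
skip connections, instance normalization, leaky-ReLU encoder / ReLU decoder
and a sigmoid output, sized for single-CPU training on synthetic cohorts
(three resolution levels, 16 base channels by default).

The critic is a five-layer strided convolutional network with leaky-ReLU
activations, no normalization layers (they interact badly with the gradient
penalty) and a final linear head producing one unbounded score per patch.

Because the critic is piecewise linear, its input gradient can be written as
an explicit transpose pass with the activation masks held constant; that pass
is built as a differentiable graph (:meth:`Critic.input_gradient_graph`) so
the WGAN-GP penalty's parameter gradients come out of first-order backprop.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..simgrowth import ImagePatch
from ..tensor import (Tensor, concat, conv_transpose2d, leaky_relu, relu,
                      sigmoid, upsample_nearest)
from .layers import Conv2d, InstanceNorm2d, Linear, Module

__all__ = ["Critic", "GrowthPredictor", "FrozenModelError",
           "load_predictor", "predict_followup", "predictor_forward",
           "save_predictor", "patches_to_batch", "batch_to_patches"]


class FrozenModelError(RuntimeError):
    """Raised when training or mutating a frozen (deployment) predictor."""


def patches_to_batch(patches, dtype=np.float32) -> np.ndarray:
    """Stack ImagePatch / 2D arrays into an NCHW batch."""
    arrs = []
    for p in patches:
        a = p.values if isinstance(p, ImagePatch) else np.asarray(p)
        if a.ndim != 2:
            raise ValueError(f"expected 2D patches, got shape {a.shape}")
        arrs.append(a.astype(dtype))
    return np.stack(arrs)[:, None, :, :]


def batch_to_patches(batch: np.ndarray,
                     pixel_spacing_mm: float = 0.5) -> list[ImagePatch]:
    out = []
    for img in np.clip(np.asarray(batch, dtype=np.float64), 0.0, 1.0):
        v = img[0] if img.ndim == 3 else img
        out.append(ImagePatch(values=v, pixel_spacing_mm=pixel_spacing_mm,
                              side_mm=v.shape[0] * pixel_spacing_mm))
    return out


class GrowthPredictor(Module):
    """Encoder-decoder follow-up predictor with skip connections."""

    def __init__(self, seed: int = 0, base_channels: int = 16,
                 input_size: int = 64, instance_norm: bool = True,
                 residual: bool = True, dtype=np.float32):
        rng = np.random.default_rng(seed)
        c0, c1, c2 = base_channels, 2 * base_channels, 4 * base_channels
        self.descriptor = {
            "kind": "encoder-decoder-skip",
            "base_channels": base_channels,
            "levels": 3,
            "input_size": input_size,
            "instance_norm": instance_norm,
            "residual": residual,
            "seed": seed,
        }
        self.residual = residual
        self.frozen = False
        self.instance_norm = instance_norm
        self.enc0 = Conv2d(rng, 1, c0, dtype=dtype)
        self.enc1 = Conv2d(rng, c0, c1, stride=2, dtype=dtype)
        self.enc2 = Conv2d(rng, c1, c2, stride=2, dtype=dtype)
        self.bottleneck = Conv2d(rng, c2, c2, dtype=dtype)
        self.dec1 = Conv2d(rng, c2, c1, dtype=dtype)
        self.dec1_merge = Conv2d(rng, 2 * c1, c1, dtype=dtype)
        self.dec0 = Conv2d(rng, c1, c0, dtype=dtype)
        self.dec0_merge = Conv2d(rng, 2 * c0, c0, dtype=dtype)
        self.head = Conv2d(rng, c0, 1, dtype=dtype)
        if residual:
            # zero-init head: the model starts as the identity map in logit
            # space and learns only the change between baseline and follow-up
            self.head.weight.data = np.zeros_like(self.head.weight.data)
            self.head.bias.data = np.zeros_like(self.head.bias.data)
        if instance_norm:
            self.n_enc1 = InstanceNorm2d(c1, dtype=dtype)
            self.n_enc2 = InstanceNorm2d(c2, dtype=dtype)
            self.n_dec1 = InstanceNorm2d(c1, dtype=dtype)
            self.n_dec0 = InstanceNorm2d(c0, dtype=dtype)

    def _norm(self, name: str, x: Tensor) -> Tensor:
        return getattr(self, name)(x) if self.instance_norm else x

    def forward(self, x) -> Tensor:
        """Predict follow-up patches for an NCHW batch; output in (0, 1)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 4 or x.shape[1] != 1 \
                or x.shape[2] != self.descriptor["input_size"]:
            raise ValueError(f"expected (B,1,{self.descriptor['input_size']},"
                             f"{self.descriptor['input_size']}), got {x.shape}")
        e0 = leaky_relu(self.enc0(x))
        e1 = leaky_relu(self._norm("n_enc1", self.enc1(e0)))
        e2 = leaky_relu(self._norm("n_enc2", self.enc2(e1)))
        b = relu(self.bottleneck(e2))
        d1 = relu(self._norm("n_dec1", self.dec1(upsample_nearest(b))))
        d1 = relu(self.dec1_merge(concat([d1, e1], axis=1)))
        d0 = relu(self._norm("n_dec0", self.dec0(upsample_nearest(d1))))
        d0 = relu(self.dec0_merge(concat([d0, e0], axis=1)))
        delta = self.head(d0)
        if self.residual:
            eps = 1e-4
            xc = np.clip(x.data, eps, 1.0 - eps)
            logit_x = Tensor(np.log(xc / (1.0 - xc)).astype(x.dtype))
            return sigmoid(delta + logit_x)
        return sigmoid(delta)

    def freeze(self) -> "GrowthPredictor":
        self.frozen = True
        for p in self.parameters():
            p.requires_grad = False
        return self

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self._named_parameters()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        if self.frozen:
            raise FrozenModelError("cannot load weights into a frozen model")
        for name, p in self._named_parameters():
            p.data = np.array(arrays[name], dtype=p.data.dtype)

    def _named_parameters(self):
        for attr, value in sorted(self.__dict__.items()):
            if isinstance(value, Module):
                for sub, t in sorted(value.__dict__.items()):
                    if isinstance(t, Tensor):
                        yield f"{attr}.{sub}", t


class Critic(Module):
    """Five-layer strided convolutional Wasserstein critic."""

    def __init__(self, seed: int = 0, widths=(16, 32, 64, 128, 256),
                 input_size: int = 64, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.descriptor = {"kind": "strided-dcnn-critic",
                           "widths": list(widths),
                           "input_size": input_size, "seed": seed}
        self.alpha = 0.2
        self.convs = []
        in_ch, size = 1, input_size
        for w in widths:
            self.convs.append(Conv2d(rng, in_ch, w, stride=2, dtype=dtype))
            in_ch, size = w, size // 2
        if size < 1:
            raise ValueError("too many critic layers for the input size")
        self.flat_shape = (in_ch, size, size)
        self.head = Linear(rng, in_ch * size * size, 1, dtype=dtype)

    def forward(self, x) -> Tensor:
        """One unbounded real score per patch (shape (B,))."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 4 or x.shape[2] != self.descriptor["input_size"]:
            raise ValueError(f"expected NCHW {self.descriptor['input_size']}-"
                             f"pixel batch, got {x.shape}")
        h = x
        for conv in self.convs:
            h = leaky_relu(conv(h), self.alpha)
        flat = h.reshape(h.shape[0], -1)
        return self.head(flat).reshape(h.shape[0])

    # ------------------------------------------------------- input gradient
    def _forward_masks(self, x_data: np.ndarray) -> list[np.ndarray]:
        """Numeric forward pass recording leaky-ReLU derivative masks."""
        from ..tensor import _conv_forward

        masks = []
        h = x_data
        for conv in self.convs:
            pre = _conv_forward(h, conv.weight.data, conv.stride, conv.pad)
            pre = pre + conv.bias.data.reshape(1, -1, 1, 1)
            masks.append(np.where(pre > 0, 1.0, self.alpha).astype(h.dtype))
            h = np.where(pre > 0, pre, self.alpha * pre)
        return masks

    def input_gradient_graph(self, x_data: np.ndarray) -> Tensor:
        """Differentiable graph of grad_x D(x) with activation masks frozen.

        The critic is piecewise linear, so for fixed masks the input gradient
        is linear in the weights; its own gradient with respect to the weights
        (needed by the WGAN-GP penalty) is then exact almost everywhere.
        """
        x_data = np.asarray(x_data)
        b = x_data.shape[0]
        masks = self._forward_masks(x_data)
        # dD/d(flat features) = head weight row, replicated per sample
        ones = Tensor(np.ones((b, 1), dtype=x_data.dtype))
        g = (ones @ self.head.weight).reshape(b, *self.flat_shape)
        shapes = [x_data.shape] + [m.shape for m in masks[:-1]]
        for conv, mask, out_shape in zip(reversed(self.convs),
                                         reversed(masks), reversed(shapes)):
            g = g * Tensor(mask)
            g = conv_transpose2d(g, conv.weight, conv.stride, conv.pad,
                                 out_shape[2:])
        return g

    def input_gradient(self, x_data: np.ndarray) -> np.ndarray:
        """Numeric grad_x D(x) via ordinary backprop (oracle route)."""
        x = Tensor(np.asarray(x_data), requires_grad=True)
        scores = self.forward(x)
        scores.sum().backward()
        return x.grad


def predictor_forward(model: GrowthPredictor, baseline) -> ImagePatch:
    """Predict one follow-up patch from one baseline patch."""
    batch = patches_to_batch([baseline])
    out = model.forward(batch).data
    return batch_to_patches(out)[0]


def predict_followup(model: GrowthPredictor, baselines) -> list[ImagePatch]:
    """Deployment entry point: batch prediction with a frozen predictor."""
    if not model.frozen:
        raise FrozenModelError(
            "predict_followup requires a frozen predictor; call freeze()")
    if len(baselines) == 0:
        return []
    out = model.forward(patches_to_batch(baselines)).data
    return batch_to_patches(out)


# ----------------------------------------------------------------- checkpoints
def save_predictor(model: GrowthPredictor, path: str | Path,
                   extra: dict | None = None) -> None:
    """Self-describing checkpoint: architecture descriptor + weights."""
    arrays = model.state_arrays()
    meta = {"descriptor": model.descriptor, "extra": extra or {},
            "format": 1}
    np.savez(path, __meta__=json.dumps(meta),
             **{k: v for k, v in arrays.items()})


def load_predictor(path: str | Path, freeze: bool = True) -> GrowthPredictor:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        desc = meta["descriptor"]
        model = GrowthPredictor(seed=desc["seed"],
                                base_channels=desc["base_channels"],
                                input_size=desc["input_size"],
                                instance_norm=desc["instance_norm"],
                                residual=desc.get("residual", True))
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__meta__"})
    if freeze:
        model.freeze()
    return model
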