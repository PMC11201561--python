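"""Feature extractors for the learned perceptual loss.

The perceptual term compares two patches in the feature space of a small
frozen ResNet-style convolutional network (stem + two residual stages;
features are taken at the end of each stage and channel-normalized, as in
LPIPS-style perceptual distances). No pretrained weights are shipped or
downloaded: the extractor is randomly initialized from a fixed seed and
frozen, which is a standard and surprisingly effective choice for perceptual
distances, and keeps runs fully reproducible offline. The seed is recorded in
the run manifest.
"""

from __future__ import annotations

import numpy as np

from ..tensor import Tensor, conv2d, relu
from .layers import Conv2d, Module

__all__ = ["IdentityExtractor", "RandomResNetExtractor"]


class IdentityExtractor:
    """Returns the raw image as its only feature map (testing/reduction)."""

    normalize = False

    def __call__(self, x: Tensor) -> list[Tensor]:
        return [x if isinstance(x, Tensor) else Tensor(x)]


class RandomResNetExtractor(Module):
    """Frozen two-stage residual feature extractor with fixed random weights."""

    def __init__(self, seed: int = 0, base_channels: int = 8,
                 normalize: bool = True, dtype=np.float32):
        rng = np.random.default_rng(seed)
        c1, c2 = base_channels, 2 * base_channels
        self.normalize = normalize
        self.eps = 1e-8
        self.stem = Conv2d(rng, 1, c1, stride=2, dtype=dtype)
        self.s1a = Conv2d(rng, c1, c1, dtype=dtype)
        self.s1b = Conv2d(rng, c1, c1, dtype=dtype)
        self.down = Conv2d(rng, c1, c2, stride=2, dtype=dtype)
        self.s2a = Conv2d(rng, c2, c2, dtype=dtype)
        self.s2b = Conv2d(rng, c2, c2, dtype=dtype)
        for p in self.parameters():
            p.requires_grad = False

    def _unit_normalize(self, f: Tensor) -> Tensor:
        norm = ((f * f).sum(axis=1, keepdims=True) + self.eps).sqrt()
        return f / norm

    def __call__(self, x: Tensor) -> list[Tensor]:
        x = x if isinstance(x, Tensor) else Tensor(x)
        h = relu(self.stem(x))
        h = relu(h + self.s1b(relu(self.s1a(h))))
        f1 = h
        h = relu(self.down(h))
        h = relu(h + self.s2b(relu(self.s2a(h))))
        f2 = h
        if self.normalize:
            return [self._unit_normalize(f1), self._unit_normalize(f2)]
        return [f1, f2]
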