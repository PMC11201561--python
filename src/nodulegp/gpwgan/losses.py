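"""Loss functions for adversarial follow-up prediction.

Generator side combines four terms,

    LG = lambda1 * L1 + lambda2 * L_SSIM + lambda3 * L_LP + lambda4 * L_A,

where L1 is mean absolute pixel error, L_SSIM = 1 - SSIM (11x11 Gaussian
window, sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1), L_LP is a learned
perceptual feature distance, and L_A = -E[D(GX)] rewards fooling the critic.

Critic side is the Wasserstein loss with gradient penalty on images
interpolated between real follow-ups XF and generated patches GX,

    x_hat = t * XF + (1 - t) * GX,  t ~ Unif(0, 1),
    LD = -E[D(GX)] + E[D(XF)] + lambdaD * E[(||grad_{x_hat} D(x_hat)|| - 1)^2].

Two sign conventions are supported for the Wasserstein terms. "printed" is
the form above; under it the critic and the generator both push D(GX) upward,
so it is not usable for adversarial training. "standard" flips the two
expectation signs (critic minimizes E[D(GX)] - E[D(XF)], i.e. maximizes real
minus fake) and is what the trainer uses by default.

All functions return :class:`~nodulegp.tensor.Tensor` scalars (call
``.item()`` for a float) and accept ImagePatch, ndarray or Tensor inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..simgrowth import ImagePatch
from ..tensor import Tensor, as_tensor, conv2d

__all__ = ["LossWeights", "discriminator_loss", "generative_loss",
           "gradient_penalty", "interpolate", "loss_adversarial", "loss_l1",
           "loss_perceptual", "loss_ssim"]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the four generator terms and the gradient penalty."""

    lambda1: float = 100.0  # L1
    lambda2: float = 10.0   # 1 - SSIM
    lambda3: float = 1.0    # learned perceptual
    lambda4: float = 1.0    # adversarial
    lambda_d: float = 10.0  # gradient penalty

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda_d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and >= 0")


def _to_batch_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        t = x
    elif isinstance(x, ImagePatch):
        t = Tensor(x.values[None, None])
    else:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        t = Tensor(arr)
    if t.ndim != 4:
        raise ValueError(f"expected image batch, got shape {t.shape}")
    return t


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


# ------------------------------------------------------------------ L1 / SSIM
def loss_l1(generated, target) -> Tensor:
    """Mean absolute pixel difference."""
    a, b = _to_batch_tensor(generated), _to_batch_tensor(target)
    _check_same_shape(a, b)
    return (a - b).abs().mean()


def _gaussian_kernel(size: int, sigma: float, dtype) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return (k / k.sum()).astype(dtype)[None, None]


def loss_ssim(generated, target, window: int = 11, sigma: float = 1.5,
              k1: float = 0.01, k2: float = 0.03,
              data_range: float = 1.0) -> Tensor:
    """1 - mean windowed SSIM; lies in [0, 2] since SSIM is in [-1, 1]."""
    a, b = _to_batch_tensor(generated), _to_batch_tensor(target)
    _check_same_shape(a, b)
    if a.shape[2] < window or a.shape[3] < window:
        raise ValueError(f"patch smaller than the {window}x{window} window")
    kern = Tensor(_gaussian_kernel(window, sigma, a.data.dtype))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def smooth(x: Tensor) -> Tensor:
        return conv2d(x, kern, stride=1, pad=0)

    mu_a, mu_b = smooth(a), smooth(b)
    var_a = smooth(a * a) - mu_a * mu_a
    var_b = smooth(b * b) - mu_b * mu_b
    cov = smooth(a * b) - mu_a * mu_b
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2))
    return 1.0 - ssim_map.mean()


# ------------------------------------------------------------- perceptual / LA
def loss_perceptual(generated, target, feature_extractor) -> Tensor:
    """Mean squared feature distance summed over the extractor's layers."""
    a, b = _to_batch_tensor(generated), _to_batch_tensor(target)
    _check_same_shape(a, b)
    total = None
    for fa, fb in zip(feature_extractor(a), feature_extractor(b)):
        d = fa - fb
        term = (d * d).mean()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("feature extractor produced no feature maps")
    return total


def loss_adversarial(critic_scores) -> Tensor:
    """Generator-side adversarial term: -mean critic score on generated."""
    scores = critic_scores if isinstance(critic_scores, Tensor) \
        else Tensor(np.asarray(critic_scores, dtype=float))
    if scores.data.size == 0:
        raise ValueError("empty critic score list")
    return -scores.mean()


def generative_loss(generated, target, critic_scores, weights: LossWeights,
                    feature_extractor) -> tuple[Tensor, dict[str, Tensor]]:
    """Weighted four-term generator loss plus the unweighted term breakdown."""
    terms = {
        "l1": loss_l1(generated, target),
        "ssim": loss_ssim(generated, target),
        "perceptual": loss_perceptual(generated, target, feature_extractor),
        "adversarial": loss_adversarial(critic_scores),
    }
    total = (weights.lambda1 * terms["l1"] + weights.lambda2 * terms["ssim"]
             + weights.lambda3 * terms["perceptual"]
             + weights.lambda4 * terms["adversarial"])
    return total, terms


# --------------------------------------------------------------- critic side
def interpolate(real_batch: np.ndarray, generated_batch: np.ndarray,
                t_samples: np.ndarray) -> np.ndarray:
    """x_hat = t * XF + (1 - t) * GX, one t per pair."""
    real = np.asarray(real_batch)
    fake = np.asarray(generated_batch)
    t = np.asarray(t_samples, dtype=real.dtype)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch: {real.shape} vs {fake.shape}")
    if t.ndim != 1 or t.shape[0] != real.shape[0]:
        raise ValueError("need exactly one t per image pair")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("t samples must lie in [0, 1]")
    tb = t.reshape(-1, *([1] * (real.ndim - 1)))
    return tb * real + (1.0 - tb) * fake


def _penalty_from_grad_graph(grad: Tensor) -> Tensor:
    b = grad.shape[0]
    sq = (grad * grad).reshape(b, -1).sum(axis=1)
    norms = (sq + 1e-12).sqrt()
    dev = norms - 1.0
    return (dev * dev).mean()


def gradient_penalty(critic, real_batch, generated_batch,
                     t_samples) -> Tensor:
    """Mean (||grad_{x_hat} D(x_hat)||_2 - 1)^2, unscaled by lambdaD.

    Works with any critic exposing ``forward(Tensor) -> Tensor``: the input
    gradient is obtained by ordinary backpropagation. (The trainer instead
    uses :meth:`Critic.input_gradient_graph` so the penalty contributes
    parameter gradients.)
    """
    xhat = interpolate(np.asarray(real_batch), np.asarray(generated_batch),
                       t_samples)
    x = Tensor(xhat, requires_grad=True)
    scores = critic.forward(x)
    scores.sum().backward()
    return _penalty_from_grad_graph(Tensor(x.grad))


def discriminator_loss(critic, real_batch, generated_batch,
                       weights: LossWeights, t_samples,
                       sign_convention: str = "printed",
                       differentiable_penalty: bool = False
                       ) -> tuple[Tensor, dict[str, Tensor]]:
    """Critic loss: Wasserstein terms plus lambdaD * gradient penalty.

    With ``differentiable_penalty=True`` the penalty is built from the
    critic's mask-frozen transpose pass so that backpropagating the returned
    total yields WGAN-GP parameter gradients (requires a
    :class:`~nodulegp.gpwgan.models.Critic`).
    """
    if sign_convention not in ("printed", "standard"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    real = np.asarray(real_batch)
    fake = np.asarray(generated_batch)
    d_fake = critic.forward(fake if isinstance(fake, Tensor) else Tensor(fake))
    d_real = critic.forward(real if isinstance(real, Tensor) else Tensor(real))
    if sign_convention == "printed":
        wasserstein = -d_fake.mean() + d_real.mean()
    else:
        wasserstein = d_fake.mean() - d_real.mean()
    if differentiable_penalty:
        xhat = interpolate(real, fake, t_samples)
        penalty = _penalty_from_grad_graph(critic.input_gradient_graph(xhat))
    else:
        penalty = gradient_penalty(critic, real, fake, t_samples)
    total = wasserstein + weights.lambda_d * penalty
    return total, {"wasserstein": wasserstein, "penalty": penalty,
                   "d_fake_mean": d_fake.mean(), "d_real_mean": d_real.mean()}
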