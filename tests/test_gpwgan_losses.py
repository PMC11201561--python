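"""Generator and critic loss terms: identities, oracles, closed forms."""

import numpy as np
import pytest

from nodulegp.gpwgan import (IdentityExtractor, LossWeights,
                             RandomResNetExtractor, discriminator_loss,
                             generative_loss, gradient_penalty, interpolate,
                             loss_adversarial, loss_l1, loss_perceptual,
                             loss_ssim)
from nodulegp.gpwgan.models import Critic
from nodulegp.tensor import Tensor

rng = np.random.default_rng(99)


class LinearCritic:
    """D(x) = <w, x> per sample; grad_x D = w everywhere."""

    def __init__(self, w: np.ndarray):
        self.w = Tensor(np.asarray(w, dtype=float).ravel())

    def forward(self, x: Tensor) -> Tensor:
        flat = x.reshape(x.shape[0], -1)
        return flat @ self.w.reshape(-1, 1)


class ConstantCritic:
    """D(x) = c for every input; grad_x D = 0."""

    def __init__(self, c: float):
        self.c = c

    def forward(self, x: Tensor) -> Tensor:
        flat = x.reshape(x.shape[0], -1)
        return flat.sum(axis=1) * 0.0 + self.c


# ------------------------------------------------------------------------ L1
def test_l1_identities_and_bruteforce_oracle():
    a = rng.random((64, 64))
    assert loss_l1(a, a).item() == 0.0
    assert loss_l1(np.zeros((64, 64)), np.ones((64, 64))).item() == 1.0
    b = rng.random((64, 64))
    brute = sum(abs(a[i, j] - b[i, j]) for i in range(64)
                for j in range(64)) / 4096
    assert loss_l1(a, b).item() == pytest.approx(brute, rel=1e-12)
    with pytest.raises(ValueError):
        loss_l1(a, rng.random((32, 32)))


# ---------------------------------------------------------------------- SSIM
def _single_window_ssim(a, b, sigma=1.5, k1=0.01, k2=0.03):
    """Direct SSIM of one 11x11 window from the definition."""
    ax = np.arange(11) - 5.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    w = np.outer(g, g)
    w /= w.sum()
    mu_a, mu_b = (w * a).sum(), (w * b).sum()
    var_a = (w * a * a).sum() - mu_a ** 2
    var_b = (w * b * b).sum() - mu_b ** 2
    cov = (w * a * b).sum() - mu_a * mu_b
    c1, c2 = k1 ** 2, k2 ** 2
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))


def test_ssim_loss_identities_bounds_and_single_window_oracle():
    a = rng.random((64, 64))
    assert loss_ssim(a, a).item() == pytest.approx(0.0, abs=1e-12)
    for _ in range(5):
        u, v = rng.random((64, 64)), rng.random((64, 64))
        assert 0.0 <= loss_ssim(u, v).item() <= 2.0
    # fixed constant-plus-gradient 11x11 patches -> single conv output window
    gx = np.linspace(0, 1, 11)
    pa = 0.4 + 0.3 * np.tile(gx, (11, 1))
    pb = 0.5 + 0.2 * np.tile(gx[::-1], (11, 1))
    ours = 1.0 - loss_ssim(pa, pb).item()
    assert ours == pytest.approx(_single_window_ssim(pa, pb), rel=1e-9)


def test_ssim_loss_agrees_with_skimage_reference():
    from skimage.metrics import structural_similarity

    a = rng.random((64, 64))
    b = np.clip(a + 0.15 * rng.standard_normal((64, 64)), 0, 1)
    ref = structural_similarity(a, b, win_size=11, gaussian_weights=True,
                                sigma=1.5, use_sample_covariance=False,
                                data_range=1.0)
    assert 1.0 - loss_ssim(a, b).item() == pytest.approx(ref, abs=1e-10)


# ---------------------------------------------------------------- perceptual
def test_perceptual_loss_zero_on_identical_and_nonnegative():
    extractor = RandomResNetExtractor(seed=0)
    a = rng.random((2, 1, 64, 64)).astype(np.float32)
    assert loss_perceptual(a, a.copy(), extractor).item() == 0.0
    b = rng.random((2, 1, 64, 64)).astype(np.float32)
    assert loss_perceptual(a, b, extractor).item() >= 0.0


def test_perceptual_identity_extractor_reduces_to_mse():
    a, b = rng.random((64, 64)), rng.random((64, 64))
    brute = float(np.mean((a - b) ** 2))
    got = loss_perceptual(a, b, IdentityExtractor()).item()
    assert got == pytest.approx(brute, rel=1e-12)


# --------------------------------------------------------------- adversarial
def test_adversarial_loss_is_negative_mean_score():
    assert loss_adversarial([0.0, 0.0]).item() == 0.0
    assert loss_adversarial([1.0, 3.0]).item() == -2.0
    scores = rng.standard_normal(17)
    assert loss_adversarial(scores).item() == pytest.approx(
        -scores.sum() / 17, rel=1e-12)
    with pytest.raises(ValueError):
        loss_adversarial([])


# ----------------------------------------------------------- composite LG
def test_generative_loss_recomposes_and_is_linear_in_weights():
    extractor = IdentityExtractor()
    gen = rng.random((2, 1, 64, 64))
    tgt = rng.random((2, 1, 64, 64))
    scores = rng.standard_normal(2)

    zero, _ = generative_loss(gen, tgt, scores, LossWeights(0, 0, 0, 0, 0),
                              extractor)
    assert zero.item() == 0.0

    l1_only, _ = generative_loss(gen, tgt, scores, LossWeights(1, 0, 0, 0, 0),
                                 extractor)
    assert l1_only.item() == pytest.approx(loss_l1(gen, tgt).item())

    total, terms = generative_loss(gen, tgt, scores,
                                   LossWeights(1, 1, 1, 1, 0), extractor)
    manual = (loss_l1(gen, tgt).item() + loss_ssim(gen, tgt).item()
              + loss_perceptual(gen, tgt, extractor).item()
              + loss_adversarial(scores).item())
    assert total.item() == pytest.approx(manual, rel=1e-10)

    # linearity in each lambda: doubling one weight adds exactly one term
    for i, key in enumerate(["l1", "ssim", "perceptual", "adversarial"]):
        lam = [1.0, 1.0, 1.0, 1.0]
        lam[i] = 2.0
        doubled, _ = generative_loss(gen, tgt, scores,
                                     LossWeights(*lam, 0), extractor)
        assert doubled.item() - total.item() == pytest.approx(
            terms[key].item(), rel=1e-9, abs=1e-12)


# ------------------------------------------------------------- interpolation
def test_interpolation_endpoints_are_bitwise_exact():
    real = rng.random((4, 1, 8, 8))
    fake = rng.random((4, 1, 8, 8))
    ones = interpolate(real, fake, np.ones(4))
    zeros = interpolate(real, fake, np.zeros(4))
    np.testing.assert_array_equal(ones, real)
    np.testing.assert_array_equal(zeros, fake)
    with pytest.raises(ValueError):
        interpolate(real, fake, np.array([0.5, 1.2, 0.0, 0.1]))
    with pytest.raises(ValueError):
        interpolate(real, fake, np.array([0.5, 0.5]))


# ---------------------------------------------------------- gradient penalty
def test_gradient_penalty_closed_form_constant_critic():
    real = rng.random((3, 1, 8, 8))
    fake = rng.random((3, 1, 8, 8))
    t = rng.random(3)
    pen = gradient_penalty(ConstantCritic(2.5), real, fake, t)
    assert pen.item() == pytest.approx(1.0, abs=1e-5)  # (0 - 1)^2


def test_gradient_penalty_closed_form_linear_critic():
    w = rng.standard_normal(64) * 0.3
    real = rng.random((5, 1, 8, 8))
    fake = rng.random((5, 1, 8, 8))
    t = rng.random(5)
    pen = gradient_penalty(LinearCritic(w), real, fake, t)
    expected = (np.linalg.norm(w) - 1.0) ** 2
    assert pen.item() == pytest.approx(expected, rel=1e-9)


def test_discriminator_loss_sign_conventions_and_constant_critic():
    real = rng.random((4, 1, 8, 8))
    fake = rng.random((4, 1, 8, 8))
    t = rng.random(4)
    weights = LossWeights(lambda_d=10.0)
    total, terms = discriminator_loss(ConstantCritic(3.0), real, fake,
                                      weights, t)
    # Wasserstein terms cancel (-c + c), penalty = 10 * 1
    assert total.item() == pytest.approx(10.0, abs=1e-4)

    # linear critic arranged so D(GX) = 1 and D(XF) = 2, lambdaD = 0
    f = real[0].size
    w = np.ones(f) / f
    fake1 = np.ones((1, 1, 8, 8))
    real2 = np.full((1, 1, 8, 8), 2.0)
    printed, _ = discriminator_loss(LinearCritic(w), real2, fake1,
                                    LossWeights(lambda_d=0.0), np.array([0.5]),
                                    sign_convention="printed")
    assert printed.item() == pytest.approx(1.0)  # -1 + 2
    standard, _ = discriminator_loss(LinearCritic(w), real2, fake1,
                                     LossWeights(lambda_d=0.0),
                                     np.array([0.5]),
                                     sign_convention="standard")
    assert standard.item() == pytest.approx(-1.0)


def test_discriminator_loss_parameter_gradient_matches_finite_differences():
    """Full LD gradient (incl. penalty) vs central differences at 1e-4."""
    crit = Critic(seed=3, widths=(2, 4), input_size=8, dtype=np.float64)
    real = rng.random((3, 1, 8, 8))
    fake = rng.random((3, 1, 8, 8))
    t = rng.random(3)
    weights = LossWeights(lambda_d=10.0)

    def total():
        return discriminator_loss(crit, real, fake, weights, t,
                                  differentiable_penalty=True)[0].item()

    crit.zero_grad()
    loss, _ = discriminator_loss(crit, real, fake, weights, t,
                                 differentiable_penalty=True)
    loss.backward()
    eps = 1e-6
    for p in crit.parameters()[:3]:
        idx = tuple(0 for _ in p.data.shape)
        orig = p.data[idx]
        p.data[idx] = orig + eps
        fp = total()
        p.data[idx] = orig - eps
        fm = total()
        p.data[idx] = orig
        fd = (fp - fm) / (2 * eps)
        assert p.grad[idx] == pytest.approx(fd, abs=1e-4)


def test_penalty_value_identical_between_graph_and_backprop_routes():
    crit = Critic(seed=4, widths=(2, 4), input_size=8, dtype=np.float64)
    xhat = rng.random((3, 1, 8, 8))
    g_graph = crit.input_gradient_graph(xhat).data
    g_num = crit.input_gradient(xhat)
    np.testing.assert_allclose(g_graph, g_num, atol=1e-12)
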