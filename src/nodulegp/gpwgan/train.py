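"""Alternating WGAN-GP training of the growth predictor.

Follows the usual WGAN-GP recipe: Adam with learning rate 1e-4 and momentum
parameters (0, 0.9), ``n_critic`` critic updates per generator update, and
gradient-penalty weight 10. One master seed fans out (via splitmix hashing)
to independent streams for parameter initialization, batch order, and the
interpolation coefficients t, so runs are bit-reproducible on a fixed
platform configuration.

Each iteration draws one minibatch: the critic takes ``n_critic`` steps on it
against the current (detached) predictions, then the predictor takes one step
on the composite generative loss. Per-term loss histories are recorded every
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..simgrowth import NodulePair, derive_seed
from ..tensor import Tensor
from .features import RandomResNetExtractor
from .losses import LossWeights, discriminator_loss, generative_loss
from .models import Critic, FrozenModelError, GrowthPredictor, patches_to_batch

__all__ = ["Adam", "TrainConfig", "TrainingDiverged", "TrainingState", "train"]


class TrainingDiverged(RuntimeError):
    """Raised on non-finite losses; carries the diagnostic state."""

    def __init__(self, message: str, state: "TrainingState"):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 200          # generator steps
    n_critic: int = 5
    batch_size: int = 8
    learning_rate: float = 2e-4    # standard image-to-image translation rate
    beta1: float = 0.0
    beta2: float = 0.9
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    sign_convention: str = "standard"  # see losses module: "printed" is
    # faithful to the defining equation but non-adversarial
    base_channels: int = 16
    critic_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    extractor_channels: int = 8
    input_size: int = 64


@dataclass
class TrainingState:
    iteration: int
    predictor: GrowthPredictor
    critic: Critic
    extractor: RandomResNetExtractor
    history: dict[str, list[float]]
    config: TrainConfig

    def check_consistent(self) -> bool:
        return all(len(v) == self.iteration for v in self.history.values())


class Adam:
    """Adam over a fixed parameter list (decoupled per-parameter slots)."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float,
                 beta2: float, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(dataset: list[NodulePair], config: TrainConfig | None = None
          ) -> TrainingState:
    """Train predictor and critic adversarially on baseline/follow-up pairs."""
    config = config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty training dataset")

    x = patches_to_batch([p.baseline for p in dataset])
    xf = patches_to_batch([p.followup for p in dataset])

    predictor = GrowthPredictor(seed=derive_seed(config.seed, 1),
                                base_channels=config.base_channels,
                                input_size=config.input_size)
    if predictor.frozen:
        raise FrozenModelError("cannot train a frozen predictor")
    critic = Critic(seed=derive_seed(config.seed, 2),
                    widths=config.critic_widths,
                    input_size=config.input_size)
    extractor = RandomResNetExtractor(seed=derive_seed(config.seed, 3),
                                      base_channels=config.extractor_channels)
    batch_rng = np.random.default_rng(derive_seed(config.seed, 4))
    t_rng = np.random.default_rng(derive_seed(config.seed, 5))

    opt_g = Adam(predictor.parameters(), config.learning_rate,
                 config.beta1, config.beta2)
    opt_c = Adam(critic.parameters(), config.learning_rate,
                 config.beta1, config.beta2)

    history: dict[str, list[float]] = {k: [] for k in (
        "l1", "ssim", "perceptual", "adversarial", "generator_total",
        "critic_total", "penalty", "critic_updates")}
    state = TrainingState(0, predictor, critic, extractor, history, config)

    n = x.shape[0]
    bs = min(config.batch_size, n)
    for it in range(config.iterations):
        idx = batch_rng.choice(n, size=bs, replace=n < bs)
        xb, xfb = x[idx], xf[idx]

        # critic steps on the current (detached) predictions
        fake = predictor.forward(xb).data
        critic_updates = 0
        d_total_val = penalty_val = float("nan")
        for _ in range(config.n_critic):
            critic.zero_grad()
            t = t_rng.uniform(0.0, 1.0, size=bs)
            d_total, d_terms = discriminator_loss(
                critic, xfb, fake, config.weights, t,
                sign_convention=config.sign_convention,
                differentiable_penalty=True)
            d_total_val = d_total.item()
            penalty_val = d_terms["penalty"].item()
            if not np.isfinite(d_total_val):
                state.iteration = it
                raise TrainingDiverged(
                    f"non-finite critic loss at iteration {it}", state)
            d_total.backward()
            opt_c.step()
            critic_updates += 1

        # one generator step
        predictor.zero_grad()
        gx = predictor.forward(xb)
        scores = critic.forward(gx)
        g_total, g_terms = generative_loss(gx, Tensor(xfb), scores,
                                           config.weights, extractor)
        g_total_val = g_total.item()
        if not np.isfinite(g_total_val):
            state.iteration = it
            raise TrainingDiverged(
                f"non-finite generator loss at iteration {it}", state)
        g_total.backward()
        opt_g.step()

        history["l1"].append(g_terms["l1"].item())
        history["ssim"].append(g_terms["ssim"].item())
        history["perceptual"].append(g_terms["perceptual"].item())
        history["adversarial"].append(g_terms["adversarial"].item())
        history["generator_total"].append(g_total_val)
        history["critic_total"].append(d_total_val)
        history["penalty"].append(penalty_val)
        history["critic_updates"].append(critic_updates)
        state.iteration = it + 1

    return state
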