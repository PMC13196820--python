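"""Denoising diffusion probabilistic model (DDPM) machinery for point sets.

Forward process: a Markov chain that gradually Gaussianizes a shape,

    q(X(t) | X(t-1)) = N( sqrt(1 - beta_t) X(t-1), beta_t I ),

whose t-step marginal has the closed form

    X(t) = sqrt(alpha_bar_t) X(0) + sqrt(1 - alpha_bar_t) eps,
    eps ~ N(0, I),

with alpha_t = 1 - beta_t and alpha_bar_t the running product. A network
eps_theta is trained to predict eps from (X(t), t) by plain L2 loss, and
ancestral sampling runs the learned reverse transitions

    p(X(t-1) | X(t)) = N( mu_theta(X(t), t), beta_t I ),
    mu_theta = (X(t) - beta_t / sqrt(1 - alpha_bar_t) * eps_theta) / sqrt(alpha_t).

Timesteps are 1-based: t runs from 1 to T, and alpha_bar_0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor
from .network import AttentionMask, NetworkConfig, NoisePredictor, build_attention_mask
from .shape_io import PointSet, ShapeDataset, mean_shape

__all__ = [
    "VarianceSchedule",
    "DiffusionConfig",
    "make_schedule",
    "forward_sample",
    "training_loss",
    "reverse_step",
    "sample",
    "train_noise_predictor",
    "TrainingResult",
]


@dataclass(frozen=True)
class VarianceSchedule:
    """beta_1..beta_T with derived alpha_t and cumulative alpha_bar_t."""

    betas: np.ndarray

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=np.float64)
        if betas.ndim != 1 or betas.size < 1:
            raise ValueError("betas must be a nonempty 1-D array")
        if np.any(betas <= 0) or np.any(betas >= 1):
            raise ValueError("betas must lie strictly in (0, 1)")
        object.__setattr__(self, "betas", betas)

    @property
    def T(self) -> int:
        return self.betas.size

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bars(self) -> np.ndarray:
        return np.cumprod(self.alphas)

    def alpha_bar(self, t) -> np.ndarray:
        """alpha_bar_t for 1-based t; alpha_bar_0 == 1 by convention."""
        t = np.asarray(t)
        ab = np.concatenate([[1.0], self.alpha_bars])
        return ab[t]


@dataclass(frozen=True)
class DiffusionConfig:
    T: int = 1000
    schedule_kind: str = "linear"
    beta_start: float = 1e-4
    beta_end: float = 0.02
    sampler_final_noise_off: bool = True

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (0 < self.beta_start <= self.beta_end < 1):
            raise ValueError("need 0 < beta_start <= beta_end < 1")
        if self.schedule_kind not in ("linear", "cosine"):
            raise ValueError("schedule_kind must be 'linear' or 'cosine'")


def make_schedule(config: DiffusionConfig) -> VarianceSchedule:
    if config.schedule_kind == "linear":
        betas = np.linspace(config.beta_start, config.beta_end, config.T)
    else:  # cosine: betas derived from a squared-cosine alpha_bar curve
        s = 0.008
        steps = np.arange(config.T + 1) / config.T
        ab = np.cos((steps + s) / (1 + s) * np.pi / 2) ** 2
        ab /= ab[0]
        betas = np.clip(1.0 - ab[1:] / ab[:-1], 1e-8, 0.999)
    return VarianceSchedule(betas=betas)


def _as_array(x) -> tuple[np.ndarray, bool]:
    if isinstance(x, PointSet):
        return x.coords, True
    return np.asarray(x, dtype=np.float64), False


def _check_t(t, T):
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > T):
        raise ValueError(f"t must lie in 1..{T}")
    return t


def forward_sample(x0, t, eps, sched: VarianceSchedule):
    """Closed-form forward marginal sqrt(ab_t) x0 + sqrt(1 - ab_t) eps.

    Accepts a PointSet or array; with batched input (B, N, 3), ``t`` may be
    a (B,) vector. Index order is preserved.
    """
    arr, is_ps = _as_array(x0)
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != arr.shape:
        raise ValueError(f"eps shape {eps.shape} does not match x0 {arr.shape}")
    t = _check_t(t, sched.T)
    ab = np.asarray(sched.alpha_bar(t), dtype=np.float64)
    if arr.ndim == 3 and ab.ndim == 1:
        ab = ab[:, None, None]
    out = np.sqrt(ab) * arr + np.sqrt(1.0 - ab) * eps
    return PointSet(out) if is_ps else out


def training_loss(predictor, x0, t, eps, sched: VarianceSchedule, label=None) -> Tensor:
    """L2 noise-prediction loss || eps - eps_theta(X(t), t) ||^2, reduced by
    the mean over batch, points and coordinates; differentiable w.r.t. the
    predictor's parameters."""
    arr, _ = _as_array(x0)
    xt = forward_sample(arr, t, eps, sched)
    pred = predictor.forward(xt, t, label)
    diff = pred - Tensor(np.asarray(eps, dtype=np.float64))
    return (diff * diff).mean()


def reverse_step(xt, t: int, eps_hat, sched: VarianceSchedule, noise=None):
    """One ancestral sampling step X(t) -> X(t-1).

    mu = (xt - beta_t / sqrt(1 - ab_t) * eps_hat) / sqrt(alpha_t), plus
    sqrt(beta_t) * noise (noise=None means no noise is added).
    """
    arr, is_ps = _as_array(xt)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    t = int(_check_t(t, sched.T))
    beta = sched.betas[t - 1]
    alpha = 1.0 - beta
    ab = sched.alpha_bar(t)
    mu = (arr - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)
    if noise is not None:
        mu = mu + np.sqrt(beta) * np.asarray(noise, dtype=np.float64)
    return PointSet(mu) if is_ps else mu


def sample(
    predictor,
    n_samples: int,
    sched: VarianceSchedule,
    label=None,
    rng=None,
    final_noise_off: bool = True,
) -> ShapeDataset:
    """Ancestral sampling: X(T) ~ N(0, I), then reverse steps t = T..1.

    ``label`` (an integer class index, or None) conditions every step when
    the predictor is conditional. Deterministic given the RNG.
    """
    rng = np.random.default_rng(rng)
    n_pts = predictor.n_points
    x = rng.standard_normal((n_samples, n_pts, 3))
    labels = None if label is None else np.full(n_samples, int(label))
    for t in range(sched.T, 0, -1):
        eps_hat = predictor.predict(x, np.full(n_samples, t), labels)
        add_noise = not (t == 1 and final_noise_off)
        noise = rng.standard_normal(x.shape) if add_noise else None
        x = reverse_step(x, t, eps_hat, sched, noise)
    return ShapeDataset(x, labels=labels)


@dataclass
class TrainingResult:
    predictor: NoisePredictor
    losses: np.ndarray
    label_names: tuple | None


def train_noise_predictor(
    data: ShapeDataset,
    net_config: NetworkConfig | None = None,
    diff_config: DiffusionConfig | None = None,
    n_steps: int = 4000,
    batch_size: int = 64,
    lr: float = 2e-3,
    lr_decay: bool = True,
    seed: int = 0,
    conditional: bool = False,
    mask: AttentionMask | None = None,
) -> TrainingResult:
    """Train an eps-prediction network on a (normalized) shape dataset.

    Each step draws a minibatch of shapes, a uniform timestep per shape and
    fresh Gaussian noise, and takes one Adam step on the L2 loss; with
    ``lr_decay`` the learning rate follows a cosine ramp down to 10% of
    ``lr``. The attention mask is built from the training mean shape unless
    supplied. Class labels, when used, are encoded in sorted order.
    """
    rng = np.random.default_rng(seed)
    diff_config = diff_config or DiffusionConfig()
    sched = make_schedule(diff_config)

    label_names, label_idx = None, None
    if conditional:
        if data.labels is None:
            raise ValueError("conditional training requires labels")
        label_names = tuple(sorted(set(data.labels.tolist())))
        lut = {name: i for i, name in enumerate(label_names)}
        label_idx = np.array([lut[v] for v in data.labels.tolist()])

    if net_config is None:
        net_config = NetworkConfig(n_points=data.n_points, conditional=conditional)
    if mask is None:
        mask = build_attention_mask(mean_shape(data), net_config.attention_k)
    net = NoisePredictor(net_config, mask, rng=rng.integers(2 ** 31))
    opt = Adam(net.parameters(), lr=lr)

    coords = data.coords
    n = coords.shape[0]
    losses = np.empty(n_steps)
    for step in range(n_steps):
        if lr_decay:
            opt.lr = lr * (0.1 + 0.45 * (1.0 + np.cos(np.pi * step / n_steps)))
        idx = rng.integers(n, size=min(batch_size, n))
        x0 = coords[idx]
        t = rng.integers(1, sched.T + 1, size=x0.shape[0])
        eps = rng.standard_normal(x0.shape)
        lbl = None if label_idx is None else label_idx[idx]
        loss = training_loss(net, x0, t, eps, sched, label=lbl)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses[step] = loss.data
    return TrainingResult(predictor=net, losses=losses, label_names=label_names)
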