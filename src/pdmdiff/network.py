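"""U-Net-like noise-prediction backbone for ordered point sets.

The network maps a noisy shape (N x 3), a diffusion timestep and an
optional class label to a per-point noise estimate (N x 3). Its building
blocks:

* **RFT blocks** (row-wise feature transformation): one shared affine map
  applied to every point's feature row, modulated by a timestep/label
  dependent scale-shift (FiLM-style, ``h * (1 + scale) + shift``), then a
  SiLU nonlinearity. Weight sharing makes a lone RFT block permutation
  equivariant.
* **Correspondence embeddings**: a learned N x z parameter matrix added
  row-wise to the activations of the deepest encoder level. This is the
  one component that deliberately *breaks* permutation equivariance so the
  network can tie point index i to a consistent anatomical locus.
* **Masked self-attention** at the bottleneck: scaled dot-product attention
  whose logits are forbidden (-inf) outside the k-nearest-neighbor graph of
  the training mean shape, sharing information between spatial neighbors.
* **Skip connections** concatenating encoder features into the mirrored
  decoder levels.

Setting ``use_correspondence_embeddings=False`` gives the ablation model:
identical in every other respect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from .autodiff import Tensor, concat, silu, softmax
from .shape_io import PointSet

__all__ = [
    "NetworkConfig",
    "AttentionMask",
    "build_attention_mask",
    "rft_block",
    "add_correspondence_embedding",
    "masked_self_attention",
    "NoisePredictor",
    "timestep_embedding",
]

_NEG = -1e30  # additive mask value for forbidden attention pairs


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the noise predictor.

    ``level_widths`` are the encoder feature widths (the decoder mirrors
    them); the last width is the bottleneck width z, which is also the
    correspondence-embedding width. ``attention_k`` is the neighbor count
    of the bottleneck attention mask.
    """

    n_points: int
    level_widths: tuple[int, ...] = (64, 128, 256)
    attention_k: int = 50
    n_heads: int = 4
    use_correspondence_embeddings: bool = True
    conditional: bool = False
    n_classes: int = 2
    time_embed_dim: int = 64

    def __post_init__(self):
        if len(self.level_widths) == 0:
            raise ValueError("level_widths must be nonempty")
        if self.attention_k >= self.n_points:
            raise ValueError("attention_k must be < n_points")
        if self.level_widths[-1] % self.n_heads != 0:
            raise ValueError("bottleneck width must be divisible by n_heads")
        object.__setattr__(self, "level_widths", tuple(int(w) for w in self.level_widths))

    @property
    def embed_dim(self) -> int:
        return self.level_widths[-1]


@dataclass(frozen=True)
class AttentionMask:
    """Fixed (not learned) N x N boolean adjacency: row i may attend to its
    ``k`` nearest neighbors in the source mean shape, plus itself."""

    allowed: np.ndarray
    source_mean_shape: PointSet

    @property
    def additive(self) -> np.ndarray:
        return np.where(self.allowed, 0.0, _NEG)


def build_attention_mask(mean: PointSet, k: int) -> AttentionMask:
    """k-nearest-neighbor mask from the mean shape; deterministic, ties
    broken by lower point index; self always allowed."""
    coords = mean.coords
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < N={n}")
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    allowed = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    allowed[rows, order[:, :k].ravel()] = True
    np.fill_diagonal(allowed, True)
    return AttentionMask(allowed=allowed, source_mean_shape=mean)


def timestep_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (len(t), dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb


# ---------------------------------------------------------------------------
# functional forms of the three architectural primitives
# ---------------------------------------------------------------------------

def rft_block(features, weight, bias, scale, shift):
    """Row-wise feature transformation: shared affine map, FiLM scale-shift,
    SiLU. ``features`` is (..., N, d_in); ``scale``/``shift`` broadcast
    against the output (typically (..., 1, d_out))."""
    h = Tensor._wrap(features) @ weight + bias
    h = h * (1.0 + Tensor._wrap(scale)) + Tensor._wrap(shift)
    return silu(h)


def add_correspondence_embedding(features, embedding):
    """Row-wise addition of the learned per-index embedding (N x z)."""
    f = Tensor._wrap(features)
    e = Tensor._wrap(embedding)
    if f.shape[-2:] != e.shape[-2:]:
        raise ValueError(f"shape mismatch: {f.shape} vs {e.shape}")
    return f + e


def masked_self_attention(features, mask: AttentionMask, wq, wk, wv, wo, n_heads: int):
    """Multi-head scaled dot-product attention restricted to ``mask``,
    with a residual connection around the layer."""
    h = Tensor._wrap(features)
    d = h.shape[-1]
    if d % n_heads != 0:
        raise ValueError("feature width must be divisible by n_heads")
    dk = d // n_heads
    batch = h.shape[:-2]
    n = h.shape[-2]

    def split_heads(x):
        return x.reshape(*batch, n, n_heads, dk).swapaxes(-2, -3)  # (..., H, N, dk)

    q, k_, v = split_heads(h @ wq), split_heads(h @ wk), split_heads(h @ wv)
    logits = (q @ k_.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
    weights = softmax(logits, additive_mask=mask.additive)
    attended = (weights @ v).swapaxes(-2, -3).reshape(*batch, n, d)
    return h + attended @ wo


# ---------------------------------------------------------------------------
# the full predictor
# ---------------------------------------------------------------------------

def _linear_init(rng, d_in, d_out, gain=1.0):
    w = Tensor(rng.standard_normal((d_in, d_out)) * gain / np.sqrt(d_in), requires_grad=True)
    b = Tensor(np.zeros(d_out), requires_grad=True)
    return w, b


class NoisePredictor:
    """The trained backbone: (noisy shape, timestep, optional label) -> noise.

    Owns the correspondence embeddings and the fixed attention mask.
    Input and output are both (N, 3) (or batched (B, N, 3)).
    """

    def __init__(self, config: NetworkConfig, mask: AttentionMask, rng=None):
        if mask.allowed.shape[0] != config.n_points:
            raise ValueError("mask size must match n_points")
        rng = np.random.default_rng(rng)
        self.config = config
        self.mask = mask
        self.params: dict[str, Tensor] = {}
        p = self.params
        widths = config.level_widths
        te = config.time_embed_dim
        z = config.embed_dim

        p["cond_w1"], p["cond_b1"] = _linear_init(rng, te, te)
        p["cond_w2"], p["cond_b2"] = _linear_init(rng, te, te)
        if config.conditional:
            p["label_embed"] = Tensor(
                rng.standard_normal((config.n_classes, te)) * 0.1, requires_grad=True
            )

        d_in = 3
        for i, w in enumerate(widths):
            p[f"enc{i}_w"], p[f"enc{i}_b"] = _linear_init(rng, d_in, w)
            p[f"enc{i}_film_w"], p[f"enc{i}_film_b"] = _linear_init(rng, te, 2 * w, gain=0.1)
            d_in = w

        if config.use_correspondence_embeddings:
            p["corr_embed"] = Tensor(
                rng.standard_normal((config.n_points, z)) * 0.1, requires_grad=True
            )

        for name in ("attn_wq", "attn_wk", "attn_wv", "attn_wo"):
            p[name] = Tensor(
                rng.standard_normal((z, z)) / np.sqrt(z), requires_grad=True
            )

        d = z
        for i in reversed(range(len(widths))):
            d_out = widths[i - 1] if i > 0 else widths[0]
            p[f"dec{i}_w"], p[f"dec{i}_b"] = _linear_init(rng, d + widths[i], d_out)
            p[f"dec{i}_film_w"], p[f"dec{i}_film_b"] = _linear_init(rng, te, 2 * d_out, gain=0.1)
            d = d_out
        p["out_w"], p["out_b"] = _linear_init(rng, d, 3, gain=0.1)

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    @property
    def n_points(self) -> int:
        return self.config.n_points

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward pass -----------------------------------------------------------
    def _condition(self, t, label) -> Tensor:
        emb = Tensor(timestep_embedding(t, self.config.time_embed_dim))
        if self.config.conditional and label is not None:
            labels = np.atleast_1d(np.asarray(label, dtype=np.int64))
            emb = emb + self.params["label_embed"][labels]
        h = silu(emb @ self.params["cond_w1"] + self.params["cond_b1"])
        return silu(h @ self.params["cond_w2"] + self.params["cond_b2"])

    def _film(self, level_prefix: str, cond: Tensor, width: int):
        p = self.params
        ss = cond @ p[f"{level_prefix}_film_w"] + p[f"{level_prefix}_film_b"]
        ss = ss.reshape(ss.shape[0], 1, 2 * width)  # broadcast over points
        return ss[:, :, :width], ss[:, :, width:]

    def forward(self, x, t, label=None) -> Tensor:
        """Autodiff forward pass; ``x`` is (B, N, 3) array or Tensor,
        ``t`` an int or (B,) int array. Returns a (B, N, 3) Tensor."""
        xt = Tensor._wrap(x)
        squeeze = xt.ndim == 2
        if squeeze:
            xt = xt.reshape(1, *xt.shape)
        bsz, n = xt.shape[0], xt.shape[1]
        if n != self.config.n_points:
            raise ValueError(f"expected N={self.config.n_points}, got {n}")
        t = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=np.int64)), (bsz,))
        cond = self._condition(t, label)

        p = self.params
        widths = self.config.level_widths
        h = xt
        skips = []
        for i, w in enumerate(widths):
            scale, shift = self._film(f"enc{i}", cond, w)
            h = rft_block(h, p[f"enc{i}_w"], p[f"enc{i}_b"], scale, shift)
            skips.append(h)

        if self.config.use_correspondence_embeddings:
            h = add_correspondence_embedding(h, p["corr_embed"])

        h = masked_self_attention(
            h, self.mask, p["attn_wq"], p["attn_wk"], p["attn_wv"], p["attn_wo"],
            self.config.n_heads,
        )

        for i in reversed(range(len(widths))):
            d_out = widths[i - 1] if i > 0 else widths[0]
            scale, shift = self._film(f"dec{i}", cond, d_out)
            h = rft_block(concat([h, skips[i]], axis=-1), p[f"dec{i}_w"], p[f"dec{i}_b"], scale, shift)

        out = h @ p["out_w"] + p["out_b"]
        return out.reshape(n, 3) if squeeze else out

    def predict(self, x, t, label=None) -> np.ndarray:
        """Inference-only forward pass returning a plain array."""
        return self.forward(np.asarray(x, dtype=np.float64), t, label).data

    # -- checkpointing ------------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        """Serialize weights, config, and attention mask to HDF5; ``extra``
        holds side information (e.g. schedule, normalization params)."""
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.create_dataset("mask_allowed", data=self.mask.allowed, track_times=False)
            f.create_dataset("mask_mean_shape", data=self.mask.source_mean_shape.coords, track_times=False)
            grp = f.create_group("params")
            for name, tensor in self.params.items():
                grp.create_dataset(name, data=tensor.data, track_times=False)
            if extra:
                f.attrs["extra"] = json.dumps(extra)

    @classmethod
    def load(cls, path) -> tuple["NoisePredictor", dict]:
        with h5py.File(path, "r") as f:
            cfg_d = json.loads(f.attrs["config"])
            cfg_d["level_widths"] = tuple(cfg_d["level_widths"])
            config = NetworkConfig(**cfg_d)
            mask = AttentionMask(
                allowed=f["mask_allowed"][()].astype(bool),
                source_mean_shape=PointSet(f["mask_mean_shape"][()]),
            )
            net = cls(config, mask, rng=0)
            for name in f["params"]:
                net.params[name].data = f["params"][name][()]
            extra = json.loads(f.attrs["extra"]) if "extra" in f.attrs else {}
        return net, extra
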