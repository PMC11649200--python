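"""Modular co-attention: scaled dot-product attention, SA/GA units, MCA
layers, and the L-layer encoder-decoder co-attention network.

The network treats image regions X = [x_1..x_n] and question words
Y = [y_1..y_m] as *sets* of feature vectors: there is no positional
encoding, so self-attention is permutation-equivariant over rows.  Padding
rows are excluded with an additive large-negative offset before every
softmax; the resulting attention weight at a padded position is exactly
zero, which is what makes appending padding a bit-exact no-op downstream.

Wiring follows the encoder-decoder arrangement: an L-deep stack of
self-attention (SA) units refines the visual set into X^(L); the decoder
runs, per layer, self-attention over the question stream followed by
guided attention (GA) in which the question stream queries the encoded
visual set.  A ``stacked`` wiring — each layer's GA guided by that layer's
visual output — is available for ablations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import LayerNorm, Linear, Module, Tensor, masked_softmax
from .errors import ConfigError, DegenerateInputError, ShapeError

__all__ = [
    "AttentionConfig",
    "FeatureSet",
    "AttentionWeights",
    "scaled_dot_attention",
    "MultiHeadAttention",
    "SAUnit",
    "GAUnit",
    "MCALayer",
    "CoAttentionNetwork",
    "AttentivePool",
]


@dataclass
class AttentionConfig:
    """Hyperparameters of the co-attention stack.

    d_model : common feature width (d_k per head = d_model / n_heads)
    n_heads : number of attention heads h
    d_ff    : inner width of the pointwise feed-forward sublayer
    n_layers: stack depth L (default 6, the depth at which accuracy peaks)
    dropout_rate : dropout probability after attention and feed-forward
    wiring  : "encoder_decoder" (default) or "stacked"
    norm_style : "post" (sublayer -> add -> norm, default) or "pre"
    """

    d_model: int = 512
    n_heads: int = 8
    d_ff: int = 2048
    n_layers: int = 6
    dropout_rate: float = 0.1
    wiring: str = "encoder_decoder"
    norm_style: str = "post"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.wiring not in ("encoder_decoder", "stacked"):
            raise ConfigError(f"unknown wiring {self.wiring!r}")
        if self.norm_style not in ("post", "pre"):
            raise ConfigError(f"unknown norm_style {self.norm_style!r}")


@dataclass
class FeatureSet:
    """A set of feature vectors with a validity mask.

    vectors   : Tensor of shape (..., n, d)
    valid_mask: boolean array of shape (..., n); False rows are padding and
                must never influence valid rows.
    """

    vectors: Tensor
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.vectors, Tensor):
            self.vectors = Tensor(np.asarray(self.vectors, dtype=np.float64))
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.vectors.shape[:-1], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.vectors.shape[:-1]:
            raise ShapeError(
                f"valid_mask shape {self.valid_mask.shape} does not match "
                f"vectors {self.vectors.shape}")
        if not np.isfinite(self.vectors.data).all():
            raise ShapeError("FeatureSet vectors must be finite")

    @property
    def n(self) -> int:
        return self.vectors.shape[-2]

    @property
    def d(self) -> int:
        return self.vectors.shape[-1]


@dataclass
class AttentionWeights:
    """Attention weight matrices; shape (..., n_q, n_k) or with a head axis."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)


def scaled_dot_attention(queries: Tensor, keys: Tensor, values: Tensor,
                         key_mask: np.ndarray | None = None
                         ) -> tuple[Tensor, AttentionWeights]:
    """softmax(Q K^T / sqrt(d_k)) V with additive masking of padded keys.

    Shapes: queries (..., n_q, d_k), keys (..., n_k, d_k),
    values (..., n_k, d_v).  Masked keys receive exactly zero weight.
    """
    queries = Tensor._lift(queries)
    keys = Tensor._lift(keys)
    values = Tensor._lift(values)
    if queries.shape[-1] != keys.shape[-1]:
        raise ShapeError(
            f"query width {queries.shape[-1]} != key width {keys.shape[-1]}")
    if keys.shape[-2] != values.shape[-2]:
        raise ShapeError("keys and values must have the same row count")
    d_k = queries.shape[-1]
    if key_mask is None:
        key_mask = np.ones(keys.shape[:-1], dtype=bool)
    key_mask = np.asarray(key_mask, dtype=bool)
    if not key_mask.any(axis=-1).all():
        raise DegenerateInputError("attention over a fully masked key set")
    scores = (queries @ keys.transpose(*range(keys.ndim - 2), keys.ndim - 1,
                                       keys.ndim - 2)) * (1.0 / np.sqrt(d_k))
    # broadcast key mask over the query axis
    mask = np.broadcast_to(key_mask[..., None, :], scores.shape)
    weights = masked_softmax(scores, mask, axis=-1)
    return weights @ values, AttentionWeights(weights.data)


class MultiHeadAttention(Module):
    """h parallel scaled dot-product attentions on learned projections,
    concatenated and linearly recombined."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ConfigError(f"d_model={d_model} not divisible by h={n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)
        self.last_weights: np.ndarray | None = None

    def _split_heads(self, x: Tensor) -> Tensor:
        # (..., n, d_model) -> (..., h, n, d_head)
        *lead, n, _ = x.shape
        x = x.reshape(*lead, n, self.n_heads, self.d_head)
        axes = tuple(range(len(lead))) + (x.ndim - 2, x.ndim - 3, x.ndim - 1)
        return x.transpose(*axes)

    def __call__(self, queries: Tensor, keys: Tensor, values: Tensor,
                 key_mask: np.ndarray | None = None) -> Tensor:
        q = self._split_heads(self.w_q(queries))
        k = self._split_heads(self.w_k(keys))
        v = self._split_heads(self.w_v(values))
        if key_mask is not None:
            key_mask = np.asarray(key_mask, dtype=bool)[..., None, :]
            key_mask = np.broadcast_to(key_mask, k.shape[:-1])
        out, attn = scaled_dot_attention(q, k, v, key_mask)
        self.last_weights = attn.weights  # (..., h, n_q, n_k)
        # (..., h, n, d_head) -> (..., n, d_model)
        *lead, h, n, dh = out.shape
        axes = tuple(range(len(lead))) + (out.ndim - 2, out.ndim - 3, out.ndim - 1)
        merged = out.transpose(*axes).reshape(*lead, n, h * dh)
        return self.w_o(merged)


class _FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * keep


class _AttentionBlock(Module):
    """Attention sublayer + pointwise feed-forward, each wrapped with a
    residual connection and layer normalization."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.config = config
        self.mha = MultiHeadAttention(config.d_model, config.n_heads, rng)
        self.ffn = _FeedForward(config.d_model, config.d_ff, rng)
        self.norm1 = LayerNorm(config.d_model)
        self.norm2 = LayerNorm(config.d_model)

    def __call__(self, target: Tensor, source: Tensor, source_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        if cfg.norm_style == "post":
            attended = _dropout(self.mha(target, source, source, source_mask),
                                cfg.dropout_rate, rng)
            x = self.norm1(target + attended)
            x = self.norm2(x + _dropout(self.ffn(x), cfg.dropout_rate, rng))
        else:
            attended = self.mha(self.norm1(target), source, source, source_mask)
            x = target + _dropout(attended, cfg.dropout_rate, rng)
            x = x + _dropout(self.ffn(self.norm2(x)), cfg.dropout_rate, rng)
        return x


class SAUnit(Module):
    """Self-attention unit: multi-head attention of a set onto itself,
    then the pointwise feed-forward sublayer."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.block = _AttentionBlock(config, rng)

    def __call__(self, x: FeatureSet, rng: np.random.Generator | None = None
                 ) -> FeatureSet:
        out = self.block(x.vectors, x.vectors, x.valid_mask, rng)
        return FeatureSet(out, x.valid_mask)


class GAUnit(Module):
    """Guided-attention unit: the target set queries the guide set."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.block = _AttentionBlock(config, rng)

    def __call__(self, target: FeatureSet, guide: FeatureSet,
                 rng: np.random.Generator | None = None) -> FeatureSet:
        if not guide.valid_mask.any(axis=-1).all():
            raise DegenerateInputError("guide set is fully masked")
        out = self.block(target.vectors, guide.vectors, guide.valid_mask, rng)
        return FeatureSet(out, target.valid_mask)

    @property
    def last_weights(self) -> np.ndarray | None:
        return self.block.mha.last_weights


class MCALayer(Module):
    """One modular co-attention layer.

    Models intra-modal interactions <x_i, x_j> and <y_i, y_j> through SA
    units and the cross-modal <x_i, y_j> interaction through a GA unit in
    which the question stream queries the visual stream.  Output shapes
    equal input shapes, so layers cascade.
    """

    def __init__(self, config: AttentionConfig, rng: np.random.Generator):
        self.sa_x = SAUnit(config, rng)
        self.sa_y = SAUnit(config, rng)
        self.ga = GAUnit(config, rng)

    def __call__(self, x: FeatureSet, y: FeatureSet,
                 rng: np.random.Generator | None = None
                 ) -> tuple[FeatureSet, FeatureSet]:
        x_out = self.sa_x(x, rng)
        y_sa = self.sa_y(y, rng)
        y_out = self.ga(y_sa, x_out, rng)
        return x_out, y_out


class CoAttentionNetwork(Module):
    """L-layer co-attention encoder-decoder over (visual, question) sets.

    encoder_decoder wiring: the visual set is refined by all L SA units
    first (X^(L)); every decoder layer's GA is then guided by X^(L).
    stacked wiring: layer l's GA is guided by X^(l).

    If the incoming visual width differs from d_model a linear input
    transformation aligns it; the question stream must already be d_model
    wide (it is produced by the recurrent question encoder).
    """

    def __init__(self, config: AttentionConfig, rng: np.random.Generator,
                 d_visual: int | None = None):
        self.config = config
        d = config.d_model
        self.visual_proj = (Linear(d_visual, d, rng)
                            if d_visual is not None and d_visual != d else None)
        self.layers = [MCALayer(config, rng) for _ in range(config.n_layers)]

    def encode_visual(self, x: FeatureSet,
                      rng: np.random.Generator | None = None
                      ) -> list[FeatureSet]:
        """Run the visual SA stack; returns per-layer outputs X^(1..L).

        The visual stream never depends on the question, so callers with
        repeated images may encode each image once and gather afterwards.
        """
        if self.visual_proj is not None:
            x = FeatureSet(self.visual_proj(x.vectors), x.valid_mask)
        if x.d != self.config.d_model:
            raise ShapeError(f"visual width {x.d} does not match d_model="
                             f"{self.config.d_model}")
        outs = []
        for layer in self.layers:
            x = layer.sa_x(x, rng)
            outs.append(x)
        return outs

    def decode_question(self, y: FeatureSet, x_layers: list[FeatureSet],
                        rng: np.random.Generator | None = None) -> FeatureSet:
        """Question-stream decoder: SA then GA per layer; the GA guide is
        X^(L) (encoder_decoder wiring) or X^(l) (stacked wiring)."""
        if y.d != self.config.d_model:
            raise ShapeError(f"question width {y.d} does not match d_model="
                             f"{self.config.d_model}")
        for i, layer in enumerate(self.layers):
            guide = x_layers[-1] if self.config.wiring == "encoder_decoder" \
                else x_layers[i]
            y = layer.ga(layer.sa_y(y, rng), guide, rng)
        return y

    def __call__(self, x: FeatureSet, y: FeatureSet,
                 rng: np.random.Generator | None = None
                 ) -> tuple[FeatureSet, FeatureSet]:
        x_layers = self.encode_visual(x, rng)
        y_out = self.decode_question(y, x_layers, rng)
        return x_layers[-1], y_out

    @property
    def final_ga_weights(self) -> np.ndarray | None:
        """Per-head question-to-image attention of the last decoder layer."""
        return self.layers[-1].ga.last_weights


class AttentivePool(Module):
    """Mask-aware reduction of a feature set to a single vector: a linear
    scoring map, softmax over valid rows, and the weighted sum."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.score = Linear(d, 1, rng)
        self.last_weights: np.ndarray | None = None

    def __call__(self, features: FeatureSet) -> Tensor:
        if not features.valid_mask.any(axis=-1).all():
            raise DegenerateInputError("attentive pooling over an all-invalid set")
        scores = self.score(features.vectors).reshape(*features.vectors.shape[:-1])
        w = masked_softmax(scores, features.valid_mask, axis=-1)
        self.last_weights = w.data
        # (..., n) x (..., n, d) -> (..., d)
        return (w.reshape(*w.shape, 1) * features.vectors).sum(axis=-2)
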