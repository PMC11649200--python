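"""Multimodal fusion of the attended question and visual vectors.

The full bilinear interaction between a d_q question vector, a d_v visual
vector and |A| answers is a 3-way tensor T with d_q * d_v * |A| entries.
Tucker decomposition factors it as a small core tensor T_c (t_q x t_v x t_o)
multiplied along each mode by factor matrices W_q (d_q x t_q),
W_v (d_v x t_v) and W_o (t_o x |A|), shrinking the parameter count to
t_q*t_v*t_o + d_q*t_q + d_v*t_v + t_o*|A| while keeping the bilinear form.
The fused representation is

    q~ = act(q^T W_q),  v~ = act(v^T W_v)
    z[k] = sum_ij T_c[i,j,k] * q~[i] * v~[j]
    y = z^T W_o,  p = softmax(y)

with tanh the default activation.  Simpler fusions (concatenation,
elementwise product, low-rank bilinear MLB, elementwise addition) are
provided as ablation baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Linear, Module, Parameter, Tensor, concat
from .errors import ConfigError, InputError, ShapeError

__all__ = [
    "FusedRepresentation",
    "TuckerFusion",
    "BaselineFusion",
    "tucker_reconstruct",
    "mutan_fuse",
    "baseline_fuse",
    "count_parameters",
]

_ACTIVATIONS = {
    "tanh": lambda t: t.tanh(),
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
}


@dataclass
class FusedRepresentation:
    """Fusion output: core-space vector z, answer logits y, softmax p."""

    z: Tensor
    logits: Tensor
    probabilities: Tensor


def _softmax_last(logits: Tensor) -> Tensor:
    shifted = logits - np.max(logits.data, axis=-1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


class TuckerFusion(Module):
    """Tucker-parameterized bilinear fusion (trainable module)."""

    def __init__(self, d_q: int, d_v: int, n_answers: int,
                 ranks: tuple[int, int, int], rng: np.random.Generator,
                 activation: str = "tanh"):
        t_q, t_v, t_o = ranks
        if min(t_q, t_v, t_o) < 1:
            raise ConfigError("Tucker ranks must be >= 1")
        if activation not in _ACTIVATIONS:
            raise ConfigError(f"unknown activation {activation!r}")
        if t_q > d_q or t_v > d_v:
            warnings.warn(
                "Tucker rank exceeds its input dimension; no parameter saving",
                stacklevel=2)
        self.d_q, self.d_v, self.n_answers = d_q, d_v, n_answers
        self.ranks = (t_q, t_v, t_o)
        self.activation = activation
        scale = 1.0 / np.sqrt(t_q * t_v)
        self.core = Parameter(rng.normal(0.0, scale, size=(t_q, t_v, t_o)))
        self.factor_q = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d_q), size=(d_q, t_q)))
        self.factor_v = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d_v), size=(d_v, t_v)))
        self.output_map = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(t_o), size=(t_o, n_answers)))

    def __call__(self, q_vec: Tensor, v_vec: Tensor) -> FusedRepresentation:
        return mutan_fuse(q_vec, v_vec, self)


def tucker_reconstruct(params: TuckerFusion) -> np.ndarray:
    """Expand the factored interaction into the full d_q x d_v x |A| tensor.

    T[a,b,c] = sum_ijk T_c[i,j,k] W_q[a,i] W_v[b,j] W_o[k,c].  Used as a
    test oracle and for parameter-count comparison, never in the forward
    path.
    """
    core = params.core.data
    wq, wv, wo = params.factor_q.data, params.factor_v.data, params.output_map.data
    t = np.tensordot(wq, core, axes=(1, 0))        # d_q x t_v x t_o
    t = np.tensordot(t, wv, axes=(1, 1))           # d_q x t_o x d_v
    t = np.tensordot(t, wo, axes=(1, 0))           # d_q x d_v x |A|
    return t


def mutan_fuse(q_vec: Tensor, v_vec: Tensor,
               params: TuckerFusion) -> FusedRepresentation:
    """Fuse a question vector and a visual vector through the Tucker core.

    Accepts single vectors (d,) or batches (..., d).
    """
    q_vec = Tensor._lift(q_vec)
    v_vec = Tensor._lift(v_vec)
    if q_vec.shape[-1] != params.d_q:
        raise ShapeError(f"q width {q_vec.shape[-1]} != d_q={params.d_q}")
    if v_vec.shape[-1] != params.d_v:
        raise ShapeError(f"v width {v_vec.shape[-1]} != d_v={params.d_v}")
    if not (np.isfinite(q_vec.data).all() and np.isfinite(v_vec.data).all()):
        raise InputError("non-finite fusion input")
    act = _ACTIVATIONS[params.activation]
    t_q, t_v, t_o = params.ranks
    q_t = act(q_vec @ params.factor_q)                    # (..., t_q)
    v_t = act(v_vec @ params.factor_v)                    # (..., t_v)
    # z[k] = sum_ij core[i,j,k] q~[i] v~[j], batched via reshapes
    flat_core = params.core.reshape(t_q, t_v * t_o)
    mixed = (q_t @ flat_core).reshape(*q_t.shape[:-1], t_v, t_o)
    z = (v_t.reshape(*v_t.shape, 1) * mixed).sum(axis=-2)  # (..., t_o)
    logits = z @ params.output_map
    return FusedRepresentation(z=z, logits=logits,
                               probabilities=_softmax_last(logits))


class BaselineFusion(Module):
    """Simple fusion baselines used in ablations.

    mode:
      concat   - project the concatenation [q; v]
      add      - elementwise sum of width-aligned projections
      multiply - elementwise product of width-aligned projections
      mlb      - low-rank bilinear: product of rank-r projections, then an
                 output map
    """

    MODES = ("concat", "add", "multiply", "mlb")

    def __init__(self, d_q: int, d_v: int, n_answers: int, mode: str,
                 rng: np.random.Generator, d_hidden: int = 64,
                 rank: int | None = None):
        if mode not in self.MODES:
            raise ConfigError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        self.d_hidden = d_hidden
        if mode == "concat":
            self.proj = Linear(d_q + d_v, d_hidden, rng)
        elif mode in ("add", "multiply"):
            self.proj_q = Linear(d_q, d_hidden, rng, bias=False)
            self.proj_v = Linear(d_v, d_hidden, rng, bias=False)
        else:  # mlb
            r = rank if rank is not None else d_hidden
            self.proj_q = Linear(d_q, r, rng, bias=False)
            self.proj_v = Linear(d_v, r, rng, bias=False)
            self.d_hidden = r
        self.out = Linear(self.d_hidden, n_answers, rng)

    def __call__(self, q_vec: Tensor, v_vec: Tensor) -> FusedRepresentation:
        q_vec, v_vec = Tensor._lift(q_vec), Tensor._lift(v_vec)
        if self.mode == "concat":
            z = self.proj(concat([q_vec, v_vec], axis=-1)).tanh()
        elif self.mode == "add":
            z = (self.proj_q(q_vec) + self.proj_v(v_vec)).tanh()
        else:  # multiply, mlb share the elementwise-product form
            z = self.proj_q(q_vec) * self.proj_v(v_vec)
        logits = self.out(z)
        return FusedRepresentation(z=z, logits=logits,
                                   probabilities=_softmax_last(logits))


def baseline_fuse(q_vec: Tensor, v_vec: Tensor, mode: str,
                  params: BaselineFusion) -> FusedRepresentation:
    if params.mode != mode:
        raise ConfigError(f"params built for mode {params.mode!r}, got {mode!r}")
    return params(q_vec, v_vec)


def count_parameters(d_q: int, d_v: int, n_answers: int,
                     ranks: tuple[int, int, int]) -> tuple[int, int]:
    """(tucker_count, full_bilinear_count) trainable-entry totals.

    tucker_count = t_q*t_v*t_o + d_q*t_q + d_v*t_v + t_o*|A|;
    full_bilinear_count = d_q*d_v*|A|.
    """
    if min(d_q, d_v, n_answers) < 1 or min(ranks) < 1:
        raise ConfigError("dimensions and ranks must be positive")
    t_q, t_v, t_o = ranks
    tucker = t_q * t_v * t_o + d_q * t_q + d_v * t_v + t_o * n_answers
    return tucker, d_q * d_v * n_answers
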