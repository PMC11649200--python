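"""Bias-balancing strategy: a question-only branch whose sigmoid-squared
output multiplicatively masks the main prediction during training.

VQA models trained on skewed data answer from question-answer co-occurrence
statistics ("unimodal bias") while ignoring the image.  The bias-balancing
branch maps the question features alone to an |A|-vector r; the mask
m^2 = sigmoid(r)^2 scales the main logits z elementwise (z (.) m^2), so
answers the question alone already predicts contribute less learning signal
to the main path, pushing it toward visual evidence.  The branch also
feeds its own classifier c_q whose cross-entropy loss trains it to model
the bias; that loss is *barred* from backpropagating into the question
encoder so the encoder itself does not absorb the bias.  At inference the
branch and mask are removed: predictions come from the unmasked main path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Linear, Module, Tensor, masked_softmax
from .errors import ContractError, InputError, ShapeError

__all__ = [
    "BiasMask",
    "LossReport",
    "QuestionOnlyBranch",
    "apply_mask",
    "joint_loss",
    "gradient_partition_check",
    "inference_forward",
]


@dataclass
class BiasMask:
    """Per-answer multiplicative mask, entries strictly inside (0, 1)."""

    mask: Tensor

    def __post_init__(self) -> None:
        if not isinstance(self.mask, Tensor):
            self.mask = Tensor(self.mask)
        data = self.mask.data
        if not np.isfinite(data).all():
            raise InputError("non-finite bias mask")
        if (data <= 0).any() or (data >= 1).any():
            raise InputError("bias-mask entries must lie strictly in (0, 1)")


@dataclass
class LossReport:
    """Joint training loss: total = main (masked BCE) + branch (CE)."""

    total: Tensor
    main: Tensor
    branch: Tensor


class QuestionOnlyBranch(Module):
    """Question-only branch: mask-aware mean of word features -> two-layer
    perceptron r_nq -> |A| vector; classifier c_q maps |A| -> |A|.

    The incoming question features are detached (gradient barrier), so no
    gradient of any branch quantity reaches the question encoder.
    """

    def __init__(self, d_q: int, n_answers: int, rng: np.random.Generator,
                 d_hidden: int = 64):
        self.n_answers = n_answers
        self.map1 = Linear(d_q, d_hidden, rng)
        self.map2 = Linear(d_hidden, n_answers, rng)
        self.classifier = Linear(n_answers, n_answers, rng)

    def mapping(self, q_features: Tensor, valid_mask: np.ndarray) -> Tensor:
        """r_nq: (.., m, d_q) question features -> (.., |A|) vector."""
        q_features = Tensor._lift(q_features)
        if not np.isfinite(q_features.data).all():
            raise InputError("non-finite question features")
        mask = np.asarray(valid_mask, dtype=np.float64)
        denom = mask.sum(axis=-1, keepdims=True)
        if (denom == 0).any():
            raise ShapeError("question with no valid tokens")
        pooled = (q_features * mask[..., None]).sum(axis=-2) / denom
        return self.map2(self.map1(pooled).relu())

    def __call__(self, q_features: Tensor, valid_mask: np.ndarray
                 ) -> tuple[Tensor, BiasMask]:
        """Return (branch logits f_Q, mask sigma(r)^2).

        The gradient barrier is applied here: ``q_features`` is detached
        before any branch computation.
        """
        q_features = Tensor._lift(q_features).detach()
        r = self.mapping(q_features, valid_mask)
        mask = r.sigmoid() ** 2.0
        # guard against float saturation at |r| >~ 40 so the mask stays
        # strictly inside (0, 1); gradients there are ~0 regardless
        np.clip(mask.data, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0),
                out=mask.data)
        branch_logits = self.classifier(r)
        return branch_logits, BiasMask(mask)


def apply_mask(z_logits: Tensor, mask: BiasMask) -> Tensor:
    """Elementwise product z (.) m^2 of main logits and bias mask."""
    z_logits = Tensor._lift(z_logits)
    if z_logits.shape[-1] != mask.mask.shape[-1]:
        raise ShapeError(
            f"logit width {z_logits.shape[-1]} != mask width "
            f"{mask.mask.shape[-1]}")
    return z_logits * mask.mask


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against soft targets,
    computed in the stable softplus form."""
    t = np.asarray(targets, dtype=np.float64)
    # t*softplus(-z) + (1-t)*softplus(z)
    return (Tensor._lift(t) * (-logits).softplus()
            + (1.0 - Tensor._lift(t)) * logits.softplus()).mean()


def _cross_entropy(logits: Tensor, hard_targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy against integer class targets."""
    idx = np.atleast_1d(np.asarray(hard_targets, dtype=np.int64))
    batched = logits.ndim > 1
    z = logits if batched else logits.reshape(1, -1)
    shifted = z - np.max(z.data, axis=-1, keepdims=True)
    log_norm = shifted.exp().sum(axis=-1, keepdims=True).log()
    log_probs = shifted - log_norm
    picked = log_probs[np.arange(idx.shape[0]), idx]
    return -picked.mean()


def joint_loss(masked_logits: Tensor, branch_logits: Tensor,
               soft_targets: np.ndarray, hard_target) -> LossReport:
    """L = L_QM + L_QO: masked-main BCE plus question-branch CE.

    soft_targets: per-answer supervision in [0, 1] (see dataset_io);
    hard_target: index (or batch of indices) of the branch's class target.
    """
    soft_targets = np.asarray(soft_targets, dtype=np.float64)
    if ((soft_targets < 0) | (soft_targets > 1)).any():
        raise InputError("soft targets must lie in [0, 1]")
    masked_logits = Tensor._lift(masked_logits)
    if masked_logits.shape != soft_targets.shape:
        raise ShapeError(
            f"logits shape {masked_logits.shape} != targets {soft_targets.shape}")
    main = _bce_with_logits(masked_logits, soft_targets)
    branch = _cross_entropy(Tensor._lift(branch_logits), hard_target)
    return LossReport(total=main + branch, main=main, branch=branch)


def inference_forward(z_logits: Tensor) -> Tensor:
    """Mask-free prediction: the branch is removed after training, so
    inference scores are the unmasked main-path logits."""
    return Tensor._lift(z_logits)


def gradient_partition_check(model, batch) -> dict:
    """Verify the training-time gradient partition on a built model.

    * d L_QO / d (question-encoder params) == 0 exactly (gradient barrier);
    * d L_QM / d (branch classifier c_q params) == 0 exactly;
    * encoder gradients under the combined loss equal those under L_QM
      alone.

    ``model`` must expose ``training_losses(batch) -> LossReport``,
    ``encoder_parameters()`` and ``branch`` (a QuestionOnlyBranch).
    Raises ContractError naming the offending parameter group.
    """

    def grads(loss: Tensor) -> dict[str, np.ndarray]:
        model.zero_grad()
        loss.backward()
        return {name: (np.zeros_like(p.data) if p.grad is None else p.grad.copy())
                for name, p in model.named_parameters().items()}

    enc_names = set(model.encoder_parameters())
    cq_names = {n for n in model.named_parameters() if ".classifier." in n}

    report = {"encoder_params": sorted(enc_names),
              "branch_classifier_params": sorted(cq_names)}

    g_branch = grads(model.training_losses(batch).branch)
    for name in enc_names:
        if np.abs(g_branch[name]).max() != 0.0:
            raise ContractError(
                f"branch loss leaks gradient into encoder parameter {name}")

    g_main = grads(model.training_losses(batch).main)
    for name in cq_names:
        if np.abs(g_main[name]).max() != 0.0:
            raise ContractError(
                f"main loss leaks gradient into branch classifier {name}")

    g_total = grads(model.training_losses(batch).total)
    for name in enc_names:
        if not np.array_equal(g_total[name], g_main[name]):
            raise ContractError(
                f"combined-loss encoder gradient differs from main-loss "
                f"gradient for {name}")

    report["ok"] = True
    return report
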