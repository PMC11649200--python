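"""The assembled VQA model and its trainer.

Pipeline: word embeddings -> single-layer LSTM question encoder, and a
pluggable image feature extractor -> co-attention encoder-decoder ->
mask-aware attentive pooling of each stream -> Tucker bilinear fusion ->
answer logits.  During training the bias-balancing branch masks the
logits and adds its own cross-entropy term; at inference the branch is
removed and predictions come from the unmasked main path.

Everything is deterministic given the configuration seed on one thread.
Checkpoints are numpy archives carrying the parameters, the configuration,
both vocabularies and a format version; the branch parameters are stored
in a separate namespace so stripping them for an inference-only checkpoint
is a structural operation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .attention import (AttentionConfig, AttentivePool, CoAttentionNetwork,
                        FeatureSet)
from .autodiff import AdamW, Module, Tensor
from .biba import (LossReport, QuestionOnlyBranch, apply_mask,
                   inference_forward, joint_loss)
from .dataset_io import (EvaluationReport, VQATriple, build_answer_vocab,
                         evaluate, soft_targets)
from .encoders import (EmbeddingTable, GridExtractor, LSTMQuestionEncoder,
                       Vocabulary, extract_image_features, tokenize)
from .errors import ConfigError, InputError
from .fusion import BaselineFusion, TuckerFusion

__all__ = ["ModelConfig", "TrainConfig", "VQAModel", "Batch",
           "build_model", "prepare_batches", "train_model", "evaluate_model",
           "save_checkpoint", "load_checkpoint", "strip_branch"]

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the assembled model (toy-scale defaults)."""

    d_model: int = 32
    n_heads: int = 4
    d_ff: int = 64
    n_layers: int = 2
    d_emb: int = 16
    d_v: int = 16
    fusion_ranks: tuple[int, int, int] = (16, 16, 16)
    fusion_activation: str = "tanh"
    fusion_mode: str = "mutan"          # mutan | concat | add | multiply | mlb
    biba: bool = True
    mask_on: str = "logits"             # logits | probabilities
    branch_hidden: int = 64
    dropout_rate: float = 0.0
    wiring: str = "encoder_decoder"
    max_len: int = 14
    grid: int = 8
    resize_to: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_on not in ("logits", "probabilities"):
            raise ConfigError(f"unknown mask_on {self.mask_on!r}")


@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0


@dataclass
class Batch:
    """Pre-extracted tensors for a list of triples.

    Because the visual stream is question-independent and questions are
    often repeated verbatim, the batch may carry *unique* image features
    and token rows plus inverse index maps; the model encodes the unique
    rows once and gathers.  When the inverse maps are None each row is
    its own unique entry.
    """

    token_ids: np.ndarray        # (B, max_len)
    question_mask: np.ndarray    # (B, max_len) bool
    image_features: np.ndarray   # (U, n_v, d_v) unique image features
    soft_targets: np.ndarray     # (B, |A|)
    hard_targets: np.ndarray     # (B,)
    question_ids: list[str]
    categories: list[str]
    image_inverse: np.ndarray | None = None   # (B,) row -> unique image
    token_unique: np.ndarray | None = None    # (Uq, max_len)
    token_inverse: np.ndarray | None = None   # (B,) row -> unique question


class VQAModel(Module):
    """Encoder + co-attention + fusion + (optional) bias-balancing branch."""

    def __init__(self, config: ModelConfig, question_vocab: Vocabulary,
                 answer_vocab: Vocabulary,
                 embedding_weights: np.ndarray | None = None):
        self.config = config
        self.question_vocab = question_vocab
        self.answer_vocab = answer_vocab
        self.n_answers = len(answer_vocab)
        rng = np.random.default_rng(config.seed)
        self.embedding = EmbeddingTable(len(question_vocab), config.d_emb,
                                        rng=rng, weights=embedding_weights)
        self.question_encoder = LSTMQuestionEncoder(config.d_emb,
                                                    config.d_model, rng)
        att_cfg = AttentionConfig(d_model=config.d_model, n_heads=config.n_heads,
                                  d_ff=config.d_ff, n_layers=config.n_layers,
                                  dropout_rate=config.dropout_rate,
                                  wiring=config.wiring)
        self.coattention = CoAttentionNetwork(att_cfg, rng, d_visual=config.d_v)
        self.pool_q = AttentivePool(config.d_model, rng)
        self.pool_v = AttentivePool(config.d_model, rng)
        if config.fusion_mode == "mutan":
            self.fusion = TuckerFusion(config.d_model, config.d_model,
                                       self.n_answers, config.fusion_ranks,
                                       rng, activation=config.fusion_activation)
        else:
            self.fusion = BaselineFusion(config.d_model, config.d_model,
                                         self.n_answers, config.fusion_mode, rng)
        self.branch = (QuestionOnlyBranch(config.d_model, self.n_answers, rng,
                                          d_hidden=config.branch_hidden)
                       if config.biba else None)
        self._encoder_param_names = {
            name for name in self.named_parameters()
            if name.startswith(("embedding.", "question_encoder."))}

    # -- forward -----------------------------------------------------------
    def encode(self, batch: Batch) -> tuple[FeatureSet, FeatureSet, Tensor]:
        """Returns (visual set, question set, raw question features).

        Unique questions go through the LSTM and unique images through the
        visual SA stack exactly once; results are gathered back to batch
        order (a pure indexing operation, so per-row outputs are identical
        to encoding every row separately)."""
        q_raw = self._encode_questions(batch)
        x = FeatureSet(Tensor._lift(batch.image_features))
        x_layers = self.coattention.encode_visual(x)
        if batch.image_inverse is not None:
            x_layers = [FeatureSet(fs.vectors[batch.image_inverse],
                                   fs.valid_mask[batch.image_inverse])
                        for fs in x_layers]
        y = FeatureSet(q_raw, batch.question_mask)
        y_out = self.coattention.decode_question(y, x_layers)
        return x_layers[-1], y_out, q_raw

    def _encode_questions(self, batch: Batch) -> Tensor:
        if batch.token_unique is not None and batch.token_inverse is not None:
            emb = self.embedding.table[batch.token_unique]
            q_u = self.question_encoder(emb, batch.token_unique != 0)
            return q_u[batch.token_inverse]
        emb = self.embedding.table[batch.token_ids]
        return self.question_encoder(emb, batch.question_mask)

    def main_logits(self, batch: Batch) -> Tensor:
        x_out, y_out, _ = self.encode(batch)
        v_vec = self.pool_v(x_out)
        q_vec = self.pool_q(y_out)
        return self.fusion(q_vec, v_vec).logits

    def training_losses(self, batch: Batch) -> LossReport:
        """Joint loss L = L_QM(masked main) + L_QO(question branch)."""
        x_out, y_out, q_raw = self.encode(batch)
        v_vec = self.pool_v(x_out)
        q_vec = self.pool_q(y_out)
        z = self.fusion(q_vec, v_vec).logits
        if self.branch is None:
            # ablation path: plain BCE, zero branch term
            report = joint_loss(z, Tensor(np.zeros_like(z.data)),
                                batch.soft_targets, batch.hard_targets)
            zero = Tensor(np.zeros(()))
            return LossReport(total=report.main, main=report.main, branch=zero)
        branch_logits, mask = self.branch(q_raw, batch.question_mask)
        if self.config.mask_on == "logits":
            masked = apply_mask(z, mask)
        else:
            masked_p = z.sigmoid() * mask.mask
            # fold back to logit space is ill-posed; supervise probabilities
            masked = (masked_p / (1.0 - masked_p + 1e-12)).log()
        return joint_loss(masked, branch_logits, batch.soft_targets,
                          batch.hard_targets)

    def predict(self, batch: Batch) -> list[str]:
        """Mask-free inference; answers by argmax over the vocabulary."""
        logits = inference_forward(self.main_logits(batch))
        idx = np.argmax(logits.data, axis=-1)
        return [self.answer_vocab.token(int(i)) for i in idx]

    def predict_from_branch(self, batch: Batch) -> list[str]:
        """Question-only prediction (diagnostic: quantifies language bias)."""
        if self.branch is None:
            raise ConfigError("model built without the bias-balancing branch")
        q_raw = self._encode_questions(batch)
        branch_logits, _ = self.branch(q_raw, batch.question_mask)
        idx = np.argmax(branch_logits.data, axis=-1)
        return [self.answer_vocab.token(int(i)) for i in idx]

    def encoder_parameters(self) -> set[str]:
        return set(self._encoder_param_names)


def prepare_batches(triples: list[VQATriple], images: dict[str, np.ndarray],
                    model: VQAModel, extractor: GridExtractor,
                    batch_size: int, rng: np.random.Generator | None = None,
                    feature_cache: dict[str, np.ndarray] | None = None
                    ) -> list[Batch]:
    """Tokenize, extract features, build soft/hard targets, and batch.

    Records with no in-vocabulary answer are skipped with a log line.
    ``feature_cache`` (image_id -> features) avoids re-extracting shared
    images across epochs.
    """
    cfg = model.config
    cache = feature_cache if feature_cache is not None else {}
    rows = []
    for t in triples:
        try:
            target = soft_targets(t, model.answer_vocab)
        except InputError as exc:
            logger.warning("skipping record: %s", exc)
            continue
        tok = tokenize(t.question, model.question_vocab, cfg.max_len)
        if t.image_id not in cache:
            cache[t.image_id] = extract_image_features(
                images[t.image_id], extractor).features
        truths = t.ground_truths()
        hard = model.answer_vocab.id(truths[0]) if truths else int(np.argmax(target))
        rows.append((tok.token_ids, tok.token_ids != 0, cache[t.image_id],
                     target, hard, t.question_id, t.question_category))
    order = np.arange(len(rows))
    if rng is not None:
        rng.shuffle(order)
    batches = []
    for start in range(0, len(rows), batch_size):
        chunk = [rows[i] for i in order[start:start + batch_size]]
        token_ids = np.stack([r[0] for r in chunk])
        feats = np.stack([r[2] for r in chunk])
        tok_u, tok_inv = np.unique(token_ids, axis=0, return_inverse=True)
        img_u, img_inv = np.unique(feats.reshape(len(chunk), -1), axis=0,
                                   return_inverse=True)
        batches.append(Batch(
            token_ids=token_ids,
            question_mask=np.stack([r[1] for r in chunk]),
            image_features=img_u.reshape(-1, *feats.shape[1:]),
            soft_targets=np.stack([r[3] for r in chunk]),
            hard_targets=np.asarray([r[4] for r in chunk]),
            question_ids=[r[5] for r in chunk],
            categories=[r[6] for r in chunk],
            image_inverse=img_inv.ravel(),
            token_unique=tok_u,
            token_inverse=tok_inv.ravel()))
    return batches


def build_model(triples: list[VQATriple], config: ModelConfig,
                min_answer_freq: int = 1) -> VQAModel:
    """Construct vocabularies from the training triples and build the model."""
    question_vocab = Vocabulary.from_texts([t.question for t in triples])
    answer_vocab = build_answer_vocab(triples, min_freq=min_answer_freq)
    return VQAModel(config, question_vocab, answer_vocab)


def train_model(model: VQAModel, train_triples: list[VQATriple],
                images: dict[str, np.ndarray], train_cfg: TrainConfig,
                val_triples: list[VQATriple] | None = None,
                extractor: GridExtractor | None = None,
                metrics_log: list[dict] | None = None) -> list[dict]:
    """Joint optimization of L_QM + L_QO with Adam.

    Returns per-epoch records (mean losses and optional validation
    accuracy).  Aborts on a non-finite loss.  Deterministic given the
    configuration and seed on one thread.
    """
    cfg = model.config
    extractor = extractor or GridExtractor(grid=cfg.grid, d_v=cfg.d_v,
                                           resize_to=cfg.resize_to, seed=cfg.seed)
    rng = np.random.default_rng([train_cfg.seed, 5])
    optimizer = AdamW(model.parameters(), lr=train_cfg.learning_rate,
                      weight_decay=train_cfg.weight_decay)
    cache: dict[str, np.ndarray] = {}
    history = metrics_log if metrics_log is not None else []
    for epoch in range(train_cfg.epochs):
        batches = prepare_batches(train_triples, images, model, extractor,
                                  train_cfg.batch_size, rng=rng,
                                  feature_cache=cache)
        totals = np.zeros(3)
        n = 0
        for batch in batches:
            optimizer.zero_grad()
            report = model.training_losses(batch)
            if not np.isfinite(report.total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"main={report.main.data}, branch={report.branch.data}")
            report.total.backward()
            optimizer.step()
            b = len(batch.question_ids)
            totals += b * np.array([float(report.total.data),
                                    float(report.main.data),
                                    float(report.branch.data)])
            n += b
        record = {"epoch": epoch, "loss": totals[0] / n,
                  "loss_main": totals[1] / n, "loss_branch": totals[2] / n}
        if val_triples:
            record["val_accuracy"] = evaluate_model(
                model, val_triples, images, extractor,
                batch_size=train_cfg.batch_size).overall
        history.append(record)
        logger.info("epoch %d: %s", epoch, record)
    return history


def evaluate_model(model: VQAModel, triples: list[VQATriple],
                   images: dict[str, np.ndarray],
                   extractor: GridExtractor | None = None,
                   batch_size: int = 64,
                   from_branch: bool = False) -> EvaluationReport:
    """Mask-free inference over ``triples`` scored with the category-wise
    accuracy metric.  ``from_branch`` scores the question-only branch
    instead (bias diagnostic)."""
    cfg = model.config
    extractor = extractor or GridExtractor(grid=cfg.grid, d_v=cfg.d_v,
                                           resize_to=cfg.resize_to, seed=cfg.seed)
    batches = prepare_batches(triples, images, model, extractor, batch_size)
    predictions: dict[str, str] = {}
    for batch in batches:
        answers = (model.predict_from_branch(batch) if from_branch
                   else model.predict(batch))
        predictions.update(zip(batch.question_ids, answers))
    kept = [t for t in triples if t.question_id in predictions]
    return evaluate(predictions, kept)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: VQAModel, path: str | Path,
                    extra: dict | None = None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "question_vocab": model.question_vocab.tokens,
        "answer_vocab": model.answer_vocab.tokens[2:],  # strip PAD/UNK
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> VQAModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ConfigError(f"unsupported checkpoint version {meta['version']}")
        cfg_dict = dict(meta["config"])
        cfg_dict["fusion_ranks"] = tuple(cfg_dict["fusion_ranks"])
        config = ModelConfig(**cfg_dict)
        qtokens = meta["question_vocab"][2:]  # stored with PAD/UNK prefix
        model = VQAModel(config, Vocabulary(qtokens),
                         Vocabulary(meta["answer_vocab"]))
        state = {k[len("param:"):]: data[k] for k in data.files
                 if k.startswith("param:")}
        if config.biba and not any(k.startswith("branch.") for k in state):
            # inference-only checkpoint: drop the branch structurally
            model.branch = None
            model._encoder_param_names = {
                name for name in model.named_parameters()
                if name.startswith(("embedding.", "question_encoder."))}
        model.load_state_dict(state)
    return model


def strip_branch(checkpoint_in: str | Path, checkpoint_out: str | Path) -> None:
    """Produce an inference-only checkpoint with the branch removed —
    the structural counterpart of removing the branch after training."""
    with np.load(checkpoint_in, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        kept = {k: data[k] for k in data.files
                if k != "meta" and not k.startswith("param:branch.")}
    meta["extra"]["branch_stripped"] = True
    np.savez(checkpoint_out, meta=json.dumps(meta), **kept)
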