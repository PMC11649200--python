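"""Attention heatmaps: where the model looks in the image for a question.

The final decoder layer's guided-attention weights (question stream over
image grid positions) are averaged over heads and valid question words,
reshaped to the extractor grid, upsampled, and alpha-blended over the
input image.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .encoders import GridExtractor, extract_image_features, tokenize
from .errors import InputError
from .model import Batch, VQAModel

__all__ = ["question_attention_map", "visualize_attention"]


def question_attention_map(model: VQAModel, image: np.ndarray,
                           question: str,
                           extractor: GridExtractor | None = None
                           ) -> np.ndarray:
    """Return the (g, g) question-to-image attention map; rows of the
    underlying weights sum to 1 and so does the returned map."""
    cfg = model.config
    extractor = extractor or GridExtractor(grid=cfg.grid, d_v=cfg.d_v,
                                           resize_to=cfg.resize_to, seed=cfg.seed)
    feats = extract_image_features(image, extractor).features
    if feats.shape[0] != extractor.grid ** 2:
        raise InputError("attention visualization requires grid-structured "
                         "image features")
    tok = tokenize(question, model.question_vocab, cfg.max_len)
    batch = Batch(token_ids=tok.token_ids[None], question_mask=(tok.token_ids != 0)[None],
                  image_features=feats[None],
                  soft_targets=np.zeros((1, model.n_answers)),
                  hard_targets=np.zeros(1, dtype=np.int64),
                  question_ids=["viz"], categories=["other"])
    model.main_logits(batch)
    weights = model.coattention.final_ga_weights  # (1, h, m, n_v)
    if weights is None:
        raise InputError("no attention weights recorded")
    mean_heads = weights[0].mean(axis=0)          # (m, n_v)
    valid = batch.question_mask[0]
    per_word = mean_heads[valid]                  # only real words
    grid_map = per_word.mean(axis=0)              # (n_v,), sums to 1
    g = extractor.grid
    return grid_map.reshape(g, g)


def visualize_attention(model: VQAModel, image: np.ndarray, question: str,
                        out_path: str | Path,
                        extractor: GridExtractor | None = None) -> np.ndarray:
    """Render the heatmap blended over the image and save a PNG."""
    grid_map = question_attention_map(model, image, question, extractor)
    h, w = np.asarray(image).shape[:2]
    up = np.kron(grid_map / grid_map.max(),
                 np.ones((h // grid_map.shape[0] + 1, w // grid_map.shape[1] + 1)))
    up = up[:h, :w]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(image))
    ax.imshow(up, cmap="jet", alpha=0.45, vmin=0.0, vmax=1.0)
    ax.set_title(question, fontsize=9)
    ax.axis("off")
    fig.savefig(out_path, format="png", bbox_inches="tight", dpi=100)
    plt.close(fig)
    return grid_map
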