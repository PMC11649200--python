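"""Question and image representations.

Questions are lowercased, stripped of punctuation, tokenized on whitespace,
truncated/padded to a fixed buffer (default 14 positions) and embedded with
a word table (GloVe-format text files are supported; tests use a small
seeded random table).  A single-layer LSTM produces per-position hidden
states; states at padded positions are zeroed so padding carries no
information downstream.

Images are resized (bilinear) to a square canvas — 448 x 448 at full scale
— and passed to a pluggable extractor emitting an (n_v, d_v) feature set.
The bundled extractor is a deterministic grid pooler: per-patch channel
statistics (mean, min, max) over a g x g grid, projected to d_v by a fixed
seeded matrix.  It needs no
pretrained weights; any backbone emitting (n_v, d_v) arrays can be plugged
in through the same callable interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .autodiff import Module, Parameter, Tensor, stack
from .errors import InputError, ShapeError

__all__ = [
    "PAD", "UNK",
    "Vocabulary",
    "TokenizedQuestion",
    "QuestionFeatures",
    "ImageFeatures",
    "normalize_text",
    "tokenize",
    "EmbeddingTable",
    "embed",
    "load_glove",
    "LSTMQuestionEncoder",
    "encode_question",
    "GridExtractor",
    "extract_image_features",
    "extract_region_features",
]

PAD = "<pad>"
UNK = "<unk>"

_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return _WS_RE.sub(" ", _PUNCT_RE.sub("", text.lower())).strip()


class Vocabulary:
    """Bijective token <-> index map with PAD fixed at index 0, UNK at 1."""

    def __init__(self, tokens: list[str] | None = None):
        self._tok2id: dict[str, int] = {PAD: 0, UNK: 1}
        self._id2tok: list[str] = [PAD, UNK]
        for t in tokens or []:
            self.add(t)

    def add(self, token: str) -> int:
        if token not in self._tok2id:
            self._tok2id[token] = len(self._id2tok)
            self._id2tok.append(token)
        return self._tok2id[token]

    def id(self, token: str) -> int:
        return self._tok2id.get(token, self._tok2id[UNK])

    def token(self, idx: int) -> str:
        return self._id2tok[idx]

    def __len__(self) -> int:
        return len(self._id2tok)

    def __contains__(self, token: str) -> bool:
        return token in self._tok2id

    @property
    def tokens(self) -> list[str]:
        return list(self._id2tok)

    @classmethod
    def from_texts(cls, texts: list[str]) -> "Vocabulary":
        vocab = cls()
        for text in texts:
            for tok in normalize_text(text).split():
                vocab.add(tok)
        return vocab


@dataclass
class TokenizedQuestion:
    token_ids: np.ndarray  # (max_len,) int
    length: int

    def __post_init__(self) -> None:
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)


@dataclass
class QuestionFeatures:
    """Per-word features (max_len, d_q) with a validity mask."""

    features: Tensor
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if not isinstance(self.features, Tensor):
            self.features = Tensor(self.features)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)


@dataclass
class ImageFeatures:
    """n_v region/grid feature vectors plus provenance."""

    features: np.ndarray  # (n_v, d_v)
    source: str = "grid"
    boxes: list[tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ShapeError("ImageFeatures must be a (n_v, d_v) matrix, n_v >= 1")
        if not np.isfinite(self.features).all():
            raise InputError("non-finite image features")


def tokenize(text: str, vocab: Vocabulary, max_len: int = 14) -> TokenizedQuestion:
    """Normalize, split, map to ids (UNK for OOV), truncate, pad with PAD."""
    norm = normalize_text(text)
    if not norm:
        raise InputError("question is empty after normalization")
    words = norm.split()[:max_len]
    ids = np.zeros(max_len, dtype=np.int64)
    for i, w in enumerate(words):
        ids[i] = vocab.id(w)
    return TokenizedQuestion(token_ids=ids, length=len(words))


class EmbeddingTable(Module):
    """Word-embedding lookup; the PAD row is pinned to zero."""

    def __init__(self, n_tokens: int, d_emb: int,
                 rng: np.random.Generator | None = None,
                 weights: np.ndarray | None = None, trainable: bool = True):
        if weights is not None:
            table = np.asarray(weights, dtype=np.float64).copy()
            if table.shape != (n_tokens, d_emb):
                raise ShapeError(f"embedding table shape {table.shape} != "
                                 f"({n_tokens}, {d_emb})")
        else:
            if rng is None:
                raise InputError("either weights or rng must be given")
            table = rng.normal(0.0, 0.1, size=(n_tokens, d_emb))
        table[0] = 0.0  # PAD
        self.d_emb = d_emb
        if trainable:
            self.table = Parameter(table)
        else:
            self.table = Tensor(table)

    def __call__(self, tokens: TokenizedQuestion) -> Tensor:
        return embed(tokens, self)


def embed(tokens: TokenizedQuestion, table: EmbeddingTable) -> Tensor:
    """Row i = table[token_ids[i]]; PAD rows are exactly zero."""
    ids = tokens.token_ids
    if ids.max(initial=0) >= table.table.shape[0]:
        raise InputError("token id outside embedding table")
    return table.table[ids]


def load_glove(path: str | Path, d_emb: int = 300) -> tuple[Vocabulary, np.ndarray]:
    """Read a GloVe-format text file (token followed by d_emb floats per line).

    Returns a vocabulary (PAD/UNK prepended) and the matching table with a
    zero PAD row and a zero UNK row.
    """
    vocab = Vocabulary()
    rows = [np.zeros(d_emb), np.zeros(d_emb)]
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d_emb + 1:
                raise InputError(
                    f"embedding line has {len(parts) - 1} values, expected {d_emb}")
            vocab.add(parts[0])
            rows.append(np.asarray(parts[1:], dtype=np.float64))
    return vocab, np.stack(rows)


class LSTMQuestionEncoder(Module):
    """Single-layer LSTM over the word embeddings.

    Emits the full hidden-state sequence (max_len, d_hidden); states at
    padded positions are zeroed, and because padding sits at the end of
    the buffer it cannot influence earlier states.
    """

    def __init__(self, d_emb: int, d_hidden: int, rng: np.random.Generator):
        self.d_emb = d_emb
        self.d_hidden = d_hidden
        k = 1.0 / np.sqrt(d_hidden)
        self.w_x = Parameter(rng.uniform(-k, k, size=(d_emb, 4 * d_hidden)))
        self.w_h = Parameter(rng.uniform(-k, k, size=(d_hidden, 4 * d_hidden)))
        self.bias = Parameter(np.zeros(4 * d_hidden))

    def __call__(self, embeddings: Tensor, valid_mask: np.ndarray) -> Tensor:
        """embeddings (..., max_len, d_emb), valid_mask (..., max_len)."""
        embeddings = Tensor._lift(embeddings)
        if embeddings.shape[-1] != self.d_emb:
            raise ShapeError(f"embedding width {embeddings.shape[-1]} != "
                             f"{self.d_emb}")
        valid_mask = np.asarray(valid_mask, dtype=bool)
        *lead, max_len, _ = embeddings.shape
        H = self.d_hidden
        h = Tensor(np.zeros((*lead, H)))
        c = Tensor(np.zeros((*lead, H)))
        outputs = []
        for t in range(max_len):
            x_t = embeddings[..., t, :]
            gates = x_t @ self.w_x + h @ self.w_h + self.bias
            i_g = gates[..., 0 * H:1 * H].sigmoid()
            f_g = gates[..., 1 * H:2 * H].sigmoid()
            g_g = gates[..., 2 * H:3 * H].tanh()
            o_g = gates[..., 3 * H:4 * H].sigmoid()
            c = f_g * c + i_g * g_g
            h = o_g * c.tanh()
            step_mask = valid_mask[..., t].astype(np.float64)[..., None]
            h = h * step_mask          # zero state at padded steps
            c = c * step_mask
            outputs.append(h)
        return stack(outputs, axis=-2)


def encode_question(embeddings: Tensor, valid_mask: np.ndarray,
                    encoder: LSTMQuestionEncoder) -> QuestionFeatures:
    feats = encoder(embeddings, valid_mask)
    return QuestionFeatures(features=feats, valid_mask=valid_mask)


def _to_array(image) -> np.ndarray:
    """Accept a path, PIL image, or [0,1] float array; return HxWx3 floats."""
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        except OSError as exc:
            raise IOError(f"cannot read image {image}: {exc}") from exc
        return arr
    if isinstance(image, Image.Image):
        return np.asarray(image.convert("RGB"), dtype=np.float64) / 255.0
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"expected HxWx3 image, got shape {arr.shape}")
    return arr


def _resize(arr: np.ndarray, size: int) -> np.ndarray:
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr
    im = Image.fromarray(np.clip(arr * 255.0, 0, 255).astype(np.uint8))
    im = im.resize((size, size), Image.BILINEAR)
    return np.asarray(im, dtype=np.float64) / 255.0


class GridExtractor:
    """Deterministic grid pooler: per-patch channel statistics (mean, min,
    max) over a g x g grid, projected to d_v.

    The projection matrix is drawn once from a seeded generator, standing
    in for a frozen pretrained backbone.  The min/max statistics make
    small high-contrast structures (disease spots) visible in a patch's
    feature vector even when they cover a minority of its pixels.
    ``resize_to`` defaults to the standard 448-pixel canvas; the grid must
    divide it.
    """

    def __init__(self, grid: int = 8, d_v: int = 16, resize_to: int = 448,
                 seed: int = 0):
        if resize_to % grid != 0:
            raise ShapeError(f"grid {grid} must divide resize_to {resize_to}")
        self.grid = grid
        self.d_v = d_v
        self.resize_to = resize_to
        rng = np.random.default_rng(seed)
        self.projection = rng.normal(0.0, 1.0, size=(9, d_v)) / np.sqrt(9.0)
        self.name = f"grid{grid}x{grid}-d{d_v}"

    @property
    def n_features(self) -> int:
        return self.grid * self.grid

    def __call__(self, arr: np.ndarray) -> np.ndarray:
        arr = _resize(arr, self.resize_to)
        g = self.grid
        p = self.resize_to // g
        tiles = arr.reshape(g, p, g, p, 3)
        stats = np.concatenate([tiles.mean(axis=(1, 3)),
                                tiles.min(axis=(1, 3)),
                                tiles.max(axis=(1, 3))], axis=-1)  # (g, g, 9)
        return stats.reshape(g * g, 9) @ self.projection


def extract_image_features(image, extractor: GridExtractor) -> ImageFeatures:
    """Resize to the extractor's canvas and emit its (n_v, d_v) features."""
    arr = _to_array(image)
    return ImageFeatures(features=extractor(arr), source=extractor.name)


def extract_region_features(image, boxes, extractor: GridExtractor) -> ImageFeatures:
    """One pooled feature row per (x, y, w, h) pixel box."""
    arr = _to_array(image)
    h_img, w_img = arr.shape[:2]
    rows = []
    for (x, y, w, h) in boxes:
        if w <= 0 or h <= 0:
            raise InputError(f"degenerate box {(x, y, w, h)}")
        if x < 0 or y < 0 or x + w > w_img or y + h > h_img:
            raise InputError(f"box {(x, y, w, h)} outside {w_img}x{h_img} image")
        crop = arr[int(round(y)):int(round(y + h)), int(round(x)):int(round(x + w))]
        rows.append(extractor(crop).mean(axis=0))
    return ImageFeatures(features=np.stack(rows), source=extractor.name,
                         boxes=[tuple(map(float, b)) for b in boxes])


class FeatureCache:
    """HDF5-backed store of extracted image features keyed by image id.

    Lets a corpus be featurized once and reused across runs; values are
    (n_v, d_v) float arrays.
    """

    def __init__(self, path: str | Path, mode: str = "a"):
        import h5py
        self._h5 = h5py.File(path, mode)

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._h5

    def put(self, image_id: str, features: ImageFeatures) -> None:
        if image_id in self._h5:
            del self._h5[image_id]
        ds = self._h5.create_dataset(image_id, data=features.features)
        ds.attrs["source"] = features.source

    def get(self, image_id: str) -> ImageFeatures:
        ds = self._h5[image_id]
        return ImageFeatures(features=ds[...], source=ds.attrs.get("source", "cache"))

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "FeatureCache":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
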