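"""Dataset augmentation: Gaussian noise, multiscale Retinex (MSRCR and
MSRCP), random rotation, and the three text operations (lowercasing,
keyword substitution/deletion, punctuation removal).

All image operations act on float images in [0, 1] and return images in
[0, 1]; every stochastic operation draws from an explicitly passed
generator so a fixed master seed reproduces the augmented corpus exactly.
Noise defaults follow the protocol variances sigma^2 in {0.1, 0.01}; the
rotation range defaults to [60, 120] degrees; Retinex surround scales
default to the customary {15, 80, 250} with equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dataset_io import VQATriple
from .errors import ConfigError, InputError
from .encoders import normalize_text, _PUNCT_RE

__all__ = [
    "AugmentationPlan",
    "add_gaussian_noise",
    "single_scale_retinex",
    "msrcr",
    "msrcp",
    "rotate_image",
    "random_rotate",
    "augment_text",
    "expand_dataset",
]

_EPS = 1e-6


@dataclass
class AugmentationPlan:
    """Parameters of the augmentation protocol.

    noise_variances : sigma^2 values; each enabled value yields one noisy
                      copy per image (defaults 0.1 and 0.01)
    rotation_range  : (min_deg, max_deg), default (60, 120)
    retinex_scales  : Gaussian-surround standard deviations in pixels
    retinex_gain / retinex_offset : output mapping of MSRCR
    color_restore_alpha / color_restore_beta : MSRCR color-restoration factors
    enable_*        : which image/text operations expand_dataset applies
    oversample_categories : stratified oversampling to balance question
                      categories
    seed            : master seed; scene/noise/rotation streams are derived
                      from it
    """

    noise_variances: list[float] = field(default_factory=lambda: [0.1, 0.01])
    rotation_range: tuple[float, float] = (60.0, 120.0)
    retinex_scales: list[float] = field(default_factory=lambda: [15.0, 80.0, 250.0])
    retinex_gain: float = 1.0
    retinex_offset: float = 0.0
    color_restore_alpha: float = 125.0
    color_restore_beta: float = 0.35
    enable_noise: bool = True
    enable_msrcr: bool = True
    enable_msrcp: bool = True
    enable_rotation: bool = True
    enable_text_ops: bool = True
    oversample_categories: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.noise_variances):
            raise InputError("noise variances must be >= 0")
        lo, hi = self.rotation_range
        if not (0.0 < lo <= hi < 360.0):
            raise InputError("rotation range must lie within (0, 360) degrees")
        if not self.retinex_scales:
            raise InputError("at least one retinex scale is required")
        if any(s <= 0 for s in self.retinex_scales):
            raise InputError("retinex scales must be positive")

    def enabled_image_ops(self) -> list[str]:
        ops = []
        if self.enable_noise:
            ops += [f"noise{v:g}" for v in self.noise_variances]
        if self.enable_msrcr:
            ops.append("msrcr")
        if self.enable_msrcp:
            ops.append("msrcp")
        if self.enable_rotation:
            ops.append("rotate")
        return ops


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise InputError("image values must lie in [0, 1]")
    return arr


def sample_noise_field(shape, variance: float,
                       rng: np.random.Generator) -> np.ndarray:
    """The i.i.d. N(0, sigma^2) field added by add_gaussian_noise."""
    if variance < 0:
        raise InputError("variance must be >= 0")
    if variance == 0:
        return np.zeros(shape)
    return rng.normal(0.0, np.sqrt(variance), size=shape)


def add_gaussian_noise(image: np.ndarray, variance: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Pixel-wise i.i.d. N(0, sigma^2) noise, clipped back to [0, 1].

    Clipping truncates the tails of the displayed noise wherever the sum
    leaves [0, 1]; the raw field (sample_noise_field) carries the exact
    moments."""
    arr = _check_image(image)
    noise = sample_noise_field(arr.shape, variance, rng)
    if variance == 0:
        return arr.copy()
    return np.clip(arr + noise, 0.0, 1.0)


def single_scale_retinex(image: np.ndarray, scale: float) -> np.ndarray:
    """log(I) - log(G_scale * I) per channel (Gaussian surround).

    The result is a signed log-ratio map, not a displayable image; the
    multiscale operators below recombine and rescale it.  Images are
    floored at a small epsilon before the logarithms.
    """
    if scale <= 0:
        raise InputError("retinex scale must be positive")
    arr = np.maximum(np.asarray(image, dtype=np.float64), _EPS)
    out = np.empty_like(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        out = out.reshape(*arr.shape)
    for ch in range(arr.shape[2]):
        blur = ndimage.gaussian_filter(arr[:, :, ch], sigma=scale, mode="nearest")
        out[:, :, ch] = np.log(arr[:, :, ch]) - np.log(np.maximum(blur, _EPS))
    return out.reshape(np.asarray(image).shape)


def _multi_scale_retinex(arr: np.ndarray, scales: list[float]) -> np.ndarray:
    acc = np.zeros_like(arr, dtype=np.float64)
    for s in scales:
        acc += single_scale_retinex(arr, s)
    return acc / len(scales)


def msrcr(image: np.ndarray, plan: AugmentationPlan) -> np.ndarray:
    """Multiscale Retinex with color restoration.

    msr  = mean over scales of the per-channel log-ratio maps
    C_ch = beta * (log(alpha * I_ch) - log(sum_ch I_ch))   (color restoration)
    out  = clip(gain * stretch(C (.) msr) + offset)

    where stretch maps mean +/- 2 std of the restored map onto [0, 1]
    (the customary final step; the log-ratio compresses the dynamic range
    while the restoration term counteracts the graying-out of color)."""
    arr = _check_image(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError("msrcr expects an RGB image")
    msr = _multi_scale_retinex(arr, plan.retinex_scales)
    floored = np.maximum(arr, _EPS)
    chroma = np.log(plan.color_restore_alpha * floored) - \
        np.log(floored.sum(axis=2, keepdims=True))
    restored = plan.color_restore_beta * chroma * msr
    mu, sd = restored.mean(), restored.std()
    if sd < 1e-12:
        stretched = np.full_like(restored, 0.5)
    else:
        stretched = (restored - (mu - 2.0 * sd)) / (4.0 * sd)
    return np.clip(plan.retinex_gain * stretched + plan.retinex_offset, 0.0, 1.0)


def msrcp(image: np.ndarray, plan: AugmentationPlan) -> np.ndarray:
    """Multiscale Retinex with chromaticity preservation.

    The retinex is computed on the intensity channel only and stretched to
    [0, 1]; each pixel's RGB is then rescaled by a single scalar, so the
    R:G:B ratios (hue) are preserved exactly."""
    arr = _check_image(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError("msrcp expects an RGB image")
    intensity = arr.mean(axis=2)
    msr = _multi_scale_retinex(intensity, plan.retinex_scales)
    lo, hi = msr.min(), msr.max()
    stretched = (msr - lo) / (hi - lo) if hi > lo else np.full_like(msr, 0.5)
    floored = np.maximum(intensity, _EPS)
    peak = np.maximum(arr.max(axis=2), _EPS)
    # per-pixel amplification, capped so no channel exceeds 1
    amp = np.minimum(stretched / floored, 1.0 / peak)
    out = arr * amp[:, :, None]
    return np.clip(out, 0.0, 1.0)


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the center with reflection padding (bilinear)."""
    arr = _check_image(image)
    out = ndimage.rotate(arr, angle_deg, axes=(1, 0), reshape=False,
                         order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def random_rotate(image: np.ndarray, plan: AugmentationPlan,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Rotate by an angle drawn uniformly from the plan's range; the angle
    is returned for provenance logging."""
    lo, hi = plan.rotation_range
    angle = float(rng.uniform(lo, hi))
    return rotate_image(image, angle), angle


def augment_text(question: str, synonym_table: dict[str, str] | None = None,
                 rng: np.random.Generator | None = None) -> list[str]:
    """Text variants: lowercase; punctuation-stripped; keyword-substituted
    (synonym-table driven); keyword-deleted.  Deduplicated, original first.

    The synonym table must map within answer-equivalent phrases so labels
    stay valid by construction.
    """
    if not question.strip():
        raise InputError("empty question")
    variants = [question]
    variants.append(question.lower())
    variants.append(_PUNCT_RE.sub("", question))
    if synonym_table is not None:
        if not synonym_table:
            raise ConfigError("substitution requested with an empty synonym table")
        substituted = question.lower()
        deleted_words = []
        for word in substituted.split():
            key = normalize_text(word)
            if key in synonym_table:
                substituted = substituted.replace(word, synonym_table[key])
            else:
                deleted_words.append(word)
        variants.append(substituted)
        # keyword deletion: drop the table's keywords if >1 word remains
        if deleted_words and len(deleted_words) < len(substituted.split()):
            variants.append(" ".join(deleted_words))
    seen, out = set(), []
    for v in variants:
        if v not in seen and v.strip():
            seen.add(v)
            out.append(v)
    return out


def expand_dataset(triples: list[VQATriple], images: dict[str, np.ndarray],
                   plan: AugmentationPlan,
                   synonym_table: dict[str, str] | None = None
                   ) -> tuple[list[VQATriple], dict[str, np.ndarray], list[dict]]:
    """Apply every enabled operation, returning (triples, images, provenance).

    Each enabled image operation produces one derived image per source
    image, carrying copies of the source's QA records (labels unchanged);
    with k operations enabled the image count is multiplied by (1 + k).
    Text variants add question records on the original images.  Optional
    stratified oversampling (with replacement) balances question-category
    frequencies.  Derived records get fresh ids; a provenance entry is
    logged per derived record.
    """
    rng_noise = np.random.default_rng([plan.seed, 1])
    rng_rot = np.random.default_rng([plan.seed, 2])
    rng_sample = np.random.default_rng([plan.seed, 3])
    out_triples = list(triples)
    out_images = dict(images)
    provenance: list[dict] = []
    by_image: dict[str, list[VQATriple]] = {}
    for t in triples:
        by_image.setdefault(t.image_id, []).append(t)

    for op in plan.enabled_image_ops():
        for image_id in sorted(by_image):
            arr = images[image_id]
            extra: dict = {}
            if op.startswith("noise"):
                var = float(op[len("noise"):])
                derived = add_gaussian_noise(arr, var, rng_noise)
                extra["variance"] = var
            elif op == "msrcr":
                derived = msrcr(arr, plan)
            elif op == "msrcp":
                derived = msrcp(arr, plan)
            else:
                derived, angle = random_rotate(arr, plan, rng_rot)
                extra["angle_deg"] = angle
            new_image_id = f"{image_id}__{op}"
            out_images[new_image_id] = derived
            for t in by_image[image_id]:
                new_qid = f"{t.question_id}__{op}"
                out_triples.append(VQATriple(
                    **{**t.__dict__, "image_id": new_image_id,
                       "question_id": new_qid}))
                provenance.append({"op": op, "source_question": t.question_id,
                                   "question_id": new_qid,
                                   "image_id": new_image_id, **extra})

    if plan.enable_text_ops:
        for t in triples:
            for i, variant in enumerate(augment_text(t.question, synonym_table)):
                if variant == t.question:
                    continue
                new_qid = f"{t.question_id}__text{i}"
                out_triples.append(VQATriple(
                    **{**t.__dict__, "question": variant,
                       "question_id": new_qid}))
                provenance.append({"op": "text", "variant": variant,
                                   "source_question": t.question_id,
                                   "question_id": new_qid})

    if plan.oversample_categories:
        counts = {}
        for t in out_triples:
            counts[t.question_category] = counts.get(t.question_category, 0) + 1
        target = max(counts.values())
        for cat, n in sorted(counts.items()):
            pool = [t for t in out_triples if t.question_category == cat]
            for j in range(target - n):
                src = pool[int(rng_sample.integers(len(pool)))]
                new_qid = f"{src.question_id}__os{j}"
                out_triples.append(VQATriple(
                    **{**src.__dict__, "question_id": new_qid}))
                provenance.append({"op": "oversample",
                                   "source_question": src.question_id,
                                   "question_id": new_qid})
    return out_triples, out_images, provenance
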