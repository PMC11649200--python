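"""Synthetic crop-disease VQA corpus with controllable unimodal bias.

Scenes are 64 x 64 renders of a single fruit (circle or ellipse) that may
carry colored disease spots.  Attribute-templated questions — disease
status (yes/no), spot count (number), spot color / fruit shape / spot size
(other) — are answered exactly from the scene specification, so model
accuracy is measurable without human annotation.

The generator's central control is the train-set answer prior: with
bias_strength beta (default 0.9) the marked answer of the biased template
("brown" for "what color is the spot?") appears with frequency beta in the
training scenes, while test scenes are drawn from the *complementary*
prior, normalized (1 - p).  A question-only classifier therefore scores
about beta on the biased template in training data but near chance on the
anti-biased test — the signature of unimodal bias the bias-balancing
strategy is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .dataset_io import VQATriple
from .errors import InputError

__all__ = [
    "PALETTE",
    "SPOT_COLORS",
    "SceneSpec",
    "BiasSpec",
    "render_scene",
    "questions_for_scene",
    "triples_for_scene",
    "generate_biased_corpus",
    "BIASED_TEMPLATE",
]

# closed six-color palette (name -> RGB in [0, 255])
PALETTE: dict[str, tuple[int, int, int]] = {
    "red": (200, 40, 40),
    "green": (60, 160, 60),
    "yellow": (220, 200, 50),
    "brown": (130, 80, 30),
    "purple": (130, 60, 160),
    "blue": (50, 80, 200),
}
FRUIT_COLORS = ("red", "green", "yellow")
SPOT_COLORS = ("brown", "purple", "blue", "yellow", "red")
BACKGROUND = (235, 235, 225)

BIASED_TEMPLATE = "what color is the spot"
_MARKED_ANSWER = "brown"


@dataclass
class SceneSpec:
    """Deterministic description of one scene."""

    fruit_shape: str = "circle"          # circle | ellipse
    fruit_color: str = "red"
    spot_count: int = 0                  # 0..5; diseased <=> spot_count > 0
    spot_color: str = "brown"
    spot_size: str = "small"             # small | large
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fruit_shape not in ("circle", "ellipse"):
            raise InputError(f"unknown fruit shape {self.fruit_shape!r}")
        if self.fruit_color not in PALETTE or self.spot_color not in PALETTE:
            raise InputError("colors must come from the closed palette")
        if not (0 <= self.spot_count <= 5):
            raise InputError("spot count must lie in [0, 5]")
        if self.spot_size not in ("small", "large"):
            raise InputError(f"unknown spot size {self.spot_size!r}")

    @property
    def diseased(self) -> bool:
        return self.spot_count > 0


@dataclass
class BiasSpec:
    """Train-prior skew of the biased question template.

    bias_strength : beta, the train frequency of the marked answer
    marked_answer : the over-represented answer (default "brown")
    anti_bias_test: draw test scenes from the normalized complementary
                    prior (1 - p) instead of the training prior
    """

    bias_strength: float = 0.9
    marked_answer: str = _MARKED_ANSWER
    anti_bias_test: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias_strength <= 1.0):
            raise InputError("bias_strength must lie in [0, 1]")
        if self.marked_answer not in SPOT_COLORS:
            raise InputError(f"marked answer {self.marked_answer!r} is not a "
                             "spot color")

    def train_prior(self) -> dict[str, float]:
        beta = self.bias_strength
        others = [c for c in SPOT_COLORS if c != self.marked_answer]
        prior = {c: (1.0 - beta) / len(others) for c in others}
        prior[self.marked_answer] = beta
        return prior

    def test_prior(self) -> dict[str, float]:
        if not self.anti_bias_test:
            return self.train_prior()
        train = self.train_prior()
        comp = {c: 1.0 - p for c, p in train.items()}
        z = sum(comp.values())
        return {c: p / z for c, p in comp.items()}


def render_scene(spec: SceneSpec) -> np.ndarray:
    """Rasterize the scene; byte-identical output for equal specs.

    Returns an (image_size, image_size, 3) float array in [0, 1].  Spots
    are placed without overlap by seeded rejection sampling; failure to
    place them is an input error (cannot happen for counts <= 5 at the
    default canvas size).
    """
    s = spec.image_size
    im = Image.new("RGB", (s, s), BACKGROUND)
    draw = ImageDraw.Draw(im)
    cx, cy = s // 2, s // 2
    if spec.fruit_shape == "circle":
        rx = ry = int(s * 0.40)
    else:
        rx, ry = int(s * 0.44), int(s * 0.32)
    draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry],
                 fill=PALETTE[spec.fruit_color])
    rng = np.random.default_rng([spec.seed, 97])
    # spot radii sized so a spot dominates at least one extractor patch
    r_spot = max(2, int(s * (0.07 if spec.spot_size == "small" else 0.10)))
    # non-overlapping placement: seeded choice from a lattice of candidate
    # centers inside the fruit, with a little jitter when there is slack
    spacing = 2 * r_spot + 2
    margin_x, margin_y = rx - r_spot - 1, ry - r_spot - 1
    candidates = []
    for gx in np.arange(-margin_x, margin_x + 1e-9, spacing):
        for gy in np.arange(-margin_y, margin_y + 1e-9, spacing):
            px, py = gx + spacing / 2, gy + spacing / 2  # cell centers
            if (px / margin_x) ** 2 + (py / margin_y) ** 2 <= 1.0:
                candidates.append((cx + px, cy + py))
    if len(candidates) < spec.spot_count:
        raise InputError(
            f"cannot place {spec.spot_count} non-overlapping spots of "
            f"radius {r_spot} on a {s}x{s} canvas")
    idx = rng.choice(len(candidates), size=spec.spot_count, replace=False)
    jitter = 0.5
    for i in idx:
        px, py = candidates[int(i)]
        px += rng.uniform(-jitter, jitter)
        py += rng.uniform(-jitter, jitter)
        draw.ellipse([px - r_spot, py - r_spot, px + r_spot, py + r_spot],
                     fill=PALETTE[spec.spot_color])
    return np.asarray(im, dtype=np.float64) / 255.0


def questions_for_scene(spec: SceneSpec) -> list[tuple[str, str, str]]:
    """Template questions with exact answers: (question, answer, category)."""
    qs = [
        ("is the fruit diseased?", "yes" if spec.diseased else "no", "yes/no"),
        ("how many spots are there?", str(spec.spot_count), "number"),
        ("what shape is the fruit?", spec.fruit_shape, "other"),
        ("what color is the fruit?", spec.fruit_color, "other"),
    ]
    if spec.diseased:
        qs.append(("what color is the spot?", spec.spot_color, "other"))
        qs.append(("what is the size of the spot?", spec.spot_size, "other"))
    return qs


def _candidate_answers(truth: str, category: str, question: str,
                       rng: np.random.Generator) -> list[tuple[str, str]]:
    """Ten confidence-labeled candidates: the truth repeated with
    confidence "yes" plus plausible same-domain distractors as "maybe"."""
    if category == "yes/no":
        domain = ["yes", "no"]
    elif category == "number":
        domain = [str(i) for i in range(6)]
    elif "color" in question:
        domain = (list(FRUIT_COLORS) if "fruit" in question
                  else list(SPOT_COLORS))
    elif "shape" in question:
        domain = ["circle", "ellipse"]
    else:
        domain = ["small", "large"]
    distractors = [a for a in domain if a != truth]
    k = min(len(distractors), 2)
    chosen = list(rng.choice(distractors, size=k, replace=False)) if k else []
    answers = [(truth, "yes")] * (10 - k) + [(str(c), "maybe") for c in chosen]
    return answers


def _sample_spec(rng: np.random.Generator, prior: dict[str, float],
                 seed: int, image_size: int) -> SceneSpec:
    colors = list(prior)
    probs = np.asarray([prior[c] for c in colors])
    spot_color = str(rng.choice(colors, p=probs / probs.sum()))
    fruit_color = str(rng.choice([c for c in FRUIT_COLORS if c != spot_color]))
    # 1-in-6 healthy scenes keep the yes/no template informative
    spot_count = int(rng.integers(0, 6))
    return SceneSpec(
        fruit_shape=str(rng.choice(["circle", "ellipse"])),
        fruit_color=fruit_color,
        spot_count=spot_count,
        spot_color=spot_color,
        spot_size=str(rng.choice(["small", "large"])),
        image_size=image_size,
        seed=seed,
    )


def triples_for_scene(spec: SceneSpec, image_id: str,
                      rng: np.random.Generator) -> list[VQATriple]:
    triples = []
    for j, (question, answer, category) in enumerate(questions_for_scene(spec)):
        answer_type = ("yes/no" if category == "yes/no"
                       else "number" if category == "number"
                       else "color" if "color" in question else "other")
        triples.append(VQATriple(
            image_id=image_id,
            question_id=f"{image_id}_q{j}",
            question=question,
            answers=_candidate_answers(answer, category, question, rng),
            question_category=category,
            answer_type=answer_type))
    return triples


def generate_biased_corpus(n_scenes: int, bias: BiasSpec | None = None,
                           seed: int = 0, image_size: int = 64,
                           val_fraction: float = 0.15,
                           test_fraction: float = 0.3
                           ) -> tuple[list[VQATriple], list[VQATriple],
                                      list[VQATriple],
                                      dict[str, np.ndarray],
                                      dict[str, SceneSpec]]:
    """Generate (train, val, test) triples plus rendered images and specs.

    ``n_scenes`` counts training scenes; validation scenes follow the
    training prior, test scenes the complementary (anti-biased) prior.
    One master seed fans out to independent scene/answer streams.
    Returns (train, val, test, images, specs) where images and specs are
    keyed by image id.
    """
    if n_scenes < 30:
        raise InputError("n_scenes must be >= 30 for a usable corpus")
    bias = bias or BiasSpec()
    rng_scene = np.random.default_rng([seed, 11])
    rng_ans = np.random.default_rng([seed, 13])
    images: dict[str, np.ndarray] = {}
    specs: dict[str, SceneSpec] = {}

    def make(split: str, count: int, prior: dict[str, float]) -> list[VQATriple]:
        out: list[VQATriple] = []
        for i in range(count):
            scene_seed = int(rng_scene.integers(0, 2 ** 31 - 1))
            spec = _sample_spec(rng_scene, prior, scene_seed, image_size)
            image_id = f"{split}_{i:05d}"
            images[image_id] = render_scene(spec)
            specs[image_id] = spec
            out.extend(triples_for_scene(spec, image_id, rng_ans))
        return out

    n_val = max(5, int(round(n_scenes * val_fraction)))
    n_test = max(10, int(round(n_scenes * test_fraction)))
    train = make("train", n_scenes, bias.train_prior())
    val = make("val", n_val, bias.train_prior())
    test = make("test", n_test, bias.test_prior())
    return train, val, test, images, specs
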