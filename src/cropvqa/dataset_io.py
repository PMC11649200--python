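"""VQA-dialect dataset plumbing: reading/writing question and annotation
JSON files, the answer vocabulary, soft answer targets, image-level 8:1:1
splitting, prior-knowledge merging, and the category-wise accuracy metric.

The on-disk dialect mirrors the VQA-v2 layout: a questions file
``{"questions": [{"image_id", "question_id", "question"}]}`` and an
annotations file whose records carry exactly ten confidence-labeled
candidate answers (confidence "yes" or "maybe"), a question category from
{yes/no, number, other} and an answer type from {number, color, yes/no,
other}.  Prior-knowledge records additionally carry region bounding boxes.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoders import Vocabulary, normalize_text
from .errors import ConfigError, InputError

__all__ = [
    "QUESTION_CATEGORIES",
    "ANSWER_TYPES",
    "VQATriple",
    "EvaluationReport",
    "read_dataset",
    "write_dataset",
    "build_answer_vocab",
    "soft_targets",
    "split_dataset",
    "merge_prior_knowledge",
    "evaluate",
]

logger = logging.getLogger(__name__)

QUESTION_CATEGORIES = ("yes/no", "number", "other")
ANSWER_TYPES = ("number", "color", "yes/no", "other")
CONFIDENCES = ("yes", "maybe")
N_CANDIDATES = 10


@dataclass
class VQATriple:
    """One (image, question, answers) record.

    answers: exactly 10 (answer text, confidence) pairs, confidence in
    {"yes", "maybe"}.  Records derived from the prior-knowledge pipeline
    carry region boxes (x, y, w, h in pixels) and source "prior".
    """

    image_id: str
    question_id: str
    question: str
    answers: list[tuple[str, str]]
    question_category: str
    answer_type: str = "other"
    boxes: list[tuple[float, float, float, float]] | None = None
    source: str = "base"

    def __post_init__(self) -> None:
        if len(self.answers) != N_CANDIDATES:
            raise InputError(
                f"question {self.question_id}: expected {N_CANDIDATES} candidate "
                f"answers, got {len(self.answers)}")
        self.answers = [(str(a), str(c)) for a, c in self.answers]
        bad = {c for _, c in self.answers} - set(CONFIDENCES)
        if bad:
            raise InputError(f"question {self.question_id}: bad confidences {bad}")
        if self.question_category not in QUESTION_CATEGORIES:
            raise InputError(
                f"question {self.question_id}: unknown category "
                f"{self.question_category!r}")
        if self.answer_type not in ANSWER_TYPES:
            raise InputError(
                f"question {self.question_id}: unknown answer type "
                f"{self.answer_type!r}")

    def ground_truths(self) -> list[str]:
        """Normalized answers carried with confidence 'yes'."""
        return [normalize_text(a) for a, c in self.answers if c == "yes"]


@dataclass
class EvaluationReport:
    """Category-wise accuracy with TP/TN/FP/FN counts.

    For yes/no questions "yes" is the positive class; for number/other
    questions a correct prediction counts as TP and an incorrect one as
    FP (TN = FN = 0), so accuracy = (TP + TN) / N in every category.
    Overall accuracy is the question-weighted mean of the categories.
    """

    overall: float
    per_category: dict[str, float]
    counts: dict[str, dict[str, int]]

    def to_csv(self) -> str:
        lines = ["category,accuracy,TP,TN,FP,FN,N"]
        for cat in QUESTION_CATEGORIES:
            c = self.counts.get(cat, dict(TP=0, TN=0, FP=0, FN=0, N=0))
            acc = self.per_category.get(cat, float("nan"))
            lines.append(f"{cat},{acc:.4f},{c['TP']},{c['TN']},{c['FP']},"
                         f"{c['FN']},{c['N']}")
        total_n = sum(c["N"] for c in self.counts.values())
        lines.append(f"overall,{self.overall:.4f},,,,,{total_n}")
        return "\n".join(lines) + "\n"


def _triple_to_records(t: VQATriple) -> tuple[dict, dict]:
    q = {"image_id": t.image_id, "question_id": t.question_id,
         "question": t.question}
    a = {"question_id": t.question_id, "image_id": t.image_id,
         "answers": [{"answer": ans, "answer_confidence": conf}
                     for ans, conf in t.answers],
         "question_category": t.question_category,
         "answer_type": t.answer_type,
         "source": t.source}
    if t.boxes is not None:
        a["regions"] = [list(b) for b in t.boxes]
    return q, a


def write_dataset(triples: list[VQATriple], questions_path: str | Path,
                  annotations_path: str | Path) -> None:
    qs, anns = [], []
    for t in triples:
        q, a = _triple_to_records(t)
        qs.append(q)
        anns.append(a)
    Path(questions_path).write_text(json.dumps({"questions": qs}, indent=1))
    Path(annotations_path).write_text(json.dumps({"annotations": anns}, indent=1))


def read_dataset(questions_path: str | Path, annotations_path: str | Path,
                 images_dir: str | Path | None = None) -> list[VQATriple]:
    """Join the questions and annotations files on question_id.

    Records violating the ten-answer invariant are rejected with a logged
    reason; an annotation without a matching question (or vice versa) is an
    error; a missing image file is a logged warning only.
    """
    questions = json.loads(Path(questions_path).read_text())["questions"]
    annotations = json.loads(Path(annotations_path).read_text())["annotations"]
    ann_by_id = {a["question_id"]: a for a in annotations}
    if len(ann_by_id) != len(annotations):
        raise InputError("duplicate question_id in annotations")
    triples: list[VQATriple] = []
    seen = set()
    for q in questions:
        qid = q["question_id"]
        if qid not in ann_by_id:
            raise InputError(f"question {qid} has no annotation record")
        seen.add(qid)
        a = ann_by_id[qid]
        boxes = ([tuple(b) for b in a["regions"]] if "regions" in a else None)
        try:
            triples.append(VQATriple(
                image_id=str(q["image_id"]), question_id=str(qid),
                question=q["question"],
                answers=[(x["answer"], x["answer_confidence"])
                         for x in a["answers"]],
                question_category=a.get("question_category", "other"),
                answer_type=a.get("answer_type", "other"),
                boxes=boxes, source=a.get("source", "base")))
        except InputError as exc:
            logger.warning("rejected record %s: %s", qid, exc)
            continue
        if images_dir is not None:
            img = Path(images_dir) / f"{q['image_id']}.png"
            if not img.exists():
                logger.warning("image file missing for %s: %s", qid, img)
    dangling = set(ann_by_id) - seen
    if dangling:
        raise InputError(f"annotations without questions: {sorted(dangling)[:5]}")
    return triples


def build_answer_vocab(triples: list[VQATriple], min_freq: int = 1) -> Vocabulary:
    """Answer vocabulary over normalized answer strings, ordered by
    descending frequency then lexicographically (deterministic)."""
    if not triples:
        raise InputError("cannot build an answer vocabulary from no triples")
    counts: Counter[str] = Counter()
    for t in triples:
        for ans, _conf in t.answers:
            counts[normalize_text(ans)] += 1
    kept = sorted((a for a, n in counts.items() if n >= min_freq and a),
                  key=lambda a: (-counts[a], a))
    if not kept:
        raise ConfigError(f"no answers survive min_freq={min_freq}")
    return Vocabulary(kept)


def soft_targets(triple: VQATriple, vocab: Vocabulary) -> np.ndarray:
    """Per-vocabulary-answer supervision: max over the triple's confidences
    for that answer, yes -> 1.0, maybe -> 0.5; out-of-vocab answers ignored.

    The returned vector is indexed by the answer vocabulary (special tokens
    included, always 0 there).  Raises InputError when no answer is in
    vocabulary (callers should skip and log such records).
    """
    target = np.zeros(len(vocab))
    score = {"yes": 1.0, "maybe": 0.5}
    hit = False
    for ans, conf in triple.answers:
        norm = normalize_text(ans)
        if norm in vocab:
            idx = vocab.id(norm)
            target[idx] = max(target[idx], score[conf])
            hit = True
    if not hit:
        raise InputError(f"question {triple.question_id}: no in-vocab answer")
    return target


def split_dataset(triples: list[VQATriple], ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> tuple[list[VQATriple], list[VQATriple],
                                          list[VQATriple]]:
    """Split at the image level so all questions of an image (including any
    augmented copies sharing its id) land in one split.  Image counts per
    split follow the ratios by largest remainder; the shuffle is seeded."""
    if min(ratios) <= 0:
        raise InputError("split ratios must be positive")
    image_ids = sorted({t.image_id for t in triples})
    if len(image_ids) < len(ratios):
        raise InputError(f"need at least {len(ratios)} images, got {len(image_ids)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(image_ids)
    total = sum(ratios)
    n = len(image_ids)
    exact = [n * r / total for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    splits: list[set[str]] = []
    start = 0
    for c in counts:
        splits.append(set(image_ids[start:start + c]))
        start += c
    out = tuple([t for t in triples if t.image_id in s] for s in splits)
    return out  # type: ignore[return-value]


def merge_prior_knowledge(base_triples: list[VQATriple],
                          pk_triples: list[VQATriple]) -> list[VQATriple]:
    """Union of the base training set and region-annotated prior-knowledge
    records; sources tagged, counts additive, duplicate ids rejected."""
    for t in pk_triples:
        if t.boxes is None or not t.boxes:
            raise InputError(
                f"prior-knowledge record {t.question_id} carries no region boxes")
    base_ids = {t.question_id for t in base_triples}
    dup = base_ids & {t.question_id for t in pk_triples}
    if dup:
        raise InputError(f"duplicate question_id across sources: {sorted(dup)[:5]}")
    merged = list(base_triples)
    for t in pk_triples:
        t = VQATriple(**{**t.__dict__, "source": "prior"})
        merged.append(t)
    return merged


def evaluate(predictions: dict[str, str], truths: list[VQATriple],
             include_maybe: bool = False) -> EvaluationReport:
    """Category-wise plain accuracy of predicted answer strings.

    A prediction is correct iff its normalized form equals one of the
    record's confident ("yes") ground-truth answers; ``include_maybe``
    widens the correct set to all ten candidates.  Accuracy per category
    is (TP + TN) / N; overall is the question-weighted mean.
    """
    by_id = {t.question_id: t for t in truths}
    unknown = set(predictions) - set(by_id)
    if unknown:
        raise InputError(f"predictions for unknown question_id: {sorted(unknown)[:5]}")
    missing = set(by_id) - set(predictions)
    if missing:
        raise InputError(f"no prediction for question_id: {sorted(missing)[:5]}")
    counts = {cat: dict(TP=0, TN=0, FP=0, FN=0, N=0) for cat in QUESTION_CATEGORIES}
    for qid, t in by_id.items():
        pred = normalize_text(predictions[qid])
        gold = set(t.ground_truths())
        if include_maybe:
            gold |= {normalize_text(a) for a, _ in t.answers}
        correct = pred in gold
        c = counts[t.question_category]
        c["N"] += 1
        if t.question_category == "yes/no":
            gold_yes = "yes" in gold
            if correct:
                c["TP" if gold_yes else "TN"] += 1
            else:
                c["FP" if pred == "yes" else "FN"] += 1
        else:
            c["TP" if correct else "FP"] += 1
    per_cat = {}
    total_correct = 0
    total_n = 0
    for cat, c in counts.items():
        if c["N"]:
            per_cat[cat] = (c["TP"] + c["TN"]) / c["N"]
            total_correct += c["TP"] + c["TN"]
            total_n += c["N"]
    overall = total_correct / total_n if total_n else float("nan")
    return EvaluationReport(overall=overall, per_category=per_cat, counts=counts)


def write_predictions(predictions: dict[str, str], path: str | Path) -> None:
    """One JSON object per line: {"question_id": ..., "answer": ...}."""
    with open(path, "w") as fh:
        for qid in sorted(predictions):
            fh.write(json.dumps({"question_id": qid,
                                 "answer": predictions[qid]}) + "\n")


def read_predictions(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out[str(rec["question_id"])] = str(rec["answer"])
    return out
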