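"""Dataset dialect round-trip, vocabulary, targets, splitting, merging,
and the category-wise accuracy metric."""

import numpy as np
import pytest

from cropvqa.dataset_io import (VQATriple, build_answer_vocab, evaluate,
                                merge_prior_knowledge, read_dataset,
                                soft_targets, split_dataset, write_dataset)
from cropvqa.errors import ConfigError, InputError


def make_triple(qid="q1", image_id="img1", question="is the fruit diseased?",
                answers=None, category="yes/no", boxes=None):
    if answers is None:
        answers = [("yes", "yes")] * 7 + [("no", "maybe")] * 3
    return VQATriple(image_id=image_id, question_id=qid, question=question,
                     answers=answers, question_category=category, boxes=boxes)


@pytest.fixture()
def fixture_triples():
    out = []
    for i in range(12):
        out.append(make_triple(
            qid=f"q{i}", image_id=f"img{i % 4}",
            question="what color is the spot?" if i % 2 else
            "is the fruit diseased?",
            answers=([("brown", "yes")] * 6 + [("purple", "maybe")] * 4)
            if i % 2 else None,
            category="other" if i % 2 else "yes/no"))
    return out


class TestTripleInvariants:
    def test_wrong_answer_count_rejected(self):
        with pytest.raises(InputError):
            make_triple(answers=[("yes", "yes")] * 9)

    def test_bad_confidence_and_category_rejected(self):
        with pytest.raises(InputError):
            make_triple(answers=[("yes", "sure")] * 10)
        with pytest.raises(InputError):
            make_triple(category="judgement")

    def test_ground_truths_are_normalized_yes_answers(self):
        t = make_triple(answers=[("Brown!", "yes")] * 5 + [("red", "maybe")] * 5)
        assert t.ground_truths() == ["brown"] * 5


class TestReadWrite:
    def test_round_trip_is_lossless(self, tmp_path, fixture_triples):
        qp, ap = tmp_path / "q.json", tmp_path / "a.json"
        write_dataset(fixture_triples, qp, ap)
        back = read_dataset(qp, ap)
        assert len(back) == len(fixture_triples)
        for a, b in zip(fixture_triples, back):
            assert a == b

    def test_nine_answer_record_rejected_with_reason(self, tmp_path, caplog):
        import json
        t = make_triple()
        write_dataset([t], tmp_path / "q.json", tmp_path / "a.json")
        data = json.loads((tmp_path / "a.json").read_text())
        data["annotations"][0]["answers"] = data["annotations"][0]["answers"][:9]
        (tmp_path / "a.json").write_text(json.dumps(data))
        with caplog.at_level("WARNING"):
            back = read_dataset(tmp_path / "q.json", tmp_path / "a.json")
        assert back == []
        assert "rejected" in caplog.text

    def test_dangling_question_id_is_an_error(self, tmp_path):
        write_dataset([make_triple(qid="q1")], tmp_path / "q.json",
                      tmp_path / "a.json")
        write_dataset([make_triple(qid="q2")], tmp_path / "q2.json",
                      tmp_path / "a2.json")
        with pytest.raises(InputError):
            read_dataset(tmp_path / "q.json", tmp_path / "a2.json")

    def test_region_boxes_survive_round_trip(self, tmp_path):
        t = make_triple(boxes=[(1.0, 2.0, 10.0, 12.0)])
        write_dataset([t], tmp_path / "q.json", tmp_path / "a.json")
        back = read_dataset(tmp_path / "q.json", tmp_path / "a.json")
        assert back[0].boxes == [(1.0, 2.0, 10.0, 12.0)]


class TestAnswerVocab:
    def test_min_freq_one_keeps_all_distinct_answers(self, fixture_triples):
        vocab = build_answer_vocab(fixture_triples, min_freq=1)
        assert {"yes", "no", "brown", "purple"} <= set(vocab.tokens)

    def test_counts_match_brute_force_tally(self, fixture_triples):
        from collections import Counter
        tally = Counter()
        for t in fixture_triples:
            for a, _ in t.answers:
                tally[a.lower()] += 1
        vocab = build_answer_vocab(fixture_triples,
                                   min_freq=max(tally.values()))
        expected = {a for a, n in tally.items() if n == max(tally.values())}
        assert set(vocab.tokens) - {"<pad>", "<unk>"} == expected

    def test_ordering_deterministic_across_runs(self, fixture_triples):
        v1 = build_answer_vocab(fixture_triples)
        v2 = build_answer_vocab(list(reversed(fixture_triples)))
        assert v1.tokens == v2.tokens

    def test_empty_vocab_after_filtering_rejected(self, fixture_triples):
        with pytest.raises(ConfigError):
            build_answer_vocab(fixture_triples, min_freq=10 ** 6)


class TestSoftTargets:
    def test_unanimous_yes_gives_single_one(self):
        t = make_triple(answers=[("brown", "yes")] * 10)
        vocab = build_answer_vocab([t])
        target = soft_targets(t, vocab)
        assert target[vocab.id("brown")] == 1.0
        assert target.sum() == 1.0

    def test_max_over_confidences_for_same_answer(self):
        t = make_triple(answers=[("brown", "maybe")] * 5 + [("brown", "yes")] * 5)
        vocab = build_answer_vocab([t])
        assert soft_targets(t, vocab)[vocab.id("brown")] == 1.0

    def test_mixed_answers_match_hand_built_vector(self):
        t = make_triple(answers=[("brown", "yes")] * 4 + [("purple", "maybe")] * 3
                        + [("blue", "maybe")] * 3)
        vocab = build_answer_vocab([t])
        target = soft_targets(t, vocab)
        assert target[vocab.id("brown")] == 1.0
        assert target[vocab.id("purple")] == 0.5
        assert target[vocab.id("blue")] == 0.5

    def test_no_in_vocab_answer_rejected(self):
        t1 = make_triple(answers=[("brown", "yes")] * 10)
        t2 = make_triple(answers=[("chartreuse", "yes")] * 10)
        vocab = build_answer_vocab([t1])
        with pytest.raises(InputError):
            soft_targets(t2, vocab)


class TestSplit:
    def test_ten_images_split_8_1_1(self):
        triples = [make_triple(qid=f"q{i}", image_id=f"img{i}")
                   for i in range(10)]
        train, val, test = split_dataset(triples, seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_no_image_straddles_splits(self, fixture_triples):
        train, val, test = split_dataset(fixture_triples, seed=1)
        sets = [{t.image_id for t in s} for s in (train, val, test)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert len(train) + len(val) + len(test) == len(fixture_triples)

    def test_97_images_within_one_of_exact_ratio(self):
        triples = [make_triple(qid=f"q{i}", image_id=f"img{i}")
                   for i in range(97)]
        train, val, test = split_dataset(triples, seed=2)
        assert abs(len(train) - 97 * 0.8) <= 1
        assert abs(len(val) - 9.7) <= 1
        assert abs(len(test) - 9.7) <= 1

    def test_fewer_images_than_splits_rejected(self):
        with pytest.raises(InputError):
            split_dataset([make_triple()], seed=0)


class TestMergePriorKnowledge:
    def test_counts_additive_and_sources_tagged(self, fixture_triples):
        pk = [make_triple(qid=f"pk{i}", image_id=f"pkimg{i}",
                          boxes=[(0, 0, 5, 5)]) for i in range(3)]
        merged = merge_prior_knowledge(fixture_triples, pk)
        assert len(merged) == len(fixture_triples) + 3
        assert sum(1 for t in merged if t.source == "prior") == 3

    def test_pk_without_boxes_rejected(self, fixture_triples):
        with pytest.raises(InputError):
            merge_prior_knowledge(fixture_triples, [make_triple(qid="pk0")])

    def test_duplicate_question_id_rejected(self, fixture_triples):
        pk = [make_triple(qid="q1", boxes=[(0, 0, 5, 5)])]
        with pytest.raises(InputError):
            merge_prior_knowledge(fixture_triples, pk)


class TestEvaluate:
    def test_all_correct_gives_perfect_report(self, fixture_triples):
        preds = {t.question_id: t.ground_truths()[0] for t in fixture_triples}
        report = evaluate(preds, fixture_triples)
        assert report.overall == 1.0
        assert all(v == 1.0 for v in report.per_category.values())

    def test_three_of_four_gives_75_percent(self):
        triples = [make_triple(qid=f"q{i}", image_id=f"i{i}") for i in range(4)]
        preds = {"q0": "yes", "q1": "yes", "q2": "yes", "q3": "no"}
        report = evaluate(preds, triples)
        assert report.overall == 0.75
        c = report.counts["yes/no"]
        assert (c["TP"], c["FN"], c["N"]) == (3, 1, 4)

    def test_category_accuracies_recombine_to_overall(self, fixture_triples):
        rng = np.random.default_rng(0)
        preds = {}
        for t in fixture_triples:
            preds[t.question_id] = (t.ground_truths()[0]
                                    if rng.random() < 0.5 else "wrong")
        report = evaluate(preds, fixture_triples)
        total = sum(c["N"] for c in report.counts.values())
        weighted = sum(report.per_category[cat] * report.counts[cat]["N"]
                       for cat in report.per_category)
        assert np.isclose(report.overall, weighted / total)
        # brute-force recount
        n_correct = sum(preds[t.question_id] in t.ground_truths()
                        for t in fixture_triples)
        assert np.isclose(report.overall, n_correct / len(fixture_triples))

    def test_prediction_normalization_and_order_invariance(self, fixture_triples):
        preds = {t.question_id: t.ground_truths()[0].upper() + "!"
                 for t in fixture_triples}
        report = evaluate(preds, fixture_triples)
        assert report.overall == 1.0

    def test_unknown_question_id_rejected(self, fixture_triples):
        preds = {t.question_id: "yes" for t in fixture_triples}
        preds["ghost"] = "yes"
        with pytest.raises(InputError):
            evaluate(preds, fixture_triples)

    def test_csv_export_contains_all_categories(self, fixture_triples):
        preds = {t.question_id: t.ground_truths()[0] for t in fixture_triples}
        csv = evaluate(preds, fixture_triples).to_csv()
        for cat in ("yes/no", "number", "other", "overall"):
            assert cat in csv


class TestPredictionsJSONL:
    def test_round_trip(self, tmp_path, fixture_triples):
        from cropvqa.dataset_io import read_predictions, write_predictions
        preds = {t.question_id: t.ground_truths()[0] for t in fixture_triples}
        path = tmp_path / "preds.jsonl"
        write_predictions(preds, path)
        assert read_predictions(path) == preds
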