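import itertools

import numpy as np
import pytest

from promptner.corpus import AnnotatedDocument, EntityMention, EntityType
from promptner.error_taxonomy import (
    AlignmentRecord,
    Category,
    align_document,
    classify_alignment,
    greedy_align,
    spurious_crosscheck,
    taxonomy_distribution,
    token_overlap,
)
from promptner.evaluation import parse_model_output


class TestTokenOverlap:
    def test_identity_counts_distinct_tokens(self):
        assert token_overlap("muscle weakness", "muscle weakness") == 2
        assert token_overlap("pain pain pain", "pain pain") == 1

    def test_subset(self):
        assert token_overlap("muscle weakness", "weakness") == 1

    def test_hand_token_sets(self):
        a = "sudden drastic drop in blood pressure"
        b = "sudden drop in blood pressure"
        assert token_overlap(a, b) == 5

    def test_symmetric_and_case_insensitive(self):
        assert token_overlap("Fever, chills", "chills") == token_overlap(
            "chills", "Fever, chills"
        ) == 1


class TestClassifyAlignment:
    S = EntityType.SIGN

    def test_correct(self):
        assert classify_alignment(
            "orthostatic hypotension", "orthostatic hypotension", self.S, self.S, 2
        ) is Category.CORRECT

    def test_boundary(self):
        assert classify_alignment(
            "sudden drop in blood pressure",
            "sudden drastic drop in blood pressure", self.S, self.S, 5,
        ) is Category.BOUNDARY

    def test_type(self):
        assert classify_alignment(
            "fatigue", "fatigue", self.S, EntityType.SYMPTOM, 1
        ) is Category.TYPE

    def test_boundary_type(self):
        assert classify_alignment(
            "severe fatigue", "fatigue", self.S, EntityType.SYMPTOM, 1
        ) is Category.BOUNDARY_TYPE

    def test_unmatched_sides(self):
        assert classify_alignment("x", None, None, self.S, 0) is Category.SPURIOUS
        assert classify_alignment(None, "x", self.S, self.S, 0) is Category.MISSED

    def test_self_alignment_is_always_correct(self):
        for s in ["a", "multi token string", "x-linked disorder"]:
            assert classify_alignment(s, s, self.S, self.S, token_overlap(s, s)) \
                is Category.CORRECT


class TestGreedyAlign:
    def test_single_exact_pair(self):
        recs = greedy_align(["fever"], [("fever", EntityType.SIGN)], EntityType.SIGN)
        assert len(recs) == 1
        assert recs[0].category is Category.CORRECT
        assert recs[0].overlap == 1

    def test_two_predictions_one_gold(self):
        recs = greedy_align(
            ["fever rash", "fever chills"],
            [("fever rash", EntityType.SIGN)],
            EntityType.SIGN,
        )
        assert recs[0].category is Category.CORRECT
        assert recs[1].category is Category.SPURIOUS

    def test_cross_type_gold_yields_type_category(self):
        recs = greedy_align(
            ["fatigue"], [("fatigue", EntityType.SIGN)], EntityType.SYMPTOM
        )
        assert recs[0].category is Category.TYPE
        # the consumed sign gold is not a symptom miss
        assert all(r.category is not Category.MISSED for r in recs)

    def test_leftover_task_type_gold_is_missed_other_types_are_not(self):
        recs = greedy_align(
            [],
            [("fever", EntityType.SIGN), ("pain", EntityType.SYMPTOM)],
            EntityType.SIGN,
        )
        assert [r.category for r in recs] == [Category.MISSED]
        assert recs[0].gold == "fever"

    def test_ties_go_to_annotation_order(self):
        recs = greedy_align(
            ["fever"],
            [("fever chills", EntityType.SIGN), ("fever rash", EntityType.SIGN)],
            EntityType.SIGN,
        )
        assert recs[0].gold == "fever chills"

    def _oracle(self, preds, golds, task):
        """Independent re-implementation of the greedy matching rule."""
        available = list(range(len(golds)))
        matched = []
        spurious = []
        for p in preds:
            overlaps = [(token_overlap(p, golds[g][0]), -g) for g in available]
            if not overlaps or max(overlaps)[0] == 0:
                spurious.append(p)
                continue
            best = max(overlaps)
            gi = -best[1]
            available.remove(gi)
            matched.append((p, gi))
        missed = [g for g in available if golds[g][1] == task]
        return matched, spurious, missed

    def test_matches_independent_oracle_on_random_small_instances(self, rng):
        vocab = ["fever", "rash", "chills", "pain", "drop", "blood"]
        task = EntityType.SIGN
        for trial in range(200):
            n_p = int(rng.integers(0, 6))
            n_g = int(rng.integers(0, 6))
            preds = [
                " ".join(rng.choice(vocab, size=rng.integers(1, 4), replace=False))
                for _ in range(n_p)
            ]
            golds = [
                (
                    " ".join(rng.choice(vocab, size=rng.integers(1, 4), replace=False)),
                    EntityType.SIGN if rng.random() < 0.7 else EntityType.SYMPTOM,
                )
                for _ in range(n_g)
            ]
            recs = greedy_align(preds, golds, task)
            matched, spurious, missed = self._oracle(preds, golds, task)
            got_matched = [(r.prediction, r.gold) for r in recs
                           if r.prediction and r.gold]
            assert len(got_matched) == len(matched)
            assert [(p, golds[g][0]) for p, g in matched] == got_matched
            assert [r.prediction for r in recs
                    if r.category is Category.SPURIOUS] == spurious
            assert len([r for r in recs if r.category is Category.MISSED]) == len(missed)

    def test_partition_invariants(self, rng):
        """matched + spurious = #preds; matched task-type golds + missed = #task golds."""
        vocab = ["a", "b", "c", "d", "e"]
        for trial in range(100):
            preds = [" ".join(rng.choice(vocab, size=2, replace=False))
                     for _ in range(int(rng.integers(0, 5)))]
            golds = [(" ".join(rng.choice(vocab, size=2, replace=False)),
                      EntityType.SIGN) for _ in range(int(rng.integers(0, 5)))]
            recs = greedy_align(preds, golds, EntityType.SIGN)
            n_matched = sum(1 for r in recs if r.prediction and r.gold)
            n_spurious = sum(1 for r in recs if r.category is Category.SPURIOUS)
            n_missed = sum(1 for r in recs if r.category is Category.MISSED)
            assert n_matched + n_spurious == len(preds)
            assert n_matched + n_missed == len(golds)
            for r in recs:
                assert sum(c is r.category for c in Category) == 1


class TestTaxonomyDistribution:
    def test_known_composition(self):
        recs = (
            [AlignmentRecord("d", EntityType.SIGN, "x", "x", EntityType.SIGN, 1,
                             Category.CORRECT)] * 5
            + [AlignmentRecord("d", EntityType.SIGN, "x y", "x", EntityType.SIGN, 1,
                               Category.BOUNDARY)] * 2
            + [AlignmentRecord("d", EntityType.SIGN, "x", "x", EntityType.SYMPTOM, 1,
                               Category.TYPE)]
            + [AlignmentRecord("d", EntityType.SIGN, "z", None, None, 0,
                               Category.SPURIOUS)]
            + [AlignmentRecord("d", EntityType.SIGN, None, "w", EntityType.SIGN, 0,
                               Category.MISSED)]
        )
        dist = taxonomy_distribution(recs)
        assert dist.denominator == 10
        assert dist.proportions[Category.CORRECT] == 0.5
        assert dist.proportions[Category.BOUNDARY] == 0.2
        assert dist.proportions[Category.TYPE] == 0.1
        assert dist.proportions[Category.SPURIOUS] == 0.1
        assert dist.proportions[Category.MISSED] == 0.1
        assert sum(dist.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            taxonomy_distribution([])


class TestSpuriousCrosscheck:
    def _spurious(self, doc_id, s):
        return AlignmentRecord(doc_id, EntityType.SYMPTOM, s, None, None, 0,
                               Category.SPURIOUS)

    def test_printed_counts_arithmetic(self):
        recs = [self._spurious("d", f"match {i}") for i in range(101)]
        recs += [self._spurious("d", f"nomatch {i}") for i in range(81)]
        signs = {"d": [f"match {i}" for i in range(101)]}
        num, den, pct = spurious_crosscheck(recs, signs)
        assert (num, den, pct) == (101, 182, 55.5)

    def test_zero_spurious_flagged_undefined(self):
        assert spurious_crosscheck([], {}) == (0, 0, None)

    def test_all_copies_give_hundred_percent(self):
        recs = [self._spurious("d1", "elevated rash"), self._spurious("d2", "mild pallor")]
        signs = {"d1": ["Elevated rash"], "d2": ["mild pallor"]}
        assert spurious_crosscheck(recs, signs)[2] == 100.0

    def test_same_document_scoping(self):
        recs = [self._spurious("d1", "elevated rash")]
        signs = {"d2": ["elevated rash"]}  # match exists only in another document
        assert spurious_crosscheck(recs, signs) == (0, 1, 0.0)


class TestAlignDocument:
    def test_cross_type_toggle(self):
        doc = AnnotatedDocument(
            doc_id="d", text="elevated rash seen",
            mentions=[EntityMention("elevated rash", EntityType.SIGN, 0, 13)],
        )
        pred = parse_model_output("elevated rash", "d", EntityType.SYMPTOM)
        with_pool = align_document(pred, doc, cross_type=True)
        assert with_pool[0].category is Category.TYPE
        task_only = align_document(pred, doc, cross_type=False)
        assert task_only[0].category is Category.SPURIOUS
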