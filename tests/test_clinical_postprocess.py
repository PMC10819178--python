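"""Mechanism inference and critical-interaction-avoiding substitution."""

import numpy as np
import pytest

from _stubs import StubFeatures, StubModel
from ddiscreen import (InteractionRecord, Registry, find_alternatives,
                       find_mechanism_candidates, flagged_critical_pairs,
                       suggest_substitutions)
from ddiscreen.clinical_postprocess import _max_critical_activation
from ddiscreen.config import CRITICAL_TYPES
from ddiscreen.corpus import DrugRecord
from ddiscreen.interaction_predictor import PredictionSet


def _pset(records, threshold=0.5):
    pset = PredictionSet(threshold=threshold)
    for subject, obj, type_id, score in records:
        pset.add(InteractionRecord(subject, obj, type_id,
                                   provenance="predicted", score=score))
    return pset


class TestMechanismCandidates:
    PAIRS = [frozenset({"Z", "O"}), frozenset({"A", "B"}), frozenset({"C", "D"})]

    def test_adverse_pair_with_co_predicted_type(self):
        # mirrors a hypnotic/antiemetic pattern: gold adverse-effect
        # record plus a co-predicted metabolism type
        gold = [InteractionRecord("O", "Z", 26)]
        preds = _pset([("O", "Z", 26, 0.97), ("Z", "O", 6, 0.95)])
        out = find_mechanism_candidates(self.PAIRS, gold, preds)
        assert len(out) == 1
        assert out[0].pair == frozenset({"Z", "O"})
        assert [m.type_id for m in out[0].mechanisms] == [6]

    def test_adverse_only_prediction_excluded(self):
        gold = [InteractionRecord("O", "Z", 26)]
        preds = _pset([("O", "Z", 26, 0.97)])
        assert find_mechanism_candidates(self.PAIRS, gold, preds) == []

    def test_non_adverse_gold_excluded(self):
        gold = [InteractionRecord("O", "Z", 15)]
        preds = _pset([("O", "Z", 26, 0.97), ("Z", "O", 6, 0.95)])
        assert find_mechanism_candidates(self.PAIRS, gold, preds) == []

    def test_pair_outside_cohort_excluded(self):
        gold = [InteractionRecord("X", "Y", 26)]
        preds = _pset([("X", "Y", 26, 0.97), ("Y", "X", 6, 0.95)])
        assert find_mechanism_candidates(self.PAIRS, gold, preds) == []

    def test_mechanisms_sorted_by_descending_score(self):
        gold = [InteractionRecord("A", "B", 26)]
        preds = _pset([("A", "B", 26, 0.97), ("B", "A", 6, 0.95),
                       ("A", "B", 15, 0.96)])
        out = find_mechanism_candidates(self.PAIRS, gold, preds)
        assert [m.type_id for m in out[0].mechanisms] == [15, 6]

    def test_equals_brute_force_three_condition_filter(self):
        rng = np.random.default_rng(4)
        ids = [f"D{i}" for i in range(12)]
        pairs = [frozenset({a, b}) for i, a in enumerate(ids)
                 for b in ids[i + 1:]]
        cohort = [p for p in pairs if rng.random() < 0.5]
        gold = [InteractionRecord(*sorted(p), int(rng.choice([6, 15, 26])))
                for p in pairs if rng.random() < 0.5]
        pred_rows = []
        for p in pairs:
            for t in (6, 15, 26):
                if rng.random() < 0.3:
                    pred_rows.append((*sorted(p), t, round(0.9 + 0.1 * rng.random(), 3)))
        preds = _pset(pred_rows)
        got = {c.pair for c in find_mechanism_candidates(cohort, gold, preds)}
        brute = set()
        for p in cohort:
            has_gold26 = any(g.unordered == p and g.type_id == 26 for g in gold)
            ptypes = {r.type_id for r in preds.records if r.unordered == p}
            if has_gold26 and 26 in ptypes and ptypes - {26}:
                brute.add(p)
        assert got == brute


def _toy_registry():
    t1i = frozenset({("T1", "inhibitor")})
    return Registry([
        DrugRecord("A", "A", "CCO", True, t1i),
        DrugRecord("B", "B", "CCO", True, t1i),
        DrugRecord("C", "C", "CCO", True, frozenset({("T1", "agonist")})),
        DrugRecord("D", "D", "CCO", False, t1i),          # not approved
        DrugRecord("E", "E", "CCO", True,
                   frozenset({("T1", "inhibitor"), ("T2", "agonist")})),
    ])


class TestFindAlternatives:
    def test_exact_target_action_match(self):
        reg = _toy_registry()
        assert [d.drug_id for d in find_alternatives(reg["A"], reg)] == ["B"]

    def test_input_drug_excluded_from_own_alternatives(self):
        reg = _toy_registry()
        assert "A" not in [d.drug_id for d in find_alternatives(reg["A"], reg)]

    def test_no_shared_set_gives_empty_list(self):
        reg = _toy_registry()
        assert find_alternatives(reg["C"], reg) == []

    def test_empty_target_set_gives_empty_list(self):
        reg = Registry([DrugRecord("X", "X", "CCO", True, frozenset()),
                        DrugRecord("Y", "Y", "CCO", True, frozenset())])
        assert find_alternatives(reg["X"], reg) == []

    def test_superset_match_relaxation(self):
        reg = _toy_registry()
        relaxed = [d.drug_id for d in find_alternatives(reg["A"], reg,
                                                        superset_match=True)]
        assert relaxed == ["B", "E"]


class TestSuggestSubstitutions:
    """Toy universe: pair (A, X) flagged critical; B shares A's targets."""

    def _setup(self, crit_score_b):
        reg = Registry([
            DrugRecord("A", "A", "CCO", True, frozenset({("T1", "inhibitor")})),
            DrugRecord("B", "B", "CCO", True, frozenset({("T1", "inhibitor")})),
            DrugRecord("X", "X", "CCO", True, frozenset({("T9", "agonist")})),
        ])
        feats = StubFeatures(["A", "B", "X"])
        table = {(0, 2): {20: 0.96},                   # A->X critical fires
                 (1, 2): {20: crit_score_b},           # B->X candidate pair
                 (2, 1): {6: 0.2}}
        return reg, StubModel(table), feats

    def test_alternative_with_high_critical_activation_rejected(self):
        reg, model, feats = self._setup(0.50)
        out = suggest_substitutions(("A", "X"), [20], reg, model, feats)
        assert out == []

    def test_alternative_with_low_activations_accepted(self):
        reg, model, feats = self._setup(0.10)
        out = suggest_substitutions(("A", "X"), [20], reg, model, feats)
        assert [(s.replaced, s.alternative) for s in out] == [("A", "B")]
        assert out[0].max_critical_activation < 0.47

    def test_gold_critical_record_vetoes(self):
        reg, model, feats = self._setup(0.10)
        gold = [InteractionRecord("B", "X", 20)]
        assert suggest_substitutions(("A", "X"), [20], reg, model, feats,
                                     gold=gold) == []

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(5)
        ids = ["A", "B", "C", "X", "Y"]
        t1i = frozenset({("T1", "inhibitor")})
        reg = Registry([
            DrugRecord("A", "A", "CCO", True, t1i),
            DrugRecord("B", "B", "CCO", True, t1i),
            DrugRecord("C", "C", "CCO", True, t1i),
            DrugRecord("X", "X", "CCO", True, frozenset({("T2", "agonist")})),
            DrugRecord("Y", "Y", "CCO", True, frozenset({("T2", "agonist")})),
        ])
        feats = StubFeatures(ids)
        table = {}
        for i in range(5):
            for j in range(5):
                if i != j and rng.random() < 0.6:
                    table[(i, j)] = {int(rng.choice([20, 27, 6])):
                                     float(np.round(rng.random(), 3))}
        model = StubModel(table)
        pair = ("A", "X")
        got = {(s.replaced, s.alternative)
               for s in suggest_substitutions(pair, [20], reg, model, feats)}
        brute = set()
        for replaced, kept in (("A", "X"), ("X", "A")):
            for alt in reg:
                if (alt.drug_id in pair or not alt.approved
                        or alt.targets != reg[replaced].targets):
                    continue
                mca = _max_critical_activation(alt.drug_id, kept, model, feats,
                                               CRITICAL_TYPES)
                if mca < 0.47:
                    brute.add((replaced, alt.drug_id))
        assert got == brute

    def test_preventability_monotone_in_alternatives(self):
        # removing an alternative never creates new suggestions
        reg, model, feats = self._setup(0.10)
        full = suggest_substitutions(("A", "X"), [20], reg, model, feats)
        smaller_reg = Registry([reg["A"], reg["X"]])
        fewer = suggest_substitutions(("A", "X"), [20], smaller_reg, model, feats)
        assert {(s.replaced, s.alternative) for s in fewer} <= \
               {(s.replaced, s.alternative) for s in full}
        assert full and not fewer


class TestFlaggedPairs:
    def test_only_critical_types_flag_pairs(self):
        preds = _pset([("A", "B", 20, 0.95), ("B", "C", 6, 0.95),
                       ("A", "C", 27, 0.96), ("A", "C", 29, 0.95)])
        flagged = flagged_critical_pairs(preds)
        assert flagged == {frozenset({"A", "B"}): [20],
                           frozenset({"A", "C"}): [27, 29]}

    def test_cohort_restriction(self):
        preds = _pset([("A", "B", 20, 0.95), ("C", "D", 27, 0.95)])
        flagged = flagged_critical_pairs(preds, [frozenset({"A", "B"})])
        assert set(flagged) == {frozenset({"A", "B"})}
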