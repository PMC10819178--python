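"""Decision-support post-processing of the prediction output:

* mechanism inference — for drug pairs whose gold-standard record is
  the unspecific adverse-effect type 26, co-predicted types of a
  different kind suggest a pharmacokinetic or pharmacodynamic
  explanation;
* substitution — for pairs flagged with a critical interaction type, an
  approved drug sharing the replaced drug's exact (target, action) set
  is accepted as an alternative iff the candidate pair's activations
  stay below the safety threshold for *every* critical type in *both*
  orderings (the sentences are directional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemfeat import FeaturePipeline
from .config import ADVERSE_EFFECT_TYPE, CRITICAL_TYPES, DEFAULT_THRESHOLD
from .corpus import DrugRecord, InteractionRecord, Registry
from .interaction_predictor import PredictionSet
from .neural_model import InteractionClassifier


@dataclass(frozen=True)
class MechanismCandidate:
    """A pair whose adverse-effect record may be explained by a
    co-predicted type."""

    pair: frozenset[str]
    gold_record: InteractionRecord
    mechanisms: tuple[InteractionRecord, ...]  # co-predicted, descending score


def find_mechanism_candidates(cohort_pairs: Iterable[frozenset[str]],
                              gold: Iterable[InteractionRecord],
                              predictions: PredictionSet,
                              adverse_type: int = ADVERSE_EFFECT_TYPE
                              ) -> list[MechanismCandidate]:
    """Pairs that are (1) taken together in the cohort, (2) recorded as
    the adverse-effect type in the gold standard and predicted as such,
    and (3) co-predicted with at least one other type."""
    cohort_pairs = set(cohort_pairs)
    gold_by_pair: dict[frozenset, InteractionRecord] = {}
    for g in gold:
        if g.type_id == adverse_type:
            gold_by_pair[g.unordered] = g
    pred_by_pair: dict[frozenset, list[InteractionRecord]] = {}
    for r in predictions.records:
        pred_by_pair.setdefault(r.unordered, []).append(r)

    out = []
    for pair in sorted(cohort_pairs & set(gold_by_pair), key=sorted):
        preds = pred_by_pair.get(pair, [])
        if not any(r.type_id == adverse_type for r in preds):
            continue
        others = sorted((r for r in preds if r.type_id != adverse_type),
                        key=lambda r: (-r.score, r.type_id))
        if not others:
            continue
        out.append(MechanismCandidate(pair, gold_by_pair[pair], tuple(others)))
    return out


def find_alternatives(drug: DrugRecord, registry: Registry,
                      superset_match: bool = False) -> list[DrugRecord]:
    """Approved drugs (other than the input) whose (target, action) set
    equals the input drug's set; ordered by drug id.

    ``superset_match`` relaxes equality to "candidate's set contains
    the input's set".  An empty target set yields no alternatives.
    """
    if not drug.targets:
        return []
    out = []
    for cand in registry:
        if cand.drug_id == drug.drug_id or not cand.approved:
            continue
        match = (drug.targets <= cand.targets if superset_match
                 else cand.targets == drug.targets)
        if match:
            out.append(cand)
    return sorted(out, key=lambda r: r.drug_id)


@dataclass(frozen=True)
class SubstitutionSuggestion:
    original_pair: tuple[str, str]
    flagged_types: tuple[int, ...]
    replaced: str
    alternative: str
    max_critical_activation: float  # over both orderings of the new pair


def _max_critical_activation(a: str, b: str, model: InteractionClassifier,
                             features: FeaturePipeline,
                             critical_types: frozenset[int]) -> float:
    idx = np.array(sorted(critical_types)) - 1
    acts_ab = model.predict_activations(features.pair_vector(a, b)[None, :])[0]
    acts_ba = model.predict_activations(features.pair_vector(b, a)[None, :])[0]
    return float(max(acts_ab[idx].max(), acts_ba[idx].max()))


def suggest_substitutions(pair: tuple[str, str], flagged_types: Sequence[int],
                          registry: Registry, model: InteractionClassifier,
                          features: FeaturePipeline,
                          gold: Iterable[InteractionRecord] = (),
                          safety_threshold: float = DEFAULT_THRESHOLD,
                          critical_types: frozenset[int] = CRITICAL_TYPES,
                          superset_match: bool = False
                          ) -> list[SubstitutionSuggestion]:
    """All safe replacements of either drug of a critical pair.

    For each drug of the pair and each of its alternatives, the new
    pair is evaluated in both orderings; the suggestion is accepted iff
    every critical-type activation stays below the safety threshold and
    the gold standard holds no critical record for the new pair
    (conservative veto).  The pair is *preventable* iff at least one
    suggestion exists.
    """
    gold_critical: set[frozenset] = {
        g.unordered for g in gold if g.type_id in critical_types}
    suggestions = []
    for replaced, kept in (pair, pair[::-1]):
        if replaced not in registry:
            continue
        for alt in find_alternatives(registry[replaced], registry,
                                     superset_match=superset_match):
            if alt.drug_id in pair or not alt.has_structure:
                continue
            if frozenset((alt.drug_id, kept)) in gold_critical:
                continue
            mca = _max_critical_activation(alt.drug_id, kept, model, features,
                                           critical_types)
            if mca < safety_threshold:
                suggestions.append(SubstitutionSuggestion(
                    original_pair=pair, flagged_types=tuple(sorted(flagged_types)),
                    replaced=replaced, alternative=alt.drug_id,
                    max_critical_activation=mca))
    return suggestions


def flagged_critical_pairs(predictions: PredictionSet,
                           cohort_pairs: Iterable[frozenset[str]] | None = None,
                           critical_types: frozenset[int] = CRITICAL_TYPES
                           ) -> dict[frozenset[str], list[int]]:
    """Unordered pairs with >= 1 predicted critical type, optionally
    restricted to pairs co-used in the cohort."""
    restrict = set(cohort_pairs) if cohort_pairs is not None else None
    out: dict[frozenset, list[int]] = {}
    for r in predictions.records:
        if r.type_id not in critical_types:
            continue
        if restrict is not None and r.unordered not in restrict:
            continue
        out.setdefault(r.unordered, []).append(r.type_id)
    return {k: sorted(set(v)) for k, v in out.items()}


def export_mechanism_report(candidates: Sequence[MechanismCandidate],
                            templates, name_of, path) -> None:
    from .interaction_predictor import render_sentence
    rows = []
    for c in candidates:
        rows.append({
            "pair": "|".join(sorted(c.pair)),
            "gold_sentence": render_sentence(c.gold_record, templates, name_of),
            "mechanism_sentences": " ; ".join(
                render_sentence(m, templates, name_of) for m in c.mechanisms),
            "mechanism_scores": ";".join(f"{m.score:.4f}" for m in c.mechanisms),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_substitution_report(suggestions: Sequence[SubstitutionSuggestion],
                               path) -> None:
    rows = [{
        "pair": "|".join(s.original_pair),
        "flagged_types": ";".join(map(str, s.flagged_types)),
        "replaced": s.replaced, "alternative": s.alternative,
        "max_critical_activation": s.max_critical_activation,
    } for s in suggestions]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
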