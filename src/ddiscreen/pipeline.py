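"""End-to-end orchestration of the screening study on one scenario:

registry -> features -> trained classifier -> pair predictions ->
cohort screening -> mechanism / substitution / food-network reports.

The full-scale architecture (nine hidden layers of 2048 units) is kept
for parameter accounting; studies run here use the same depth at
reduced width (:meth:`ModelConfig.desk`), which trains in well under a
minute on one CPU at the shipped scenario size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemfeat import FeaturePipeline, canonicalize_structure, fingerprint
from .config import DEFAULT_THRESHOLD, SCREEN_THRESHOLD
from .corpus import InteractionRecord, split_dataset
from .clinical_postprocess import (MechanismCandidate, SubstitutionSuggestion,
                                   find_mechanism_candidates,
                                   flagged_critical_pairs, suggest_substitutions)
from .cohort_screen import CohortReport, enumerate_plan_pairs, screen_cohort
from .dfi_network import build_network, filter_concentration_dfis
from .interaction_predictor import (DfiValidator, PredictionSet,
                                    filter_validated_dfis, predict_all_pairs,
                                    predict_drug_food_pairs)
from .neural_model import (InteractionClassifier, ModelConfig, TrainingHistory,
                           categorical_accuracy, threshold_types, train_model)
from .synthetic_data import ScenarioConfig, ScenarioData, generate_scenario


@dataclass
class StudyResult:
    scenario: ScenarioData
    features: FeaturePipeline
    model: InteractionClassifier
    history: TrainingHistory
    test_accuracy: float
    gold_recovery: float
    ddi_predictions: PredictionSet
    cohort_report: CohortReport
    mechanism_candidates: list[MechanismCandidate]
    flagged_pairs: dict[frozenset, list[int]]
    substitutions: dict[tuple[str, str], list[SubstitutionSuggestion]]
    dfi_predictions: PredictionSet
    validated_dfis: list[InteractionRecord]
    concentration_dfis: list[InteractionRecord]
    dfi_network: "object"
    food_ids: set[str] = field(default_factory=set)


def _pair_features(features: FeaturePipeline,
                   records: list[InteractionRecord]) -> np.ndarray:
    return features.pair_matrix([(r.subject_id, r.object_id) for r in records])


def gold_recovery_rate(gold: list[InteractionRecord],
                       model: InteractionClassifier,
                       features: FeaturePipeline,
                       threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of gold records whose type fires at the threshold in at
    least one ordering of the pair (the "normal run" recovery check)."""
    pairs = [(g.subject_id, g.object_id) for g in gold]
    fwd = model.predict_activations(features.pair_matrix(pairs))
    rev = model.predict_activations(
        features.pair_matrix([(b, a) for a, b in pairs]))
    hits = 0
    for g, f_row, r_row in zip(gold, fwd, rev):
        fired = {t for t, _ in threshold_types(f_row, threshold)}
        fired |= {t for t, _ in threshold_types(r_row, threshold)}
        hits += g.type_id in fired
    return hits / len(gold) if gold else 0.0


def run_study(cfg: ScenarioConfig | None = None,
              model_cfg: ModelConfig | None = None,
              screen_threshold: float = SCREEN_THRESHOLD,
              safety_threshold: float = DEFAULT_THRESHOLD,
              split_seed: int = 0) -> StudyResult:
    """Run the whole study on a (generated) synthetic scenario."""
    scenario = generate_scenario(cfg)
    registry = scenario.registry
    features = FeaturePipeline.fit(registry.smiles_by_id())

    train, val, test = split_dataset(scenario.gold, seed=split_seed)
    model_cfg = model_cfg or ModelConfig.desk()
    model, history = train_model(
        _pair_features(features, train), [r.type_id for r in train],
        _pair_features(features, val), [r.type_id for r in val],
        cfg=model_cfg)
    test_accuracy = categorical_accuracy(
        model, _pair_features(features, test), [r.type_id for r in test])
    recovery = gold_recovery_rate(scenario.gold, model, features,
                                  threshold=safety_threshold)

    drug_ids = [r.drug_id for r in registry.predictable()]
    ddi_predictions = predict_all_pairs(drug_ids, model, features,
                                        threshold=screen_threshold)
    cohort_report = screen_cohort(scenario.plans, scenario.gold,
                                  ddi_predictions, registry)

    cohort_pairs = {frozenset(p) for plan in scenario.plans
                    for p in enumerate_plan_pairs(plan, registry)}
    mechanisms = find_mechanism_candidates(cohort_pairs, scenario.gold,
                                           ddi_predictions)
    flagged = flagged_critical_pairs(ddi_predictions, cohort_pairs)
    substitutions = {}
    for pair_key, types in flagged.items():
        pair = tuple(sorted(pair_key))
        substitutions[pair] = suggest_substitutions(
            pair, types, registry, model, features, gold=scenario.gold,
            safety_threshold=safety_threshold)

    # drug-food branch
    food_fps = {}
    for comp in scenario.food_compounds:
        if comp.has_structure:
            _, mol = canonicalize_structure(comp.smiles)
            food_fps[comp.compound_id] = fingerprint(mol)
            features.add_compound(comp.compound_id, comp.smiles)
    food_ids = set(food_fps)
    dfi_predictions = predict_drug_food_pairs(
        sorted(food_ids), drug_ids, model, features, threshold=screen_threshold)
    approved_fps = {}
    for rec in registry.predictable():
        if rec.approved:
            _, mol = canonicalize_structure(rec.smiles)
            approved_fps[rec.drug_id] = fingerprint(mol)
    validator = DfiValidator(approved_fps, scenario.gold)
    validated = filter_validated_dfis(dfi_predictions, food_fps, validator)
    concentration = filter_concentration_dfis(validated, food_ids)
    drug_class = {r.drug_id: r.category for r in registry}
    network = build_network(concentration, scenario.food_contents, food_ids,
                            drug_class=drug_class)

    return StudyResult(
        scenario=scenario, features=features, model=model, history=history,
        test_accuracy=test_accuracy, gold_recovery=recovery,
        ddi_predictions=ddi_predictions, cohort_report=cohort_report,
        mechanism_candidates=mechanisms, flagged_pairs=flagged,
        substitutions=substitutions, dfi_predictions=dfi_predictions,
        validated_dfis=validated, concentration_dfis=concentration,
        dfi_network=network, food_ids=food_ids,
    )
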