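"""Producing typed interaction predictions and human-readable sentences.

Every unordered compound pair is evaluated in both orderings, since the
output sentences are directional (the subject is the causal agent).  A
type fired in one ordering is reported for that ordering; if both
orderings fire the same type, the higher-scoring one is kept so that
tallies count each (pair, type) once.  The full activation vectors are
retained for the downstream safety checks.

Predicted drug-food interactions additionally pass a structural
validation: the food compound must be Dice-similar (>= 0.75) to an
approved drug that itself appears in a gold-standard record of the same
type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .chemfeat import FeaturePipeline, Fingerprint, dice_similarity
from .config import DFI_DICE_MIN, SCREEN_THRESHOLD
from .corpus import InteractionRecord, TemplateTable
from .neural_model import InteractionClassifier, threshold_types


@dataclass
class PredictionSet:
    """Predicted records keyed by ordered pair, plus their activations."""

    threshold: float
    records: list[InteractionRecord] = field(default_factory=list)
    #: full activation vector per evaluated ordered pair
    activations: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_unordered_pairs: int = 0

    def add(self, record: InteractionRecord) -> None:
        if record.score < self.threshold:
            raise ValueError("record scored below the prediction threshold")
        self.records.append(record)

    def for_pair(self, a: str, b: str) -> list[InteractionRecord]:
        key = frozenset((a, b))
        return [r for r in self.records if r.unordered == key]

    def types_for_pair(self, a: str, b: str) -> set[int]:
        return {r.type_id for r in self.for_pair(a, b)}

    def pairs_with_predictions(self) -> set[frozenset[str]]:
        return {r.unordered for r in self.records}


def _iter_batches(items: Sequence, size: int):
    for start in range(0, len(items), size):
        yield items[start:start + size]


def _predict_ordered(ordered_pairs: Sequence[tuple[str, str]],
                     model: InteractionClassifier, features: FeaturePipeline,
                     batch_size: int = 4096) -> dict[tuple[str, str], np.ndarray]:
    acts: dict[tuple[str, str], np.ndarray] = {}
    for chunk in _iter_batches(list(ordered_pairs), batch_size):
        X = features.pair_matrix(chunk)
        P = model.predict_activations(X)
        for pair, row in zip(chunk, P):
            acts[pair] = row
    return acts


def _collect_records(unordered: Iterable[tuple[str, str]],
                     acts: Mapping[tuple[str, str], np.ndarray],
                     threshold: float) -> list[InteractionRecord]:
    records = []
    for a, b in unordered:
        best: dict[int, InteractionRecord] = {}
        for subject, obj in ((a, b), (b, a)):
            for type_id, score in threshold_types(acts[(subject, obj)], threshold):
                cur = best.get(type_id)
                if cur is None or score > cur.score:
                    best[type_id] = InteractionRecord(
                        subject, obj, type_id, provenance="predicted", score=score)
        records.extend(best[t] for t in sorted(best))
    return records


def predict_all_pairs(drug_ids: Sequence[str], model: InteractionClassifier,
                      features: FeaturePipeline,
                      threshold: float = SCREEN_THRESHOLD) -> PredictionSet:
    """Evaluate both orderings of every unordered pair of the given
    drugs and keep all types fired at the threshold."""
    ids = list(dict.fromkeys(drug_ids))
    if len(ids) < 2:
        raise ValueError("need at least two drugs")
    unordered = list(combinations(ids, 2))
    ordered = [p for a, b in unordered for p in ((a, b), (b, a))]
    acts = _predict_ordered(ordered, model, features)
    pset = PredictionSet(threshold=threshold,
                         n_unordered_pairs=len(unordered))
    pset.activations = acts
    pset.records = _collect_records(unordered, acts, threshold)
    return pset


def predict_drug_food_pairs(food_ids: Sequence[str], drug_ids: Sequence[str],
                            model: InteractionClassifier,
                            features: FeaturePipeline,
                            threshold: float = SCREEN_THRESHOLD) -> PredictionSet:
    """Same protocol for all (food compound, drug) pairs; the 86-type
    head is shared with drug-drug prediction."""
    unordered = [(f, d) for f in food_ids for d in drug_ids]
    ordered = [p for f, d in unordered for p in ((f, d), (d, f))]
    acts = _predict_ordered(ordered, model, features)
    pset = PredictionSet(threshold=threshold, n_unordered_pairs=len(unordered))
    pset.activations = acts
    pset.records = _collect_records(unordered, acts, threshold)
    return pset


def render_sentence(record: InteractionRecord, templates: TemplateTable,
                    name_of: Callable[[str], str] | Mapping[str, str] = str) -> str:
    """Fill the type's sentence template with the subject and object
    compound names."""
    if isinstance(name_of, Mapping):
        lookup = name_of.__getitem__
    else:
        lookup = name_of
    template = templates[record.type_id].template
    return template.format(subject=lookup(record.subject_id),
                           object=lookup(record.object_id))


def parse_sentence(sentence: str, templates: TemplateTable
                   ) -> tuple[int, str, str]:
    """Invert :func:`render_sentence`: recover (type_id, subject name,
    object name) from a rendered sentence."""
    for t in templates:
        pattern = re.escape(t.template)
        pattern = pattern.replace(r"\{subject\}", r"(?P<subject>.+?)")
        pattern = pattern.replace(r"\{object\}", r"(?P<object>.+?)")
        m = re.fullmatch(pattern, sentence)
        if m:
            return t.type_id, m.group("subject"), m.group("object")
    raise ValueError(f"sentence matches no template: {sentence!r}")


class DfiValidator:
    """Structural validation of predicted drug-food interactions.

    A candidate survives iff some approved drug is Dice-similar
    (>= ``dice_min``) to the food compound *and* that drug appears in a
    gold-standard record of the same type (in either role).
    """

    def __init__(self, approved_fps: Mapping[str, Fingerprint],
                 gold: Iterable[InteractionRecord],
                 dice_min: float = DFI_DICE_MIN):
        self.approved_fps = dict(approved_fps)
        self.dice_min = dice_min
        self._drugs_by_type: dict[int, set[str]] = {}
        for rec in gold:
            bucket = self._drugs_by_type.setdefault(rec.type_id, set())
            bucket.add(rec.subject_id)
            bucket.add(rec.object_id)

    def validate(self, food_fp: Fingerprint, type_id: int) -> bool:
        drugs = self._drugs_by_type.get(type_id, set())
        return any(
            dice_similarity(food_fp, self.approved_fps[d]) >= self.dice_min
            for d in drugs if d in self.approved_fps
        )


def validate_dfi(record: InteractionRecord, food_fp: Fingerprint,
                 approved_fps: Mapping[str, Fingerprint],
                 gold: Iterable[InteractionRecord],
                 dice_min: float = DFI_DICE_MIN) -> bool:
    """One-shot form of :class:`DfiValidator` for a single candidate."""
    return DfiValidator(approved_fps, gold, dice_min).validate(food_fp,
                                                               record.type_id)


def filter_validated_dfis(pset: PredictionSet, food_fps: Mapping[str, Fingerprint],
                          validator: DfiValidator) -> list[InteractionRecord]:
    """Keep only predicted drug-food records that pass validation."""
    out = []
    for rec in pset.records:
        food_id = rec.subject_id if rec.subject_id in food_fps else rec.object_id
        if food_id not in food_fps:
            continue
        if validator.validate(food_fps[food_id], rec.type_id):
            out.append(rec)
    return out


def classify_dfi_orientation(record: InteractionRecord,
                             food_ids: set[str]) -> str:
    """``compound_affects_drug`` when the food compound is the sentence
    subject of the fired ordering, else ``drug_modulates_compound``."""
    subj_food = record.subject_id in food_ids
    obj_food = record.object_id in food_ids
    if subj_food == obj_food:
        raise ValueError("record is not a drug-food pair")
    return "compound_affects_drug" if subj_food else "drug_modulates_compound"


def is_known(record: InteractionRecord,
             gold: Iterable[InteractionRecord]) -> bool:
    """A predicted record is known iff the gold standard holds the same
    unordered pair with the same type."""
    return any(g.type_id == record.type_id and g.unordered == record.unordered
               for g in gold)


def export_predictions(records: Sequence[InteractionRecord],
                       templates: TemplateTable, name_of, path) -> None:
    """TSV interchange format of the screening reports."""
    import pandas as pd
    rows = [{
        "subject": r.subject_id, "object": r.object_id, "type_id": r.type_id,
        "score": r.score, "provenance": r.provenance,
        "sentence": render_sentence(r, templates, name_of),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
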