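"""Medication-plan screening and cohort-level interaction statistics.

Pairs are counted "with repetitions" across patients: a drug pair used
by several patients contributes one combination per patient, while
within one plan each unordered pair counts once.  A pair firing two
interaction types contributes two interactions but one combination.
Drugs without parseable structures never enter pair enumeration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import InteractionRecord, MedicationPlan, Registry
from .interaction_predictor import PredictionSet


def enumerate_plan_pairs(plan: MedicationPlan,
                         registry: Registry) -> list[tuple[str, str]]:
    """All C(m, 2) unordered pairs of the plan's predictable drugs."""
    usable = sorted(d for d in plan.drug_ids
                    if d in registry and registry[d].has_structure)
    return list(combinations(usable, 2))


@dataclass
class CohortReport:
    """Cohort screening tallies, gold-based and prediction-based."""

    n_patients: int
    total_combinations: int
    per_patient: pd.DataFrame  # patient_id, n_medications, gold_ddis, predicted_ddis
    gold_total: int
    predicted_total: int
    gold_prevalence: float
    predicted_prevalence: float
    combinations_with_gold: int
    combinations_with_prediction: int
    type_frequency_gold: Counter = field(default_factory=Counter)
    type_frequency_predicted: Counter = field(default_factory=Counter)

    def type_frequency_frame(self) -> pd.DataFrame:
        types = sorted(set(self.type_frequency_gold) | set(self.type_frequency_predicted))
        return pd.DataFrame({
            "type_id": types,
            "gold": [self.type_frequency_gold.get(t, 0) for t in types],
            "predicted": [self.type_frequency_predicted.get(t, 0) for t in types],
        })


def _gold_index(gold: Iterable[InteractionRecord]) -> dict[frozenset, list[int]]:
    idx: dict[frozenset, list[int]] = {}
    for g in gold:
        idx.setdefault(g.unordered, []).append(g.type_id)
    return idx


def screen_cohort(plans: Sequence[MedicationPlan], gold: Iterable[InteractionRecord],
                  predictions: PredictionSet, registry: Registry) -> CohortReport:
    """Screen every plan against the gold standard and the prediction
    set; unknown drug IDs in a plan are an error."""
    offenders = sorted({d for p in plans for d in p.drug_ids if d not in registry})
    if offenders:
        raise ValueError(f"plans reference unknown drug IDs: {offenders}")
    gold_idx = _gold_index(gold)
    pred_idx: dict[frozenset, list[int]] = {}
    for r in predictions.records:
        pred_idx.setdefault(r.unordered, []).append(r.type_id)

    rows = []
    total_comb = 0
    comb_gold = comb_pred = 0
    freq_gold: Counter = Counter()
    freq_pred: Counter = Counter()
    for plan in plans:
        pairs = enumerate_plan_pairs(plan, registry)
        total_comb += len(pairs)
        n_gold = n_pred = 0
        for a, b in pairs:
            key = frozenset((a, b))
            g_types = gold_idx.get(key, [])
            p_types = pred_idx.get(key, [])
            n_gold += len(g_types)
            n_pred += len(p_types)
            comb_gold += bool(g_types)
            comb_pred += bool(p_types)
            freq_gold.update(g_types)
            freq_pred.update(p_types)
        rows.append({"patient_id": plan.patient_id,
                     "n_medications": len(plan.drug_ids),
                     "gold_ddis": n_gold, "predicted_ddis": n_pred})
    per_patient = pd.DataFrame(rows)
    n = len(plans)
    return CohortReport(
        n_patients=n,
        total_combinations=total_comb,
        per_patient=per_patient,
        gold_total=int(per_patient["gold_ddis"].sum()) if n else 0,
        predicted_total=int(per_patient["predicted_ddis"].sum()) if n else 0,
        gold_prevalence=float((per_patient["gold_ddis"] > 0).mean()) if n else 0.0,
        predicted_prevalence=float((per_patient["predicted_ddis"] > 0).mean()) if n else 0.0,
        combinations_with_gold=comb_gold,
        combinations_with_prediction=comb_pred,
        type_frequency_gold=freq_gold,
        type_frequency_predicted=freq_pred,
    )


def switch_risk(plans: Sequence[MedicationPlan], candidate_drug: str,
                type_id: int, predictions: PredictionSet,
                registry: Registry) -> float:
    """Fraction of patients who would face at least one predicted
    interaction of ``type_id`` with the candidate drug after stopping
    their current disease-modifying therapy.

    Every drug of the registry's ``dmd`` category is removed from the
    plan before the candidate is added (idempotently, should the
    patient already take it).
    """
    if candidate_drug not in registry or not registry[candidate_drug].has_structure:
        raise ValueError(f"candidate {candidate_drug!r} has no structure")
    dmd_ids = {r.drug_id for r in registry.by_category("dmd")}
    at_risk = 0
    for plan in plans:
        others = {d for d in plan.drug_ids - dmd_ids - {candidate_drug}
                  if d in registry and registry[d].has_structure}
        if any(type_id in predictions.types_for_pair(candidate_drug, d)
               for d in others):
            at_risk += 1
    return at_risk / len(plans) if plans else 0.0


def switch_risk_matrix(plans: Sequence[MedicationPlan],
                       candidates: Sequence[str], type_ids: Sequence[int],
                       predictions: PredictionSet,
                       registry: Registry) -> pd.DataFrame:
    """Candidate x type matrix of switch risks (heat-map export)."""
    data = {t: [switch_risk(plans, c, t, predictions, registry)
                for c in candidates] for t in type_ids}
    return pd.DataFrame(data, index=list(candidates))


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    grid: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray


def ddi_count_vs_medications(report: CohortReport, column: str = "predicted_ddis",
                             n_boot: int = 500, seed: int = 0
                             ) -> tuple[pd.DataFrame, TrendFit | None]:
    """Per-patient (medication count, interaction count) table with an
    exponential trend fitted by log-linear least squares on
    log(count + 1), plus a bootstrap confidence band.

    Returns the table and ``None`` for the fit when fewer than three
    distinct medication counts are present.
    """
    table = report.per_patient[["patient_id", "n_medications", column]].copy()
    m = table["n_medications"].to_numpy(dtype=float)
    y = np.log1p(table[column].to_numpy(dtype=float))
    if len(np.unique(m)) < 3:
        return table, None
    slope, intercept = np.polyfit(m, y, 1)
    rng = np.random.default_rng(seed)
    grid = np.linspace(m.min(), m.max(), 50)
    boot_lines = np.empty((n_boot, grid.size))
    boot_slopes = np.empty(n_boot)
    n = len(m)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(m[idx])) < 2:
            boot_slopes[i] = slope
            boot_lines[i] = slope * grid + intercept
            continue
        s, b = np.polyfit(m[idx], y[idx], 1)
        boot_slopes[i] = s
        boot_lines[i] = s * grid + b
    fit = TrendFit(
        slope=float(slope), intercept=float(intercept),
        slope_ci=(float(np.percentile(boot_slopes, 2.5)),
                  float(np.percentile(boot_slopes, 97.5))),
        grid=grid,
        band_low=np.percentile(boot_lines, 2.5, axis=0),
        band_high=np.percentile(boot_lines, 97.5, axis=0),
    )
    return table, fit
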