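"""Desk-scale synthetic fixtures with the statistical structure the
analysis assumes.

The generator emulates the four licensed/private inputs of the study:

* a drug registry whose molecules are built from an enumerated
  scaffold-plus-substituent SMILES grammar (each drug carries one
  *dominant* substructure motif, attached three times, plus up to two
  secondary motifs), with target/action sets shared across drugs so
  that the substitution analysis has candidates;
* a gold-standard interaction set whose type labels are a deterministic
  function of the two drugs' dominant motifs via an ordered rule table
  — structurally similar drugs therefore have similar interaction
  patterns, which is exactly the assumption the classifier exploits;
* a patient cohort whose per-patient medication counts follow a
  truncated negative-binomial distribution matched to mean 5.3,
  SD 3.3 on the range 0..19;
* a food-composition table in which a configurable fraction of
  compounds is structurally near-identical to approved drugs (so the
  interaction-validation path fires) and at least one compound has
  more than ten sources (exercising the top-10 truncation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import CRITICAL_TYPES
from .corpus import (DrugRecord, FoodCompound, InteractionRecord,
                     MedicationPlan, Registry)

#: Substituent motifs of the SMILES grammar (appended as branches).
MOTIFS = ("C(=O)O", "N(C)C", "S(=O)(=O)N", "C(F)(F)F",
          "c1ccccc1", "c1ccncc1", "C#N", "OC")

#: How often the dominant motif is attached (strengthens its
#: fingerprint signal relative to the secondary motifs).
_DOMINANT_REPEATS = 3

_COURSES = ("CIS", "RRMS", "SPMS", "PPMS")
_COURSE_PROBS = (27 / 627, 388 / 627, 154 / 627, 58 / 627)


def build_rule_table() -> dict[tuple[int, int], int]:
    """Ordered (subject motif, object motif) -> interaction type.

    A fixed, seed-independent table.  Pinned cells create (a) pairs
    whose two orderings fire the adverse-effect type 26 and a
    pharmacokinetic type — the raw material of the mechanism-inference
    analysis — and (b) critical-type cells feeding the substitution
    analysis.  All remaining cells cycle through a pool of non-critical
    types, several of them concentration-altering so the food-network
    path is populated.
    """
    pool = [3, 6, 9, 10, 15, 34, 39, 43, 47, 54, 58, 62, 67, 71, 76, 80, 84,
            5, 7, 12]
    assert not set(pool) & CRITICAL_TYPES
    table = {(i, j): pool[(i * len(MOTIFS) + j) % len(pool)]
             for i in range(len(MOTIFS)) for j in range(len(MOTIFS))}
    pinned = {
        # adverse-effect type with an asymmetric mechanism counterpart
        (0, 1): 26, (1, 0): 6,
        (1, 2): 26, (2, 1): 7,
        (3, 0): 26, (0, 3): 9,
        # critical cells (hepatotoxicity / bleeding / hyperkalemia / QTc)
        (0, 2): 20, (2, 0): 27,
        (3, 4): 29, (4, 3): 32,
        # assorted named types
        (2, 3): 52, (3, 2): 67,
        # concentration-altering coverage
        (4, 5): 1, (5, 4): 2, (5, 6): 4, (6, 5): 5, (6, 7): 10, (7, 6): 15,
    }
    table.update(pinned)
    return table


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the shipped scenario."""

    n_drugs: int = 300
    n_dmd: int = 11
    n_btki: int = 5
    gold_density: float = 0.135
    n_patients: int = 627
    med_mean: float = 5.3
    med_sd: float = 3.3
    med_max: int = 19
    dmd_use_rate: float = 0.62
    n_target_groups: int = 40
    approved_fraction: float = 0.8
    n_food_compounds: int = 150
    n_food_sources: int = 80
    food_drug_like_fraction: float = 0.2
    seed: int = 0
    rule_table: dict[tuple[int, int], int] = field(default_factory=build_rule_table)

    def __post_init__(self):
        if min(self.n_drugs, self.n_patients, self.n_food_compounds,
               self.n_food_sources) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_dmd + self.n_btki >= self.n_drugs:
            raise ValueError("too few non-DMD drugs")


def _rng(cfg: ScenarioConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _motif_smiles(rng: np.random.Generator) -> tuple[str, int]:
    """One drug-like SMILES from the grammar, plus its dominant motif."""
    dominant = int(rng.integers(0, len(MOTIFS)))
    n_sec = int(rng.integers(0, 3))
    others = [m for m in range(len(MOTIFS)) if m != dominant]
    secondary = list(rng.choice(others, size=n_sec, replace=False))
    pre = "C" * int(rng.integers(1, 5))
    post = "C" * int(rng.integers(1, 4))
    branches = [f"C({MOTIFS[dominant]})"] * _DOMINANT_REPEATS
    branches += [f"C({MOTIFS[int(m)]})" for m in secondary]
    return pre + "".join(branches) + post, dominant


def gen_drug_library(cfg: ScenarioConfig) -> tuple[Registry, dict[str, int]]:
    """Generate the registry; returns it with the dominant-motif map
    that drives the gold-standard labels."""
    rng = _rng(cfg, 1)
    records, motifs = [], {}
    for i in range(cfg.n_drugs):
        drug_id = f"D{i:04d}"
        smiles, dominant = _motif_smiles(rng)
        if i < cfg.n_dmd:
            category, name = "dmd", f"DMD-{i:02d}"
            approved = True
        elif i < cfg.n_dmd + cfg.n_btki:
            category, name = "btki", f"BTKi-{i - cfg.n_dmd:02d}"
            approved = False  # investigational, no gold-standard records
        else:
            category, name = "non_dmd", f"Drug-{i:04d}"
            approved = bool(rng.random() < cfg.approved_fraction)
        group = i % cfg.n_target_groups
        targets = {(f"T{group}a", "inhibitor")}
        if group % 3 == 0:
            targets.add((f"T{group}b", "agonist"))
        records.append(DrugRecord(drug_id, name, smiles, approved,
                                  frozenset(targets), category))
        motifs[drug_id] = dominant
    return Registry(records), motifs


def label_for(drug_a: str, drug_b: str, motifs: dict[str, int],
              rule_table: dict[tuple[int, int], int]) -> tuple[str, str, int]:
    """The deterministic gold label of an unordered pair: the subject is
    the lexicographically lower drug id, the type the rule-table entry
    for the ordered dominant motifs."""
    subject, obj = sorted((drug_a, drug_b))
    return subject, obj, rule_table[(motifs[subject], motifs[obj])]


def gen_gold_standard(registry: Registry, motifs: dict[str, int],
                      cfg: ScenarioConfig) -> list[InteractionRecord]:
    """Sample unordered pairs of non-BTKi drugs at the configured
    density; exactly one type per pair, assigned by the rule table."""
    rng = _rng(cfg, 2)
    eligible = sorted(r.drug_id for r in registry.predictable()
                      if r.category != "btki")
    records = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1:]:
            if rng.random() < cfg.gold_density:
                subject, obj, type_id = label_for(a, b, motifs, cfg.rule_table)
                records.append(InteractionRecord(subject, obj, type_id,
                                                 provenance="gold"))
    return records


@lru_cache(maxsize=8)
def _medication_count_pmf(mean: float, sd: float, upper: int) -> tuple[float, ...]:
    """Probability mass of the medication-count distribution on
    0..upper: a negative binomial truncated to the range, its (r, p)
    solved numerically so the truncated moments match the targets."""
    support = np.arange(upper + 1)

    def moments(params):
        r, p = params
        pmf = stats.nbinom.pmf(support, r, p)
        pmf = pmf / pmf.sum()
        mu = float(pmf @ support)
        var = float(pmf @ (support - mu) ** 2)
        return mu, np.sqrt(var)

    def loss(params):
        if params[0] <= 0 or not (0 < params[1] < 1):
            return 1e6
        mu, sigma = moments(params)
        return (mu - mean) ** 2 + (sigma - sd) ** 2

    r0 = mean ** 2 / max(sd ** 2 - mean, 1e-3)
    res = optimize.minimize(loss, x0=[r0, r0 / (r0 + mean)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    pmf = stats.nbinom.pmf(support, *res.x)
    return tuple(pmf / pmf.sum())


def gen_cohort(registry: Registry, cfg: ScenarioConfig) -> list[MedicationPlan]:
    """Generate medication plans; counts follow the truncated
    negative-binomial, a configurable fraction of patients carries one
    disease-modifying drug, the rest of each plan is drawn from the
    non-DMD small molecules."""
    rng = _rng(cfg, 3)
    pmf = np.array(_medication_count_pmf(cfg.med_mean, cfg.med_sd, cfg.med_max))
    dmd_ids = sorted(r.drug_id for r in registry.by_category("dmd")
                     if r.has_structure)
    pool = sorted(r.drug_id for r in registry.by_category("non_dmd")
                  if r.has_structure)
    plans = []
    for i in range(cfg.n_patients):
        course = str(rng.choice(_COURSES, p=_COURSE_PROBS))
        m = int(rng.choice(len(pmf), p=pmf))
        drugs: set[str] = set()
        if m >= 1 and rng.random() < cfg.dmd_use_rate:
            drugs.add(str(rng.choice(dmd_ids)))
        remaining = m - len(drugs)
        if remaining > 0:
            drugs |= set(rng.choice(pool, size=remaining, replace=False))
        plans.append(MedicationPlan(f"P{i:04d}", frozenset(drugs), course))
    return plans


def gen_food_db(registry: Registry, cfg: ScenarioConfig
                ) -> tuple[list[FoodCompound], pd.DataFrame]:
    """Food compounds plus a quantitative content table.

    A configured fraction of compounds shares the structure of an
    approved registry drug (Dice 1.0 to that drug, so the validation
    path has material); compound F0000 always has twelve sources so the
    top-10 source truncation is exercised; all amounts are positive.
    """
    rng = _rng(cfg, 4)
    approved_smiles = [r.smiles for r in registry.predictable() if r.approved]
    compounds = []
    for i in range(cfg.n_food_compounds):
        cid = f"F{i:04d}"
        if rng.random() < cfg.food_drug_like_fraction:
            smiles = str(rng.choice(approved_smiles))
        else:
            smiles, _ = _motif_smiles(rng)
        compounds.append(FoodCompound(cid, f"FoodCompound-{i:04d}", smiles))
    sources = [(f"S{j:03d}", f"Food-{j:03d}") for j in range(cfg.n_food_sources)]
    rows = []
    for i, comp in enumerate(compounds):
        n_src = 12 if i == 0 else int(rng.integers(3, 11))
        n_src = min(n_src, cfg.n_food_sources)
        chosen = rng.choice(cfg.n_food_sources, size=n_src, replace=False)
        for j in chosen:
            amount = float(np.round(rng.lognormal(mean=2.0, sigma=1.0), 4))
            sid, sname = sources[int(j)]
            rows.append((sid, sname, comp.compound_id, max(amount, 1e-4)))
    contents = pd.DataFrame(rows, columns=["source_id", "source_name",
                                           "compound_id", "amount_mg_per_100g"])
    return compounds, contents


@dataclass
class ScenarioData:
    """Everything one synthetic study comprises."""

    cfg: ScenarioConfig
    registry: Registry
    motifs: dict[str, int]
    gold: list[InteractionRecord]
    plans: list[MedicationPlan]
    food_compounds: list[FoodCompound]
    food_contents: pd.DataFrame


def generate_scenario(cfg: ScenarioConfig | None = None) -> ScenarioData:
    cfg = cfg or ScenarioConfig()
    registry, motifs = gen_drug_library(cfg)
    gold = gen_gold_standard(registry, motifs, cfg)
    plans = gen_cohort(registry, cfg)
    compounds, contents = gen_food_db(registry, cfg)
    return ScenarioData(cfg, registry, motifs, gold, plans, compounds, contents)


def write_scenario(data: ScenarioData, outdir) -> None:
    """Write the corpus-module file schemas plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg_rows = [{
        "id": r.drug_id, "name": r.name, "smiles": r.smiles or "",
        "approved": str(r.approved).lower(),
        "targets": ";".join(f"{t}:{a}" for t, a in sorted(r.targets)),
        "category": r.category,
    } for r in data.registry]
    pd.DataFrame(reg_rows).to_csv(outdir / "registry.tsv", sep="\t", index=False)
    pd.DataFrame([{"subject_id": g.subject_id, "object_id": g.object_id,
                   "type_id": g.type_id} for g in data.gold]
                 ).to_csv(outdir / "gold.tsv", sep="\t", index=False)
    pd.DataFrame([{"patient_id": p.patient_id, "course": p.course or "",
                   "drugs": ";".join(sorted(p.drug_ids))} for p in data.plans]
                 ).to_csv(outdir / "plans.csv", index=False)
    pd.DataFrame([{"compound_id": c.compound_id, "name": c.name,
                   "smiles": c.smiles or ""} for c in data.food_compounds]
                 ).to_csv(outdir / "food_compounds.csv", index=False)
    data.food_contents.to_csv(outdir / "food_contents.csv", index=False)
    manifest = asdict(data.cfg)
    manifest["rule_table"] = {f"{i},{j}": t
                              for (i, j), t in data.cfg.rule_table.items()}
    manifest["motifs"] = data.motifs
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
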