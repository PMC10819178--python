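"""Loading, validation and filtering of the pipeline's tabular inputs:
drug registry, gold-standard interaction set, sentence templates, food
compounds / content tables, and the train/validation/test split.

File schemas (all plain text):

* registry TSV: ``id  name  smiles  approved  targets  category`` where
  ``targets`` is ``;``-separated ``target:action`` pairs and ``category``
  is one of ``non_dmd, dmd, btki, other``
* interactions TSV: ``subject_id  object_id  type_id``
* templates YAML: list of ``{type_id, critical, template}``
* food compounds CSV: ``compound_id, name, smiles``
* food contents CSV: ``source_id, source_name, compound_id,
  amount_mg_per_100g``
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .chemfeat import StructureParseError, canonicalize_structure
from .config import CRITICAL_TYPES, N_TYPES

VALID_CATEGORIES = {"non_dmd", "dmd", "btki", "other"}


@dataclass(frozen=True)
class DrugRecord:
    """One small-molecule drug with structure and target annotations.

    ``smiles`` is the canonical form, or ``None`` when the input
    structure did not parse (the record is then excluded from
    prediction but kept in the registry).
    """

    drug_id: str
    name: str
    smiles: str | None
    approved: bool
    targets: frozenset[tuple[str, str]]
    category: str = "other"

    @property
    def has_structure(self) -> bool:
        return self.smiles is not None


class Registry:
    """Drug registry keyed by unique drug_id, preserving input order."""

    def __init__(self, records: Sequence[DrugRecord]):
        self._records: dict[str, DrugRecord] = {}
        for rec in records:
            if rec.drug_id in self._records:
                raise ValueError(f"duplicate drug_id {rec.drug_id!r}")
            self._records[rec.drug_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._records

    def __getitem__(self, drug_id: str) -> DrugRecord:
        return self._records[drug_id]

    def __iter__(self):
        return iter(self._records.values())

    @property
    def drug_ids(self) -> list[str]:
        return list(self._records)

    def predictable(self) -> list[DrugRecord]:
        """Records with a parseable structure (prediction-eligible)."""
        return [r for r in self if r.has_structure]

    def by_category(self, category: str) -> list[DrugRecord]:
        return [r for r in self if r.category == category]

    def smiles_by_id(self) -> dict[str, str]:
        return {r.drug_id: r.smiles for r in self.predictable()}


def _parse_targets(cell: str) -> frozenset[tuple[str, str]]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    pairs = []
    for chunk in cell.split(";"):
        target, _, action = chunk.partition(":")
        pairs.append((target.strip(), action.strip()))
    return frozenset(pairs)


def load_registry(path) -> Registry:
    """Load a drug-registry TSV.

    Rows whose SMILES does not parse are retained but flagged
    structure-less; duplicate IDs and missing columns are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "name", "smiles", "approved", "targets", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            smiles, _ = canonicalize_structure(row.smiles)
        except StructureParseError:
            smiles = None
        category = row.category.strip() or "other"
        if category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {category!r} for drug {row.id}")
        records.append(DrugRecord(
            drug_id=row.id, name=row.name, smiles=smiles,
            approved=str(row.approved).strip().lower() in {"true", "1", "yes"},
            targets=_parse_targets(row.targets), category=category,
        ))
    return Registry(records)


@dataclass(frozen=True)
class InteractionRecord:
    """Ordered compound pair plus one interaction type.

    The subject is the sentence subject (the causal agent).  ``score``
    is the output-neuron activation for predicted records and 1.0 for
    gold-standard ones.
    """

    subject_id: str
    object_id: str
    type_id: int
    provenance: str = "gold"  # "gold" | "predicted"
    score: float = 1.0

    def __post_init__(self):
        if not (1 <= self.type_id <= N_TYPES):
            raise ValueError(f"type_id {self.type_id} outside 1..{N_TYPES}")
        if self.provenance not in {"gold", "predicted"}:
            raise ValueError(f"bad provenance {self.provenance!r}")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.subject_id, self.object_id))


def load_interactions(path, provenance: str = "gold") -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "object_id": str,
                                            "type_id": int})
    return [InteractionRecord(r.subject_id, r.object_id, int(r.type_id),
                              provenance=provenance)
            for r in df.itertuples(index=False)]


@dataclass
class FilterReport:
    retained: list[InteractionRecord]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def retained_fraction(self) -> float:
        total = len(self.retained) + sum(self.dropped.values())
        return len(self.retained) / total if total else 0.0


def filter_gold_standard(raw: Iterable[dict | InteractionRecord],
                         registry: Registry) -> FilterReport:
    """Retain records where both drugs have parseable structures and the
    type is one of the 1..86 distinguished types.

    Accepts either :class:`InteractionRecord` objects or raw dicts with
    ``subject_id``/``object_id``/``type_id`` (raw dicts may carry
    out-of-range types, which are dropped rather than rejected).
    Returns the retained set plus per-reason drop counts.  Idempotent on
    its own output.
    """
    retained: list[InteractionRecord] = []
    dropped: dict[str, int] = {"no_structure": 0, "unknown_type": 0,
                               "unknown_drug": 0}
    for rec in raw:
        if isinstance(rec, InteractionRecord):
            subject, obj, type_id = rec.subject_id, rec.object_id, rec.type_id
        else:
            subject, obj, type_id = rec["subject_id"], rec["object_id"], int(rec["type_id"])
        if not (1 <= type_id <= N_TYPES):
            dropped["unknown_type"] += 1
            continue
        if subject not in registry or obj not in registry:
            dropped["unknown_drug"] += 1
            continue
        if not (registry[subject].has_structure and registry[obj].has_structure):
            dropped["no_structure"] += 1
            continue
        retained.append(InteractionRecord(subject, obj, type_id, provenance="gold"))
    return FilterReport(retained, {k: v for k, v in dropped.items() if v})


def split_sizes(n: int, fractions: Sequence[float] = (0.6, 0.2, 0.2)) -> tuple[int, ...]:
    """Partition sizes: floor(n * f) each, remainder to the first
    (training) partition."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    sizes = [int(np.floor(n * f)) for f in fractions]
    sizes[0] += n - sum(sizes)
    return tuple(sizes)


def split_dataset(records: Sequence, fractions: Sequence[float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> tuple[list, list, list]:
    """Random 60/20/20 split into train / validation / test.

    Disjoint, jointly exhaustive, deterministic for a fixed seed.
    """
    if len(records) == 0:
        raise ValueError("cannot split an empty record set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n_train, n_val, _ = split_sizes(len(records), fractions)
    parts = (perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:])
    return tuple([records[i] for i in idx] for idx in parts)


@dataclass(frozen=True)
class SentenceTemplate:
    type_id: int
    template: str
    critical: bool

    def __post_init__(self):
        if self.critical != (self.type_id in CRITICAL_TYPES):
            raise ValueError(
                f"type {self.type_id}: critical flag inconsistent with the "
                f"14-type critical set")


class TemplateTable:
    """One sentence template per interaction type."""

    def __init__(self, templates: Sequence[SentenceTemplate]):
        self._by_id: dict[int, SentenceTemplate] = {}
        for t in templates:
            if t.type_id in self._by_id:
                raise ValueError(f"duplicate template for type {t.type_id}")
            self._by_id[t.type_id] = t

    def __len__(self) -> int:
        return len(self._by_id)

    def __getitem__(self, type_id: int) -> SentenceTemplate:
        return self._by_id[type_id]

    def __iter__(self):
        return iter(self._by_id.values())

    @property
    def critical_types(self) -> frozenset[int]:
        return frozenset(t.type_id for t in self if t.critical)


def load_templates(path=None) -> TemplateTable:
    """Load the sentence-template YAML; defaults to the packaged table
    of all 86 types."""
    if path is None:
        source = importlib.resources.files("ddiscreen.data") / "templates.yaml"
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return TemplateTable([SentenceTemplate(int(r["type_id"]), r["template"],
                                           bool(r["critical"])) for r in raw])


@dataclass(frozen=True)
class FoodCompound:
    compound_id: str
    name: str
    smiles: str | None

    @property
    def has_structure(self) -> bool:
        return self.smiles is not None


def load_food_compounds(path) -> list[FoodCompound]:
    """Load food compounds; unparseable structures are flagged (excluded
    from prediction) rather than dropped."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        try:
            smiles, _ = canonicalize_structure(row.smiles)
        except StructureParseError:
            smiles = None
        out.append(FoodCompound(row.compound_id, row.name, smiles))
    return out


def load_food_contents(path) -> pd.DataFrame:
    """Load the quantitative content table (mg per 100 g); negative
    amounts are rejected."""
    df = pd.read_csv(path, dtype={"source_id": str, "source_name": str,
                                  "compound_id": str,
                                  "amount_mg_per_100g": float})
    if (df["amount_mg_per_100g"] < 0).any():
        raise ValueError("content amounts must be non-negative")
    return df


@dataclass(frozen=True)
class MedicationPlan:
    """One patient's concurrently used drugs (set semantics)."""

    patient_id: str
    drug_ids: frozenset[str]
    course: str | None = None  # CIS | RRMS | SPMS | PPMS


def load_plans(path, registry: Registry | None = None) -> list[MedicationPlan]:
    """Plans CSV: ``patient_id, course, drugs`` with ``;``-separated
    drug IDs.  Unknown drug IDs are an error when a registry is given."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    plans = []
    offenders = []
    for row in df.itertuples(index=False):
        ids = frozenset(d for d in row.drugs.split(";") if d)
        if registry is not None:
            offenders.extend(d for d in ids if d not in registry)
        plans.append(MedicationPlan(row.patient_id, ids, row.course or None))
    if offenders:
        raise ValueError(f"plans reference unknown drug IDs: {sorted(set(offenders))}")
    return plans
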