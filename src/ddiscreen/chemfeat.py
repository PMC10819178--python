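"""Structure featurization: canonical SMILES, circular fingerprints,
Dice similarity profiles and their PCA reduction into pair features.

The featurization chain is::

    SMILES -> canonical molecule -> Morgan fingerprint (radius 2, 2048 bits)
           -> similarity profile against a fixed reference drug panel
           -> PCA reduction to k dimensions (default 50)
           -> pair feature = [reduced(a), reduced(b)]  (length 2k)

Everything downstream of the SMILES string is deterministic, so identical
inputs produce bit-identical pair features across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkDiceSimilarity, ExplicitBitVect
from sklearn.decomposition import PCA

from .config import FP_NBITS, FP_RADIUS, PCA_DIM

RDLogger.DisableLog("rdApp.error")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


def canonicalize_structure(smiles: str) -> tuple[str, Chem.Mol]:
    """Parse a SMILES string and return (canonical SMILES, molecule).

    Two inputs denoting the same molecule yield identical canonical text.
    Raises :class:`StructureParseError` for malformed or empty input;
    corpus loading catches this and flags the record instead.
    """
    if not smiles or not smiles.strip():
        raise StructureParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StructureParseError(smiles)
    return Chem.MolToSmiles(mol), mol


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_GENERATORS[key]


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular fingerprint: the set of on bits out of ``n_bits``."""

    bits: frozenset[int]
    n_bits: int = FP_NBITS

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.n_bits:
            raise ValueError("bit index out of range")

    def to_rdkit(self) -> ExplicitBitVect:
        bv = ExplicitBitVect(self.n_bits)
        bv.SetBitsFromList(sorted(self.bits))
        return bv


def fingerprint(mol: Chem.Mol, radius: int = FP_RADIUS, n_bits: int = FP_NBITS) -> Fingerprint:
    """Morgan fingerprint of a molecule as a :class:`Fingerprint`."""
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    bv = _generator(radius, n_bits).GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()), n_bits)


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    if not a.bits or not b.bits:
        raise ValueError("Dice similarity of an empty fingerprint is undefined")
    inter = len(a.bits & b.bits)
    return 2.0 * inter / (len(a.bits) + len(b.bits))


@dataclass(frozen=True)
class SimilarityProfile:
    """A compound's vector of Dice similarities against a reference panel."""

    values: np.ndarray
    panel_id: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("profile must be a vector")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("profile entries must lie in [0, 1]")


class ReferencePanel:
    """Ordered, pre-fingerprinted reference drug list for profiles.

    The panel order is the input order and is persisted alongside any
    projection model fitted on its profiles.
    """

    def __init__(self, drug_ids: Sequence[str], fingerprints: Sequence[Fingerprint],
                 panel_id: str = "panel"):
        if len(drug_ids) == 0:
            raise ValueError("reference panel must be non-empty")
        if len(drug_ids) != len(fingerprints):
            raise ValueError("panel ids and fingerprints differ in length")
        self.drug_ids = list(drug_ids)
        self.panel_id = panel_id
        self._fps = list(fingerprints)
        self._bvs = [fp.to_rdkit() for fp in fingerprints]

    def __len__(self) -> int:
        return len(self.drug_ids)

    def profile(self, fp: Fingerprint) -> SimilarityProfile:
        return similarity_profile(fp, self)


def similarity_profile(fp: Fingerprint, panel: ReferencePanel) -> SimilarityProfile:
    """Dice similarities of one fingerprint against every panel member."""
    values = np.array(BulkDiceSimilarity(fp.to_rdkit(), panel._bvs), dtype=np.float64)
    return SimilarityProfile(values, panel.panel_id)


@dataclass
class ProjectionModel:
    """Centering + orthonormal projection of similarity profiles to k dims.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making refits reproducible.
    """

    mean: np.ndarray
    components: np.ndarray  # (k, panel_size), orthonormal rows
    explained_variance: np.ndarray
    panel_id: str
    k: int
    n_bits: int = FP_NBITS
    radius: int = FP_RADIUS

    def project(self, profile: SimilarityProfile) -> np.ndarray:
        if profile.values.shape[0] != self.mean.shape[0]:
            raise ValueError("profile length does not match the fitted panel size")
        return (profile.values - self.mean) @ self.components.T

    def save(self, path) -> None:
        """Persist as a text file: one JSON header line, then CSV rows
        (first the mean, then the k component rows)."""
        header = {
            "k": self.k, "panel_id": self.panel_id, "n_bits": self.n_bits,
            "radius": self.radius,
            "explained_variance": self.explained_variance.tolist(),
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, np.vstack([self.mean, self.components]),
                       delimiter=",", fmt="%.17g")

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        with open(path) as fh:
            header = json.loads(fh.readline())
            mat = np.loadtxt(fh, delimiter=",", ndmin=2)
        return cls(
            mean=mat[0], components=mat[1:],
            explained_variance=np.array(header["explained_variance"]),
            panel_id=header["panel_id"], k=header["k"],
            n_bits=header["n_bits"], radius=header["radius"],
        )


def fit_projection(profiles: Iterable[SimilarityProfile], k: int = PCA_DIM) -> ProjectionModel:
    """Fit a k-dimensional PCA on a collection of similarity profiles."""
    plist = list(profiles)
    if not plist:
        raise ValueError("no profiles to fit")
    panel_id = plist[0].panel_id
    X = np.vstack([p.values for p in plist])
    if k > min(X.shape):
        raise ValueError(
            f"k={k} exceeds the feasible rank min(n_profiles, panel_size)="
            f"{min(X.shape)}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    # deterministic sign convention: largest-|loading| entry positive
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return ProjectionModel(
        mean=pca.mean_.copy(), components=components,
        explained_variance=pca.explained_variance_.copy(),
        panel_id=panel_id, k=k,
    )


@dataclass(frozen=True)
class PairFeature:
    """Concatenated reduced profiles of an ordered compound pair."""

    vector: np.ndarray
    order: tuple[str, str]


def pair_feature(drug_a: str, drug_b: str, model: ProjectionModel,
                 profiles: Mapping[str, SimilarityProfile]) -> PairFeature:
    """Build the 2k-long feature for the ordered pair (drug_a, drug_b).

    Swapping the pair order exchanges the two halves of the vector.
    """
    for d in (drug_a, drug_b):
        if d not in profiles:
            raise KeyError(f"no similarity profile for drug {d!r}")
    vec = np.concatenate([model.project(profiles[drug_a]),
                          model.project(profiles[drug_b])])
    return PairFeature(vec, (drug_a, drug_b))


class FeaturePipeline:
    """Convenience wrapper holding panel, profiles and projection model.

    Built once per run from the predictable drugs of a registry; food
    compounds can be profiled on the fly with :meth:`add_compound`.
    """

    def __init__(self, panel: ReferencePanel, model: ProjectionModel,
                 profiles: dict[str, SimilarityProfile]):
        self.panel = panel
        self.model = model
        self.profiles = profiles
        self._reduced: dict[str, np.ndarray] = {}

    @classmethod
    def fit(cls, smiles_by_id: Mapping[str, str], k: int = PCA_DIM,
            panel_ids: Sequence[str] | None = None,
            panel_id: str = "registry") -> "FeaturePipeline":
        """Fingerprint all compounds, build the panel (default: all of
        them, input order), profile each and fit the PCA."""
        fps = {}
        for cid, smi in smiles_by_id.items():
            _, mol = canonicalize_structure(smi)
            fps[cid] = fingerprint(mol)
        ids = list(panel_ids) if panel_ids is not None else list(smiles_by_id)
        panel = ReferencePanel(ids, [fps[i] for i in ids], panel_id=panel_id)
        profiles = {cid: panel.profile(fp) for cid, fp in fps.items()}
        model = fit_projection(profiles.values(), k=k)
        return cls(panel, model, profiles)

    def add_compound(self, compound_id: str, smiles: str) -> None:
        _, mol = canonicalize_structure(smiles)
        self.profiles[compound_id] = self.panel.profile(fingerprint(mol))

    def reduced(self, compound_id: str) -> np.ndarray:
        if compound_id not in self._reduced:
            self._reduced[compound_id] = self.model.project(self.profiles[compound_id])
        return self._reduced[compound_id]

    def pair_vector(self, a: str, b: str) -> np.ndarray:
        for d in (a, b):
            if d not in self.profiles:
                raise KeyError(f"no similarity profile for compound {d!r}")
        return np.concatenate([self.reduced(a), self.reduced(b)])

    def pair_matrix(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Stack pair vectors for a batch of ordered pairs."""
        return np.vstack([self.pair_vector(a, b) for a, b in pairs])
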