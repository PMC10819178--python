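"""Featurization chain: canonical SMILES, fingerprints, Dice profiles,
PCA projection and pair features."""

import numpy as np
import pytest
from rdkit import Chem

from ddiscreen import (FeaturePipeline, Fingerprint, ProjectionModel,
                       ReferencePanel, SimilarityProfile, StructureParseError,
                       canonicalize_structure, dice_similarity, fingerprint,
                       fit_projection, pair_feature, similarity_profile)
from ddiscreen.synthetic_data import _motif_smiles


def _generated_smiles(n, seed=0):
    rng = np.random.default_rng(seed)
    return [_motif_smiles(rng)[0] for _ in range(n)]


class TestCanonicalize:
    def test_equivalent_inputs_share_canonical_form(self):
        can1, _ = canonicalize_structure("OCC")
        can2, _ = canonicalize_structure("CCO")
        assert can1 == can2

    @pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", "", "   "])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(StructureParseError):
            canonicalize_structure(bad)

    def test_idempotent_on_generated_structures(self):
        for smi in _generated_smiles(100):
            once, _ = canonicalize_structure(smi)
            twice, _ = canonicalize_structure(once)
            assert once == twice


class TestFingerprint:
    def test_deterministic(self):
        _, mol = canonicalize_structure("CC(=O)Oc1ccccc1C(=O)O")
        assert fingerprint(mol).bits == fingerprint(mol).bits

    def test_radius_environments_nest(self):
        for smi in _generated_smiles(10, seed=1):
            _, mol = canonicalize_structure(smi)
            assert len(fingerprint(mol, radius=0).bits) <= len(fingerprint(mol, radius=2).bits)

    def test_invariant_under_atom_renumbering(self):
        # oracle: a second fingerprint pass over a permuted atom order
        rng = np.random.default_rng(2)
        for smi in _generated_smiles(20, seed=3):
            _, mol = canonicalize_structure(smi)
            perm = list(rng.permutation(mol.GetNumAtoms()))
            permuted = Chem.RenumberAtoms(mol, [int(i) for i in perm])
            assert fingerprint(mol).bits == fingerprint(permuted).bits

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            fingerprint(Chem.Mol())

    def test_bit_range_invariant(self):
        with pytest.raises(ValueError):
            Fingerprint(frozenset({2048}), n_bits=2048)


class TestDice:
    def test_identity_is_one(self):
        fp = Fingerprint(frozenset({1, 5, 9}))
        assert dice_similarity(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        a = Fingerprint(frozenset({1, 2}))
        b = Fingerprint(frozenset({3, 4}))
        assert dice_similarity(a, b) == 0.0

    def test_hand_computed_overlap(self):
        a = Fingerprint(frozenset({1, 2, 3}))
        b = Fingerprint(frozenset({2, 3, 4}))
        assert dice_similarity(a, b) == pytest.approx(2 * 2 / (3 + 3))

    def test_symmetry_and_range_on_generated_fingerprints(self):
        fps = []
        for smi in _generated_smiles(15, seed=4):
            _, mol = canonicalize_structure(smi)
            fps.append(fingerprint(mol))
        for a in fps:
            assert dice_similarity(a, a) == 1.0
            for b in fps:
                d = dice_similarity(a, b)
                assert d == dice_similarity(b, a)
                assert 0.0 <= d <= 1.0

    def test_width_mismatch_rejected(self):
        a = Fingerprint(frozenset({1}), n_bits=1024)
        b = Fingerprint(frozenset({1}), n_bits=2048)
        with pytest.raises(ValueError):
            dice_similarity(a, b)


@pytest.fixture(scope="module")
def panel():
    fps = []
    for smi in _generated_smiles(10, seed=5):
        _, mol = canonicalize_structure(smi)
        fps.append(fingerprint(mol))
    return ReferencePanel([f"D{i}" for i in range(10)], fps), fps


class TestSimilarityProfile:

    def test_self_entry_is_one_and_length_matches(self, panel):
        panel_obj, fps = panel
        prof = similarity_profile(fps[3], panel_obj)
        assert prof.values.shape == (10,)
        assert prof.values[3] == 1.0

    def test_matches_double_loop_oracle(self, panel):
        panel_obj, fps = panel
        for fp in fps:
            prof = similarity_profile(fp, panel_obj)
            brute = [2 * len(fp.bits & q.bits) / (len(fp.bits) + len(q.bits))
                     for q in fps]
            np.testing.assert_allclose(prof.values, brute, atol=1e-12)

    def test_entries_bounded(self):
        with pytest.raises(ValueError):
            SimilarityProfile(np.array([0.5, 1.2]), "p")


class TestProjection:
    def _planar_profiles(self, n=30, dim=6, seed=6):
        # profiles lying exactly in a 2-plane inside [0,1]^dim
        rng = np.random.default_rng(seed)
        u = rng.random(dim) * 0.1
        v = rng.random(dim) * 0.1
        base = np.full(dim, 0.5)
        coeffs = rng.uniform(-1, 1, size=(n, 2))
        X = base + coeffs[:, :1] * u + coeffs[:, 1:] * v
        return [SimilarityProfile(x, "toy") for x in X]

    def test_planar_data_reconstructs_exactly_at_k2(self):
        profiles = self._planar_profiles()
        model = fit_projection(profiles, k=2)
        X = np.vstack([p.values for p in profiles])
        Z = (X - model.mean) @ model.components.T
        recon = Z @ model.components + model.mean
        assert np.abs(recon - X).max() < 1e-8

    def test_mean_profile_projects_to_zero(self):
        profiles = self._planar_profiles()
        model = fit_projection(profiles, k=2)
        z = model.project(SimilarityProfile(model.mean, "toy"))
        np.testing.assert_allclose(z, 0.0, atol=1e-10)

    def test_explained_variance_non_increasing(self):
        profiles = self._planar_profiles(n=40, dim=8, seed=7)
        model = fit_projection(profiles, k=4)
        ev = model.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_rows_orthonormal(self):
        profiles = self._planar_profiles(n=40, dim=8, seed=8)
        model = fit_projection(profiles, k=3)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_increasing_k_never_worsens_reconstruction(self):
        rng = np.random.default_rng(9)
        profiles = [SimilarityProfile(rng.random(8), "toy") for _ in range(30)]
        X = np.vstack([p.values for p in profiles])
        errs = []
        for k in (1, 2, 4, 6):
            m = fit_projection(profiles, k=k)
            Z = (X - m.mean) @ m.components.T
            errs.append(np.linalg.norm(Z @ m.components + m.mean - X))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_infeasible_k_rejected(self):
        profiles = self._planar_profiles(n=5, dim=6)
        with pytest.raises(ValueError):
            fit_projection(profiles, k=7)

    def test_persistence_round_trip_bit_compatible(self, tmp_path):
        profiles = self._planar_profiles(n=20, dim=6, seed=10)
        model = fit_projection(profiles, k=2)
        path = tmp_path / "proj.txt"
        model.save(path)
        loaded = ProjectionModel.load(path)
        np.testing.assert_array_equal(loaded.mean, model.mean)
        np.testing.assert_array_equal(loaded.components, model.components)
        assert loaded.k == model.k and loaded.panel_id == model.panel_id


@pytest.fixture(scope="module")
def pipeline():
    smiles = {f"D{i}": s for i, s in enumerate(_generated_smiles(60, seed=11))}
    return FeaturePipeline.fit(smiles, k=50)


class TestPairFeature:

    def test_default_vector_length_is_100(self, pipeline):
        vec = pipeline.pair_vector("D0", "D1")
        assert vec.shape == (100,)

    def test_swapping_order_exchanges_halves(self, pipeline):
        ab = pipeline.pair_vector("D0", "D1")
        ba = pipeline.pair_vector("D1", "D0")
        np.testing.assert_array_equal(ab[:50], ba[50:])
        np.testing.assert_array_equal(ab[50:], ba[:50])

    def test_missing_profile_names_the_drug(self, pipeline):
        with pytest.raises(KeyError, match="D999"):
            pipeline.pair_vector("D0", "D999")

    def test_toy_model_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(12)
        profiles = {f"D{i}": SimilarityProfile(rng.random(5), "toy")
                    for i in range(8)}
        model = fit_projection(profiles.values(), k=2)
        pf = pair_feature("D1", "D3", model, profiles)
        expected = np.concatenate([
            model.components @ (profiles["D1"].values - model.mean),
            model.components @ (profiles["D3"].values - model.mean)])
        np.testing.assert_allclose(pf.vector, expected, atol=1e-12)
        assert pf.order == ("D1", "D3")

    def test_full_chain_deterministic_across_refits(self):
        smiles = {f"D{i}": s for i, s in enumerate(_generated_smiles(20, seed=13))}
        v1 = FeaturePipeline.fit(smiles, k=5).pair_vector("D0", "D1")
        v2 = FeaturePipeline.fit(smiles, k=5).pair_vector("D0", "D1")
        np.testing.assert_array_equal(v1, v2)
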