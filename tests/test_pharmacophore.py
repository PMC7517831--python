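"""Feature perception, model generation, selectivity, fit values, model AUC."""

import itertools

import numpy as np
import pytest

from ensemble_vs.ensemble import kabsch
from ensemble_vs.errors import InsufficientDataError
from ensemble_vs.pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
    embed_smiles,
    fit_value,
    generate_models,
    model_auc,
    perceive_features,
    selectivity_score,
)

from conftest import random_rotation


def types_of(feats):
    return sorted(f.type for f in feats)


class TestPerceiveFeatures:
    def test_benzene(self):
        feats = perceive_features(embed_smiles("c1ccccc1", seed=1))
        assert types_of(feats) == ["HYD", "RA"]

    def test_methanol_oxygen_donates_and_accepts(self):
        feats = perceive_features(embed_smiles("CO", seed=1))
        assert types_of(feats) == ["HBA", "HBD"]
        hbd = next(f for f in feats if f.type == "HBD")
        hba = next(f for f in feats if f.type == "HBA")
        np.testing.assert_allclose(hbd.center, hba.center)  # same oxygen

    def test_acetate_single_negative_center(self):
        mol = embed_smiles("CC(=O)[O-]", seed=1)
        feats = perceive_features(mol)
        nis = [f for f in feats if f.type == "NI"]
        assert len(nis) == 1
        # carboxylate centroid: mean of C, O, O positions
        xyz = np.array(mol.GetConformer().GetPositions())
        centroid = xyz[1:4].mean(axis=0)  # atoms C(=O)(O-) in input order
        np.testing.assert_allclose(nis[0].center, centroid, atol=1e-6)

    def test_no_conformer_raises(self):
        from rdkit import Chem

        with pytest.raises(ValueError):
            perceive_features(Chem.MolFromSmiles("CCO"))


class TestGenerateModels:
    def test_planted_donor_survives_at_3A(self, toy_complex_five, feature_background):
        receptor, ligand, toy = toy_complex_five
        models = generate_models(receptor, ligand, feature_background, complex_id="toy")
        assert any("D" in m.letter_code for m in models)

    def test_donor_beyond_threshold_filtered(self, feature_background, tmp_path):
        from ensemble_vs.ensemble import parse_pdb
        from ensemble_vs.synthetic import PlantedFeature, ToyComplexSpec, make_toy_complex
        from rdkit import Chem

        toy = make_toy_complex(
            ToyComplexSpec(
                [
                    PlantedFeature("HBD", 4.0),  # beyond the 3.5 A H-bond cutoff
                    PlantedFeature("HBA", 3.0),
                    PlantedFeature("HYD", 4.0),
                    PlantedFeature("NI", 5.0),
                ]
            )
        )
        pdb = tmp_path / "r.pdb"
        pdb.write_text(toy.pdb_text)
        receptor = parse_pdb(pdb, "t")
        ligand = Chem.MolFromMolBlock(toy.sdf_text, removeHs=False)
        assert toy.expected_surviving == ["HBA", "HYD", "NI"]
        models = generate_models(receptor, ligand, feature_background, complex_id="t")
        assert all("D" not in m.letter_code for m in models)

    def test_top_ten_of_sixteen_candidates_ordered(self, toy_complex_five, feature_background):
        """5 complemented features -> C(5,3)+C(5,4)+C(5,5)=16 subsets, top 10."""
        receptor, ligand, toy = toy_complex_five
        models = generate_models(
            receptor, ligand, feature_background, min_features=3, top_m=10, complex_id="toy"
        )
        assert len(models) == 10
        assert all(len(m.features) >= 3 for m in models)

        # brute-force re-scoring of all 16 subsets reproduces the ordering
        from ensemble_vs.pharmacophore import complemented_features

        kept, _ = complemented_features(receptor, ligand)
        assert len(kept) == 5
        subsets = []
        for size in (3, 4, 5):
            subsets.extend(itertools.combinations(range(5), size))
        assert len(subsets) == 16
        scored = []
        for combo in subsets:
            m = PharmacophoreModel("tmp", [kept[i] for i in combo])
            s = selectivity_score(m, feature_background)
            scored.append((-s, len(combo), m.letter_code))
        scored.sort()
        expected_keys = scored[:10]
        got_keys = [
            (-m.selectivity_score, len(m.features), m.letter_code) for m in models
        ]
        assert got_keys == expected_keys

    def test_deterministic_ordering(self, toy_complex_five, feature_background):
        receptor, ligand, _ = toy_complex_five
        a = generate_models(receptor, ligand, feature_background, complex_id="toy")
        b = generate_models(receptor, ligand, feature_background, complex_id="toy")
        assert [m.letter_code for m in a] == [m.letter_code for m in b]
        assert [m.selectivity_score for m in a] == [m.selectivity_score for m in b]

    def test_insufficient_features_error_explains(self, feature_background, tmp_path):
        from ensemble_vs.ensemble import parse_pdb
        from ensemble_vs.synthetic import PlantedFeature, ToyComplexSpec, make_toy_complex
        from rdkit import Chem

        toy = make_toy_complex(
            ToyComplexSpec([PlantedFeature("HBD", 6.0), PlantedFeature("HBA", 6.0), PlantedFeature("HYD", 6.0)])
        )
        pdb = tmp_path / "r.pdb"
        pdb.write_text(toy.pdb_text)
        receptor = parse_pdb(pdb, "t")
        ligand = Chem.MolFromMolBlock(toy.sdf_text, removeHs=False)
        with pytest.raises(InsufficientDataError, match="complemented"):
            generate_models(receptor, ligand, feature_background, complex_id="t")


def triangle_model(weights=(1.0, 1.0, 1.0), tolerance=1.6):
    """Equilateral-triangle 3-feature model (radius 2 A)."""
    r = 2.0
    centers = [
        r * np.array([np.cos(a), np.sin(a), 0.0]) for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)
    ]
    feats = [
        PharmacophoreFeature(t, c, tolerance=tolerance, weight=w)
        for t, c, w in zip(("HBA", "HBD", "HYD"), centers, weights)
    ]
    return PharmacophoreModel("tri", feats)


class TestSelectivityScore:
    def test_universally_matched_model_scores_zero(self):
        model = triangle_model()
        mols = [
            [[PharmacophoreFeature(f.type, f.center.copy()) for f in model.features]]
            for _ in range(50)
        ]
        assert selectivity_score(model, mols) == pytest.approx(0.0)

    def test_unmatched_floor(self):
        model = triangle_model()
        far = [
            [[PharmacophoreFeature("NI", np.array([100.0 + i, 0, 0]))]] for i in range(1000)
        ]
        assert selectivity_score(model, far) == pytest.approx(-np.log10(0.5 / 1000), abs=1e-12)

    def test_planted_ten_of_thousand(self):
        """Background built so exactly 10 of 1000 molecules match -> score 2.0."""
        model = triangle_model()
        matching = [
            [[PharmacophoreFeature(f.type, f.center.copy()) for f in model.features]]
            for _ in range(10)
        ]
        non = [[[PharmacophoreFeature("NI", np.array([50.0 + i, 0, 0]))]] for i in range(990)]
        background = matching + non
        n_match = sum(1 for m in background if fit_value(m, model).fit_value > 0)
        assert n_match == 10
        assert selectivity_score(model, background) == pytest.approx(2.0, abs=1e-12)

    def test_empty_background_raises(self):
        with pytest.raises(InsufficientDataError):
            selectivity_score(triangle_model(), [])


class TestFitValue:
    def test_perfect_coincidence_attains_weight_sum(self):
        model = triangle_model(weights=(1.0, 2.0, 0.5))
        mol = [[PharmacophoreFeature(f.type, f.center.copy()) for f in model.features]]
        res = fit_value(mol, model)
        assert res.matched
        assert res.fit_value == pytest.approx(model.max_fit, abs=1e-9)

    def test_boundary_displacement_matches_with_zero_fit(self):
        """Features scaled radially so every post-fit displacement = tolerance."""
        tol = 0.8
        model = triangle_model(tolerance=tol)
        centroid = np.mean([f.center for f in model.features], axis=0)
        scale = 1.0 + tol / 2.0  # features sit on a radius-2 circle
        mol = [[
            PharmacophoreFeature(f.type, centroid + scale * (f.center - centroid))
            for f in model.features
        ]]
        res = fit_value(mol, model)
        assert res.matched
        assert res.fit_value == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        model = triangle_model()
        rng = np.random.default_rng(4)
        base = [
            PharmacophoreFeature(f.type, f.center + rng.normal(0, 0.3, 3))
            for f in model.features
        ]
        ref_fit = fit_value([base], model).fit_value
        assert ref_fit > 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            R, t = random_rotation(r), r.uniform(-20, 20, 3)
            moved = [[PharmacophoreFeature(f.type, R @ f.center + t) for f in base]]
            assert fit_value(moved, model).fit_value == pytest.approx(ref_fit, abs=1e-6)

    def test_matches_exhaustive_assignment_oracle(self):
        """4-feature molecule, 2 conformers vs brute force over 2 x P(4,3) maps."""
        model = triangle_model()  # types HBA, HBD, HYD
        rng = np.random.default_rng(5)

        def conformer():
            feats = [
                PharmacophoreFeature(t, rng.normal(0, 2.0, 3))
                for t in ("HBA", "HBD", "HYD", "HBA")
            ]
            return feats

        conformers = [conformer(), conformer()]

        # oracle: every injective type-compatible map, explicit Kabsch each time
        ref = np.array([f.center for f in model.features])
        tols = np.array([f.tolerance for f in model.features])
        ws = np.array([f.weight for f in model.features])
        best = 0.0
        n_checked = 0
        for feats in conformers:
            for perm in itertools.permutations(range(4), 3):
                if any(feats[p].type != model.features[k].type for k, p in enumerate(perm)):
                    continue
                n_checked += 1
                mov = np.array([feats[p].center for p in perm])
                R, t, _ = kabsch(ref, mov)
                d = np.sqrt((((mov @ R.T + t) - ref) ** 2).sum(axis=1))
                if np.all(d <= tols + 1e-9):
                    best = max(best, float((ws * (1 - d / tols)).sum()))
        assert n_checked == 2 * 2  # 2 conformers x 2 valid type assignments
        res = fit_value(conformers, model)
        assert res.fit_value == pytest.approx(best, abs=1e-9)

    def test_unmatched_gives_zero(self):
        model = triangle_model()
        res = fit_value([[PharmacophoreFeature("NI", np.zeros(3))]], model)
        assert not res.matched
        assert res.fit_value == 0.0

    def test_removing_feature_never_shrinks_match_set(self):
        """Monotonicity: any molecule matching a model matches every sub-model."""
        model4 = PharmacophoreModel(
            "m4",
            triangle_model().features
            + [PharmacophoreFeature("NI", np.array([0.0, 0.0, 2.5]))],
        )
        rng = np.random.default_rng(6)
        mols = []
        for _ in range(30):
            feats = [
                PharmacophoreFeature(f.type, f.center + rng.normal(0, 0.9, 3))
                for f in model4.features
            ]
            mols.append([feats])
        for combo in itertools.combinations(range(4), 3):
            sub = PharmacophoreModel("sub", [model4.features[i] for i in combo])
            for mol in mols:
                if fit_value(mol, model4).matched:
                    assert fit_value(mol, sub).matched
        # consequently selectivity cannot increase when features are removed
        sub = PharmacophoreModel("sub", model4.features[:3])
        assert selectivity_score(sub, mols) <= selectivity_score(model4, mols)


class TestModelAuc:
    def _mols_with_fits(self):
        model = triangle_model()
        exact = [
            [[PharmacophoreFeature(f.type, f.center.copy()) for f in model.features]]
            for _ in range(4)
        ]
        rng = np.random.default_rng(7)
        off = [
            [[PharmacophoreFeature("NI", rng.uniform(40, 60, 3))]] for _ in range(6)
        ]
        return model, exact + off, [1] * 4 + [0] * 6

    def test_perfect_separation(self):
        model, mols, labels = self._mols_with_fits()
        assert model_auc(model, mols, labels) == 1.0
        assert model.auc == 1.0

    def test_all_equal_fits_give_half(self):
        model = triangle_model()
        mols = [[[PharmacophoreFeature("NI", np.array([90.0, 0, 0]))]] for _ in range(8)]
        assert model_auc(model, mols, [1, 0, 1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        model, mols, _ = self._mols_with_fits()
        with pytest.raises(InsufficientDataError):
            model_auc(model, mols, [1] * 10)
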