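"""Shared fixtures: toy complexes, hand-built molecules, random helpers."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import RWMol

from ensemble_vs.ensemble import ParsedStructure, parse_pdb
from ensemble_vs.synthetic import PlantedFeature, ToyComplexSpec, make_toy_complex


def mol_with_coords(atoms, bonds, coords, charges=None):
    """Build an RDKit mol with an explicit conformer.

    atoms: element symbols; bonds: (i, j, BondType); coords: (n, 3).
    """
    m = RWMol()
    for k, sym in enumerate(atoms):
        a = Chem.Atom(sym)
        if charges:
            a.SetFormalCharge(charges[k])
        m.AddAtom(a)
    for i, j, order in bonds:
        m.AddBond(i, j, order)
        if order == Chem.BondType.AROMATIC:
            m.GetAtomWithIdx(i).SetIsAromatic(True)
            m.GetAtomWithIdx(j).SetIsAromatic(True)
            m.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = m.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for k, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(k, [float(x) for x in xyz])
    mol.AddConformer(conf)
    return mol


def benzene_mol(rotation_deg: float = 0.0):
    """Planar benzene; optionally rotated in-plane about its centroid."""
    angles = np.linspace(0, 2 * np.pi, 7)[:-1] + np.deg2rad(rotation_deg)
    coords = np.c_[1.39 * np.cos(angles), 1.39 * np.sin(angles), np.zeros(6)]
    bonds = [(i, (i + 1) % 6, Chem.BondType.AROMATIC) for i in range(6)]
    return mol_with_coords(["C"] * 6, bonds, coords)


@pytest.fixture(scope="session")
def toy_complex_five(tmp_path_factory):
    """Toy complex with five planted, surviving features (one per type but RA)."""
    toy = make_toy_complex(
        ToyComplexSpec(
            [
                PlantedFeature("HBD", 3.0),
                PlantedFeature("HBA", 3.0),
                PlantedFeature("HYD", 4.0),
                PlantedFeature("NI", 5.0),
                PlantedFeature("PI", 5.0),
            ]
        )
    )
    pdb = tmp_path_factory.mktemp("toy") / "receptor.pdb"
    pdb.write_text(toy.pdb_text)
    receptor = parse_pdb(pdb, "toy")
    ligand = Chem.MolFromMolBlock(toy.sdf_text, removeHs=False)
    return receptor, ligand, toy


@pytest.fixture(scope="session")
def feature_background():
    """60 random-feature 'molecules' (1 conformer each) for selectivity scoring."""
    from ensemble_vs.pharmacophore import PharmacophoreFeature

    rng = np.random.default_rng(17)
    types = ["HBA", "HBD", "HYD", "NI", "PI", "RA"]
    background = []
    for _ in range(60):
        feats = [
            PharmacophoreFeature(types[rng.integers(len(types))], rng.uniform(-20, 20, 3))
            for _ in range(3)
        ]
        background.append([feats])
    return background


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
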