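"""Synthetic test inputs for the whole pipeline.

Three generators, all seeded and deterministic:

* :func:`make_score_benchmark` — labeled active/decoy docking-score matrices
  with Gaussian class-conditional scores per column. Gaussians give a
  closed-form expected AUC, Phi((mu_d - mu_a) / (sigma * sqrt(2))) for
  lower-is-better scores, which downstream checks exploit.
* :func:`make_toy_complex` — minimal receptor PDB + ligand SDF text with
  *planted* pharmacophoric interactions: each planted ligand feature gets a
  receptor partner placed at a chosen distance, so which features survive
  the receptor-complement filter is known a priori.
* :func:`make_library` — small-molecule SMILES libraries mixing curated
  drug-like scaffolds (decorated combinatorially with inert substituents)
  and deliberate Lipinski/Veber rule violators.

The toy complexes are deliberately minimal — isolated residues, no realistic
protein geometry; they exercise the interaction-filter logic, not force
fields.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from .scores import ScoreMatrix

__all__ = [
    "ScoreBenchmarkSpec",
    "make_score_benchmark",
    "PlantedFeature",
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "make_library",
]


# ---------------------------------------------------------------------------
# score benchmarks


@dataclass
class ScoreBenchmarkSpec:
    """Gaussian class-conditional score matrix specification.

    columns maps (structure_id, mode) -> (mu_active, mu_decoy, sigma),
    scores in kcal/mol (lower = better binder).
    """

    n_active: int
    n_decoy: int
    columns: Mapping[tuple[str, str], tuple[float, float, float]]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for key, (_, _, sigma) in self.columns.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be positive for column {key}")


def make_score_benchmark(spec: ScoreBenchmarkSpec) -> tuple[ScoreMatrix, pd.Series]:
    """Seeded Gaussian score matrix plus 1/0 labels (actives first)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_active + spec.n_decoy
    width = len(str(max(n, 1)))
    ids = [f"A{i:0{width}d}" for i in range(spec.n_active)] + [
        f"D{i:0{width}d}" for i in range(spec.n_decoy)
    ]
    labels = pd.Series(
        np.r_[np.ones(spec.n_active, dtype=int), np.zeros(spec.n_decoy, dtype=int)],
        index=ids, name="label",
    )
    data = {}
    for key, (mu_a, mu_d, sigma) in spec.columns.items():
        col = np.r_[
            rng.normal(mu_a, sigma, spec.n_active),
            rng.normal(mu_d, sigma, spec.n_decoy),
        ]
        if spec.missing_rate > 0:
            col[rng.random(n) < spec.missing_rate] = np.nan
        data[key] = col
    df = pd.DataFrame(data, index=ids)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["structure", "mode"])
    df.index.name = "compound_id"
    return ScoreMatrix(df), labels


# ---------------------------------------------------------------------------
# toy receptor-ligand complexes


@dataclass
class PlantedFeature:
    """One planted ligand feature plus the receptor partner distance.

    partner_offset is the distance (A) from the feature center at which the
    complementary receptor group is placed; compare it to the filter
    thresholds (3.5 H-bond / 4.5 hydrophobic / 5.5 ionic) to know a priori
    whether the feature survives.
    """

    type: str
    partner_offset: float
    position: tuple[float, float, float] | None = None


@dataclass
class ToyComplexSpec:
    planted: list[PlantedFeature]
    decoy_atom_count: int = 0
    seed: int = 0


@dataclass
class ToyComplex:
    pdb_text: str
    sdf_text: str
    expected_surviving: list[str]  # planted types expected past the complement filter
    spec: ToyComplexSpec


_SURVIVAL_THRESHOLD = {"HBD": 3.5, "HBA": 3.5, "HYD": 4.5, "RA": 4.5, "NI": 5.5, "PI": 5.5}


def _ligand_fragment(ftype: str, center: np.ndarray):
    """Atoms (symbol, charge, xyz) and bonds (i, j, order) of one fragment.

    Geometry is arranged so the perceived feature centroid lands exactly on
    `center`.
    """
    c = np.asarray(center, dtype=float)
    if ftype == "HBD":  # hydroxyl: O (donor+acceptor) at center
        atoms = [("O", 0, c), ("C", 0, c + (0.0, 0.0, 1.43))]
        bonds = [(0, 1, Chem.BondType.SINGLE)]
    elif ftype == "HBA":  # formaldehyde-like carbonyl: O at center
        atoms = [("O", 0, c), ("C", 0, c + (0.0, 0.0, 1.22))]
        bonds = [(0, 1, Chem.BondType.DOUBLE)]
    elif ftype == "HYD":  # propane; carbon centroid = center
        atoms = [
            ("C", 0, c + (-1.26, 0.0, -0.30)),
            ("C", 0, c + (0.0, 0.0, 0.60)),
            ("C", 0, c + (1.26, 0.0, -0.30)),
        ]
        bonds = [(0, 1, Chem.BondType.SINGLE), (1, 2, Chem.BondType.SINGLE)]
    elif ftype == "NI":  # acetate; carboxylate-group centroid = center
        atoms = [
            ("C", 0, c + (0.0, 0.44, 0.0)),
            ("O", 0, c + (1.05, -0.22, 0.0)),
            ("O", -1, c + (-1.05, -0.22, 0.0)),
            ("C", 0, c + (0.0, 1.95, 0.0)),
        ]
        bonds = [
            (0, 1, Chem.BondType.DOUBLE),
            (0, 2, Chem.BondType.SINGLE),
            (0, 3, Chem.BondType.SINGLE),
        ]
    elif ftype == "PI":  # methylammonium: N+ at center
        atoms = [("N", 1, c), ("C", 0, c + (0.0, 0.0, 1.49))]
        bonds = [(0, 1, Chem.BondType.SINGLE)]
    elif ftype == "RA":  # benzene in the xy-plane, centroid = center
        r = 1.39
        atoms = [
            ("C", 0, c + (r * np.cos(a), r * np.sin(a), 0.0))
            for a in np.linspace(0, 2 * np.pi, 7)[:-1]
        ]
        bonds = [(i, (i + 1) % 6, Chem.BondType.AROMATIC) for i in range(6)]
    else:
        raise ValueError(f"unknown planted feature type {ftype!r}")
    return atoms, bonds


#: receptor partner group per planted type: (residue name, [(atom name, element)])
_PARTNERS = {
    "HBD": ("GLY", [("O", "O")]),
    "HBA": ("GLY", [("N", "N")]),
    "HYD": ("LEU", [("CG", "C"), ("CD1", "C"), ("CD2", "C")]),
    "RA": ("LEU", [("CG", "C"), ("CD1", "C"), ("CD2", "C")]),
    "NI": ("LYS", [("NZ", "N")]),
    "PI": ("ASP", [("OD1", "O")]),
}


def _partner_positions(n: int, center: np.ndarray, offset: float) -> list[np.ndarray]:
    """n points all at exactly `offset` from center, along near-x directions."""
    dirs = [np.array([1.0, 0.0, 0.0])]
    theta = np.deg2rad(7.0)
    dirs += [
        np.array([np.cos(theta), np.sin(theta), 0.0]),
        np.array([np.cos(theta), -np.sin(theta), 0.0]),
    ]
    return [center + offset * d for d in dirs[:n]]


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{20.00:6.2f}"
        f"          {element:>2s}"
    )


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Emit a minimal receptor PDB and ligand SDF with planted interactions."""
    planted = []
    for i, pf in enumerate(spec.planted):
        pos = pf.position if pf.position is not None else (10.0 * i, 0.0, 0.0)
        planted.append(PlantedFeature(pf.type, pf.partner_offset, tuple(pos)))

    # ligand
    mol = RWMol()
    conf_coords = []
    for pf in planted:
        atoms, bonds = _ligand_fragment(pf.type, np.array(pf.position))
        base = mol.GetNumAtoms()
        for sym, charge, xyz in atoms:
            a = Chem.Atom(sym)
            a.SetFormalCharge(charge)
            mol.AddAtom(a)
            conf_coords.append(np.asarray(xyz, dtype=float))
        for i, j, order in bonds:
            mol.AddBond(base + i, base + j, order)
            if order == Chem.BondType.AROMATIC:
                mol.GetBondBetweenAtoms(base + i, base + j).SetIsAromatic(True)
                mol.GetAtomWithIdx(base + i).SetIsAromatic(True)
                mol.GetAtomWithIdx(base + j).SetIsAromatic(True)
    ligand = mol.GetMol()
    Chem.SanitizeMol(ligand)
    conf = Chem.Conformer(ligand.GetNumAtoms())
    for idx, xyz in enumerate(conf_coords):
        conf.SetAtomPosition(idx, [float(x) for x in xyz])
    ligand.AddConformer(conf)
    sdf_text = Chem.MolToMolBlock(ligand) + "$$$$\n"

    # receptor
    lines = ["REMARK   2 RESOLUTION.    1.80 ANGSTROMS."]
    serial, resseq = 1, 1
    for pf in planted:
        resname, partner_atoms = _PARTNERS[pf.type]
        positions = _partner_positions(
            len(partner_atoms), np.array(pf.position), pf.partner_offset
        )
        for (aname, elem), xyz in zip(partner_atoms, positions):
            lines.append(_pdb_atom_line(serial, aname, resname, "A", resseq, xyz, elem))
            serial += 1
        resseq += 1
    rng = random.Random(spec.seed)
    for _ in range(spec.decoy_atom_count):
        xyz = np.array(
            [60.0 + rng.uniform(0, 20), rng.uniform(-10, 10), rng.uniform(-10, 10)]
        )
        lines.append(_pdb_atom_line(serial, "CA", "GLY", "B", resseq, xyz, "C"))
        serial += 1
        resseq += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    expected = [
        pf.type for pf in planted if pf.partner_offset <= _SURVIVAL_THRESHOLD[pf.type]
    ]
    return ToyComplex(pdb_text, sdf_text, expected, ToyComplexSpec(planted, spec.decoy_atom_count, spec.seed))


# ---------------------------------------------------------------------------
# SMILES libraries

# drug-like base scaffolds: modest size/lipophilicity so that decorating up
# to five aromatic CH positions with the substituents below keeps every
# variant inside the Lipinski + Veber rules (audited over the full
# enumeration; ~28k unique passing variants in total).
_DRUGLIKE_BASES = [
    "Cn1c(=O)c2ccccc2n(C)c1=O",
    "O=C1CCc2ccccc2N1",
    "CC(=O)Nc1ccccc1",
    "NC(=O)c1ccccc1",
    "O=S(=O)(N)c1ccccc1",
    "O=C(N1CCOCC1)c1ccccc1",
    "OCc1ccccc1",
    "NCc1ccccc1",
    "O=C(O)c1ccccc1",
    "Cn1cnc2ccccc21",
    "c1ccc(N2CCOCC2)cc1",
    "CN(C)C(=O)c1ccccc1",
    "CS(=O)(=O)c1ccccc1",
    "O=c1cc[nH]c2ccccc12",
    "Nc1ccccc1C(N)=O",
    "O=C1NC(=O)c2ccccc21",
    "O=C(N)Cc1ccccc1",
    "OC(=O)Cc1ccccc1",
    "O=C1CCCc2ccccc21",
]

_SUBSTITUENTS = ["", "F", "Cl", "C", "OC"]

_VIOLATOR_BASES = [
    "CCCCCCCCCCCCCCCCCCCC",  # logP and rotatable bonds
    "CCCCCCCCCCCCOC(=O)CCCCCCCCCCC",  # rotatable bonds, logP
    "OCC(O)C(O)C(O)C(O)C(O)C(O)CO",  # HBD, TPSA
    "COCCOCCOCCOCCOCCOCCOCCOCCOCCOC",  # HBA, rotatable bonds, TPSA
    "O=C(NCCCCCCCCCCCC)c1ccc(C(=O)NCCCCCCCCCCCC)cc1",  # MW, logP, rotors
    "NC(=O)C(N)CC(=O)NC(CO)C(=O)NC(CO)C(=O)NC(CO)C(=O)NC(CO)C(=O)O",  # MW, HBD, TPSA
]


def _aromatic_ch_positions(mol: Chem.Mol, max_positions: int = 5) -> list[int]:
    idxs = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() == 1
    ]
    if len(idxs) <= max_positions:
        return idxs
    step = len(idxs) / max_positions
    return [idxs[int(i * step)] for i in range(max_positions)]


def _attach(mol: RWMol, atom_idx: int, sub: str) -> None:
    """Graft a small substituent (F/Cl/methyl/ethyl/methoxy) onto an atom."""
    if sub == "":
        return
    chain = {"F": ["F"], "Cl": ["Cl"], "C": ["C"], "CC": ["C", "C"], "OC": ["O", "C"]}[sub]
    prev = atom_idx
    for sym in chain:
        new = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(prev, new, Chem.BondType.SINGLE)
        prev = new


def _decorate(base: Chem.Mol, positions: Sequence[int], subs: Sequence[str]) -> str | None:
    m = RWMol(base)
    for pos, sub in zip(positions, subs):
        _attach(m, pos, sub)
    out = m.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def make_library(n: int, seed: int = 0, fraction_rule_violators: float = 0.0) -> list[str]:
    """n unique SMILES: drug-like decorated scaffolds + rule violators.

    Exactly round(n * fraction_rule_violators) molecules violate at least one
    Lipinski/Veber rule; the rest satisfy all of them. Same seed, same list.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= fraction_rule_violators <= 1.0:
        raise ValueError("fraction_rule_violators must be in [0, 1]")
    n_viol = round(n * fraction_rule_violators)
    n_pass = n - n_viol
    rng = random.Random(seed)

    # passing pool: lazy enumeration of (base, substituent combo) in a
    # seeded shuffled order, deduplicated by canonical SMILES
    bases = [Chem.MolFromSmiles(s) for s in _DRUGLIKE_BASES]
    bases = [b for b in bases if b is not None]
    combos: list[tuple[int, tuple[str, ...]]] = []
    per_base_positions = []
    for bi, base in enumerate(bases):
        positions = _aromatic_ch_positions(base)
        per_base_positions.append(positions)
        for subs in itertools.product(_SUBSTITUENTS, repeat=len(positions)):
            combos.append((bi, subs))
    rng.shuffle(combos)

    passing: list[str] = []
    seen: set[str] = set()
    for bi, subs in combos:
        if len(passing) >= n_pass:
            break
        smi = _decorate(bases[bi], per_base_positions[bi], subs)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        passing.append(smi)
    if len(passing) < n_pass:
        raise ValueError(
            f"drug-like pool exhausted: {len(passing)} unique variants "
            f"available, {n_pass} requested"
        )

    violators: list[str] = []
    k = 0
    while len(violators) < n_viol:
        base = _VIOLATOR_BASES[k % len(_VIOLATOR_BASES)]
        smi = Chem.CanonSmiles(base + "C" * (k // len(_VIOLATOR_BASES)))
        if smi not in seen:
            seen.add(smi)
            violators.append(smi)
        k += 1

    out = passing + violators
    rng.shuffle(out)
    return out
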