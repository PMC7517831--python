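"""Complex-based pharmacophore generation and fit-value scoring.

A pharmacophore model is a small set of typed 3D interaction features
(hydrogen-bond acceptor/donor, hydrophobic, negative/positive ionizable,
aromatic ring) taken from the bound ligand of a receptor-ligand complex,
keeping only features that have a complementary partner on the receptor side
(an acceptor near a donor, an apolar patch near a hydrophobe, an opposite
charge near an ionizable group). Candidate models are all feature subsets of
at least `min_features` features; they are ranked by an empirical selectivity
score (how rarely a background library matches the model) and the top models
are retained.

A molecule's *fit value* against a model is the best weighted match over all
conformers and all type-compatible assignments of molecule features to the
model features: matched centers are superposed by least squares, each
feature's residual displacement d must stay within its tolerance t, and the
fit is sum(w * (1 - d/t)) — between 0 and sum(w).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .ensemble import Atom, ParsedStructure, kabsch
from .errors import ConfigurationError, InsufficientDataError
from .metrics import roc_auc

__all__ = [
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "FitResult",
    "load_feature_rules",
    "perceive_features",
    "featurize_molecule",
    "embed_smiles",
    "generate_models",
    "selectivity_score",
    "fit_value",
    "fit_molecule",
    "model_auc",
]

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("HBA", "HBD", "HYD", "NI", "PI", "RA")
#: one-letter codes used in model summaries (A = acceptor, D = donor, ...)
TYPE_LETTER = {"HBA": "A", "HBD": "D", "HYD": "H", "NI": "N", "PI": "P", "RA": "R"}

DEFAULT_TOLERANCE = 1.6  # Angstrom
#: receptor-complement distance cutoffs, Angstrom
DEFAULT_THRESHOLDS = {"hbond": 3.5, "hydrophobic": 4.5, "ionic": 5.5}
MAX_COMPLEMENTED = 12  # cap on features entering subset enumeration
MAX_MODEL_FEATURES = 8
_POLAR = {7, 8, 15, 16}

# residue/atom names carrying formal charge at physiological pH (receptor side)
_POSITIVE_RECEPTOR = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "CZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_NEGATIVE_RECEPTOR = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass
class PharmacophoreFeature:
    type: str
    center: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    weight: float = 1.0
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        self.center = np.asarray(self.center, dtype=float)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            self.direction = d / n if n > 0 else None


@dataclass
class PharmacophoreModel:
    model_id: str
    features: list[PharmacophoreFeature]
    selectivity_score: float = float("nan")
    auc: float | None = None
    source_complex: str = ""

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError("a pharmacophore model needs at least 3 features")

    @property
    def letter_code(self) -> str:
        return "".join(sorted(TYPE_LETTER[f.type] for f in self.features))

    @property
    def max_fit(self) -> float:
        return float(sum(f.weight for f in self.features))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "source_complex": self.source_complex,
            "selectivity_score": self.selectivity_score,
            "auc": self.auc,
            "letter_code": self.letter_code,
            "features": [
                {
                    "type": f.type,
                    "center": [round(float(x), 6) for x in f.center],
                    "tolerance": f.tolerance,
                    "weight": f.weight,
                }
                for f in self.features
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        feats = [
            PharmacophoreFeature(
                f["type"], np.array(f["center"]), f["tolerance"], f["weight"]
            )
            for f in d["features"]
        ]
        return cls(d["model_id"], feats, d.get("selectivity_score", float("nan")),
                   d.get("auc"), d.get("source_complex", ""))


@dataclass
class FitResult:
    compound_id: str
    model_id: str
    fit_value: float
    matched: bool
    mapping: tuple[int, ...] | None = None  # model-feature order -> molecule feature idx
    conformer: int | None = None


def load_feature_rules(path: str | Path | None = None) -> dict:
    """Load (and pre-compile) the SMARTS feature typing rules."""
    if path is None:
        text = resources.files("ensemble_vs").joinpath("data/feature_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    compiled: dict[str, dict[str, list]] = {"point_features": {}, "group_features": {}}
    for kind in ("point_features", "group_features"):
        for ftype, patterns in (raw.get(kind) or {}).items():
            pats = []
            for p in patterns:
                q = Chem.MolFromSmarts(p)
                if q is None:
                    raise ConfigurationError(f"invalid SMARTS for {ftype}: {p!r}")
                pats.append(q)
            compiled[kind][ftype] = pats
    return compiled


_DEFAULT_RULES: dict | None = None


def _rules(rules: dict | None) -> dict:
    global _DEFAULT_RULES
    if rules is not None:
        return rules
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_feature_rules()
    return _DEFAULT_RULES


def perceive_features(
    mol: Chem.Mol, conf_id: int = -1, rules: dict | None = None
) -> list[PharmacophoreFeature]:
    """Typed pharmacophoric features of one conformer of a molecule.

    HBD/HBA sit on the donor/acceptor heavy atom, NI/PI at the charged-group
    centroid, HYD at the centroid of each contiguous group of >= 2 apolar
    carbons, RA at each aromatic-ring centroid (with ring normal).
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    rules = _rules(rules)
    m = Chem.RemoveHs(mol)
    conf = m.GetConformer(conf_id)
    xyz = np.array(conf.GetPositions(), dtype=float)
    feats: list[PharmacophoreFeature] = []

    for ftype, patterns in rules["point_features"].items():
        atoms: set[int] = set()
        for q in patterns:
            for match in m.GetSubstructMatches(q):
                atoms.add(match[0])
        for idx in sorted(atoms):
            feats.append(PharmacophoreFeature(ftype, xyz[idx]))

    for ftype, patterns in rules["group_features"].items():
        groups: set[frozenset[int]] = set()
        for q in patterns:
            for match in m.GetSubstructMatches(q):
                groups.add(frozenset(match))
        # drop groups fully contained in a larger group of the same type
        keep = [g for g in groups if not any(g < h for h in groups)]
        for g in sorted(keep, key=lambda g: sorted(g)):
            feats.append(PharmacophoreFeature(ftype, xyz[list(sorted(g))].mean(axis=0)))

    # HYD: connected components of apolar carbons (no polar neighbour), size >= 2
    apolar = set()
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetFormalCharge() != 0:
            continue
        if any(nb.GetAtomicNum() in _POLAR for nb in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    seen: set[int] = set()
    for start in sorted(apolar):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            for nb in m.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetIdx() in apolar and nb.GetIdx() not in seen:
                    stack.append(nb.GetIdx())
        if len(comp) >= 2:
            feats.append(PharmacophoreFeature("HYD", xyz[sorted(comp)].mean(axis=0)))

    # RA: aromatic rings, centroid + plane normal
    for ring in m.GetRingInfo().AtomRings():
        if not all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        pts = xyz[list(ring)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        feats.append(PharmacophoreFeature("RA", centroid, direction=vt[2]))

    return feats


def featurize_molecule(
    mol: Chem.Mol, rules: dict | None = None
) -> list[list[PharmacophoreFeature]]:
    """Features of every conformer of a molecule (list per conformer)."""
    return [
        perceive_features(mol, conf.GetId(), rules) for conf in mol.GetConformers()
    ]


def embed_smiles(smiles: str, n_confs: int = 1, seed: int = 0) -> Chem.Mol:
    """Parse SMILES and embed seeded 3D conformer(s) (ETKDG)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if molh.GetNumConformers() == 0:
        raise ValueError(f"conformer embedding failed for {smiles!r}")
    return Chem.RemoveHs(molh)


# ---------------------------------------------------------------------------
# receptor complementarity


def _receptor_arrays(receptor: ParsedStructure | Sequence[Atom]) -> dict[str, np.ndarray]:
    atoms = receptor.atoms if isinstance(receptor, ParsedStructure) else list(receptor)
    heavy = [a for a in atoms if a.is_heavy]

    def arr(selected: list[Atom]) -> np.ndarray:
        return np.array([a.xyz for a in selected], dtype=float).reshape(-1, 3)

    # no hydrogens in typical PDB input: acceptors approximated by O atoms,
    # donors by N atoms (distance-only criterion)
    return {
        "acceptor": arr([a for a in heavy if a.element.upper() == "O"]),
        "donor": arr([a for a in heavy if a.element.upper() == "N"]),
        "apolar": arr([a for a in heavy if a.element.upper() in ("C", "S")]),
        "positive": arr([a for a in heavy if (a.residue_name, a.name) in _POSITIVE_RECEPTOR]),
        "negative": arr([a for a in heavy if (a.residue_name, a.name) in _NEGATIVE_RECEPTOR]),
    }


def _min_dist(point: np.ndarray, coords: np.ndarray) -> float:
    if coords.size == 0:
        return math.inf
    return float(np.sqrt(((coords - point) ** 2).sum(axis=1).min()))


def _complement_distance(
    feat: PharmacophoreFeature, rec: dict[str, np.ndarray], thresholds: Mapping[str, float]
) -> tuple[bool, float]:
    """Whether the receptor complements a ligand feature, and at what distance."""
    c = feat.center
    if feat.type == "HBD":
        d = _min_dist(c, rec["acceptor"])
        return d <= thresholds["hbond"], d
    if feat.type == "HBA":
        d = _min_dist(c, rec["donor"])
        return d <= thresholds["hbond"], d
    if feat.type in ("HYD", "RA"):
        if rec["apolar"].size == 0:
            return False, math.inf
        dists = np.sqrt(((rec["apolar"] - c) ** 2).sum(axis=1))
        within = int((dists <= thresholds["hydrophobic"]).sum())
        return within >= 3, float(np.sort(dists)[: min(3, len(dists))][-1])
    if feat.type == "NI":
        d = _min_dist(c, rec["positive"])
        return d <= thresholds["ionic"], d
    if feat.type == "PI":
        d = _min_dist(c, rec["negative"])
        return d <= thresholds["ionic"], d
    raise ValueError(feat.type)


def complemented_features(
    receptor: ParsedStructure | Sequence[Atom],
    ligand: Chem.Mol,
    thresholds: Mapping[str, float] | None = None,
    rules: dict | None = None,
) -> tuple[list[PharmacophoreFeature], list[tuple[PharmacophoreFeature, float]]]:
    """Ligand features that survive the receptor-complement filter.

    Returns (kept, rejected-with-distance).
    """
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    rec = _receptor_arrays(receptor)
    kept, rejected = [], []
    for feat in perceive_features(ligand, rules=rules):
        ok, dist = _complement_distance(feat, rec, thresholds)
        if ok:
            kept.append((feat, dist))
        else:
            rejected.append((feat, dist))
    if len(kept) > MAX_COMPLEMENTED:
        kept.sort(key=lambda fd: fd[1])
        logger.info(
            "capping complemented features at %d (had %d)", MAX_COMPLEMENTED, len(kept)
        )
        kept = kept[:MAX_COMPLEMENTED]
    return [f for f, _ in kept], rejected


def generate_models(
    receptor: ParsedStructure | Sequence[Atom],
    ligand: Chem.Mol,
    background: Sequence[Sequence[Sequence[PharmacophoreFeature]]],
    min_features: int = 3,
    top_m: int = 10,
    complex_id: str = "complex",
    thresholds: Mapping[str, float] | None = None,
    rules: dict | None = None,
) -> list[PharmacophoreModel]:
    """Enumerate, score and rank receptor-complemented pharmacophore models.

    All subsets of the complemented feature set with min_features..8 features
    are scored for selectivity against `background` (a list of molecules,
    each a list of per-conformer feature lists); the `top_m` models are
    returned ordered by decreasing selectivity, ties broken by fewer features
    then by letter code.
    """
    kept, rejected = complemented_features(receptor, ligand, thresholds, rules)
    if len(kept) < min_features:
        detail = ", ".join(
            f"{f.type}@{d:.1f}A" for f, d in rejected
        ) or "no ligand features perceived"
        raise InsufficientDataError(
            f"{complex_id}: only {len(kept)} receptor-complemented features "
            f"(need {min_features}); rejected: {detail}"
        )

    candidates: list[PharmacophoreModel] = []
    max_size = min(len(kept), MAX_MODEL_FEATURES)
    idx = 0
    for size in range(min_features, max_size + 1):
        for combo in itertools.combinations(range(len(kept)), size):
            model = PharmacophoreModel(
                model_id=f"{complex_id}_m{idx:03d}",
                features=[kept[i] for i in combo],
                source_complex=complex_id,
            )
            model.selectivity_score = selectivity_score(model, background)
            candidates.append(model)
            idx += 1

    candidates.sort(key=lambda m: (-m.selectivity_score, len(m.features), m.letter_code))
    return candidates[:top_m]


def selectivity_score(
    model: PharmacophoreModel,
    background: Sequence[Sequence[Sequence[PharmacophoreFeature]]],
    floor: float = 0.5,
) -> float:
    """Empirical rarity of a model in a background library.

    score = -log10(max(m, floor) / N), where m is the number of background
    molecules with fit_value > 0 and N the library size: 0 when every
    molecule matches, larger the rarer (more selective) the model is.
    """
    n = len(background)
    if n == 0:
        raise InsufficientDataError("background library is empty")
    m = sum(
        1 for mol_feats in background if fit_value(mol_feats, model).fit_value > 0
    )
    return float(-math.log10(max(m, floor) / n))


def _assignments(
    model: PharmacophoreModel, mol_feats: Sequence[PharmacophoreFeature]
):
    """Injective, type-compatible assignments model-feature -> molecule-feature."""
    by_type: dict[str, list[int]] = {}
    for i, f in enumerate(mol_feats):
        by_type.setdefault(f.type, []).append(i)
    slots: list[tuple[str, list[int]]] = []  # (type, model feature positions)
    type_positions: dict[str, list[int]] = {}
    for pos, f in enumerate(model.features):
        type_positions.setdefault(f.type, []).append(pos)
    per_type_perms = []
    for ftype, positions in type_positions.items():
        pool = by_type.get(ftype, [])
        if len(pool) < len(positions):
            return  # some model feature cannot be matched
        per_type_perms.append((positions, list(itertools.permutations(pool, len(positions)))))
    for chosen in itertools.product(*(perms for _, perms in per_type_perms)):
        mapping = [0] * len(model.features)
        for (positions, _), perm in zip(per_type_perms, chosen):
            for pos, mol_idx in zip(positions, perm):
                mapping[pos] = mol_idx
        yield tuple(mapping)


def fit_value(
    conformer_features: Sequence[Sequence[PharmacophoreFeature]],
    model: PharmacophoreModel,
    compound_id: str = "",
) -> FitResult:
    """Best fit of a molecule (given per-conformer features) to a model.

    For every conformer and every type-compatible injective assignment of
    molecule features to ALL model features, the matched centers are
    superposed (least squares); the assignment is valid iff every residual
    displacement d_f stays within the feature tolerance, and its fit is
    sum(w_f * (1 - d_f / t_f)). The maximum over valid assignments is
    returned; with no valid assignment, matched=False and fit 0.
    """
    if len(model.features) > MAX_MODEL_FEATURES:
        raise ValueError(f"model exceeds {MAX_MODEL_FEATURES} features")
    ref = np.array([f.center for f in model.features])
    tols = np.array([f.tolerance for f in model.features])
    weights = np.array([f.weight for f in model.features])

    best = FitResult(compound_id, model.model_id, 0.0, False)
    for ci, mol_feats in enumerate(conformer_features):
        for mapping in _assignments(model, mol_feats) or ():
            mov = np.array([mol_feats[i].center for i in mapping])
            R, t, _ = kabsch(ref, mov)
            d = np.sqrt((((mov @ R.T + t) - ref) ** 2).sum(axis=1))
            if np.any(d > tols + 1e-9):
                continue
            fit = float(np.clip((weights * (1.0 - d / tols)).sum(), 0.0, None))
            if not best.matched or fit > best.fit_value:
                best = FitResult(compound_id, model.model_id, fit, True, mapping, ci)
    return best


def fit_molecule(
    mol: Chem.Mol, model: PharmacophoreModel, compound_id: str = "",
    rules: dict | None = None,
) -> FitResult:
    """Convenience wrapper: perceive features of every conformer, then fit."""
    return fit_value(featurize_molecule(mol, rules), model, compound_id)


def model_auc(
    model: PharmacophoreModel,
    molecules: Sequence[Sequence[Sequence[PharmacophoreFeature]]],
    labels: Sequence[int],
    acceptable_threshold: float = 0.7,
) -> float:
    """AUC of the model's fit value for separating actives from decoys.

    Sets model.auc; a model is flagged acceptable when AUC exceeds the
    threshold (default 0.7).
    """
    fits = [fit_value(m, model).fit_value for m in molecules]
    res = roc_auc(fits, labels)
    model.auc = res.auc
    return res.auc
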