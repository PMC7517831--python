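"""Binding-site ensemble clustering.

Given an ensemble of crystal structures of one protein, each bound to a
ligand, this module extracts the binding site around each ligand (all
residues with a heavy atom within a cutoff of any ligand heavy atom),
superposes sites pairwise by least squares on shared Calpha atoms, builds a
UPGMA tree from the resulting RMSD matrix, and selects one representative
structure per cluster (the one with the best crystallographic resolution).

The ensemble members are assumed to be the *same* protein, so residue
correspondence is by residue key (chain, residue number) intersection and no
sequence alignment is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, EmptySiteError, GeometryError

__all__ = [
    "Atom",
    "ParsedStructure",
    "BindingSite",
    "SuperpositionResult",
    "DistanceMatrix",
    "ClusterTree",
    "parse_pdb",
    "extract_binding_site",
    "kabsch",
    "superpose",
    "rmsd_matrix",
    "upgma_tree",
    "select_representatives",
]

_WATER = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    xyz: tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.residue_number)


@dataclass
class ParsedStructure:
    """One complex: protein atoms, the designated bound ligand, resolution (A)."""

    structure_id: str
    atoms: list[Atom]
    ligand_atoms: list[Atom]
    resolution: float | None = None

    def __post_init__(self) -> None:
        for a in list(self.atoms) + list(self.ligand_atoms):
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinate in {self.structure_id}: {a}")


@dataclass
class BindingSite:
    """Residues of one structure within the extraction radius of its ligand."""

    structure_id: str
    residues: list[tuple[str, int]]
    ca_coords: np.ndarray  # (n, 3), ordered like `residues` (NaN row if no CA)
    all_atom_coords: np.ndarray | None = None

    def ca_map(self) -> dict[tuple[str, int], np.ndarray]:
        """Residue key -> Calpha coordinate, skipping residues without a CA."""
        out = {}
        for key, xyz in zip(self.residues, self.ca_coords):
            if np.all(np.isfinite(xyz)):
                out[key] = xyz
        return out


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_points: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                fh.write(sid + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]) + "\n")


class ClusterTree:
    """UPGMA tree over structure ids.

    Wraps a scipy linkage matrix; node heights are merge-distance / 2, the
    ultrametric convention (two leaves separated by d merge at height d/2).
    """

    def __init__(self, linkage_matrix: np.ndarray, ids: Sequence[str]):
        self.Z = np.asarray(linkage_matrix, dtype=float)
        self.ids = list(ids)
        if self.Z.shape[0] != len(self.ids) - 1:
            raise ValueError("linkage size does not match leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def merge_heights(self) -> np.ndarray:
        """Heights (merge distance / 2) of internal nodes, root-ward order."""
        return self.Z[:, 2] / 2.0

    def cut(self, k: int) -> dict[str, int]:
        """Partition leaves into exactly k clusters at the lowest sufficient cut."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}], got {k}")
        labels = cut_tree(self.Z, n_clusters=k).ravel()
        return dict(zip(self.ids, labels.tolist()))

    def newick(self) -> str:
        import scipy.cluster.hierarchy as sch

        root = sch.to_tree(self.Z)

        def walk(node, parent_height):
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6f}"
            left = walk(node.left, height)
            right = walk(node.right, height)
            return f"({left},{right}):{length:.6f}"

        height = root.dist / 2.0
        left = walk(root.left, height)
        right = walk(root.right, height)
        return f"({left},{right});"


def parse_pdb(
    path: str | Path,
    structure_id: str | None = None,
    ligand_code: str | None = None,
    ligand_chain: str | None = None,
    resolution: float | None = None,
) -> ParsedStructure:
    """Read a PDB file into a ParsedStructure.

    Alternate conformations: altloc 'A' (or blank) is kept. The ligand is the
    het-group whose residue name equals ``ligand_code`` (optionally restricted
    to ``ligand_chain``); waters are never ligands. Resolution is taken from
    the header unless overridden.
    """
    st = gemmi.read_structure(str(path))
    sid = structure_id or st.name or Path(path).stem
    res = resolution
    if res is None and st.resolution and st.resolution > 0:
        res = float(st.resolution)

    protein: list[Atom] = []
    ligand: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            rname = residue.name.strip()
            if rname in _WATER:
                continue
            is_ligand = (
                ligand_code is not None
                and rname == ligand_code
                and (ligand_chain is None or chain.name == ligand_chain)
            )
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                rec = Atom(
                    name=atom.name,
                    element=atom.element.name,
                    residue_number=residue.seqid.num,
                    residue_name=rname,
                    chain=chain.name,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                (ligand if is_ligand else protein).append(rec)

    if ligand_code is not None and not ligand:
        raise ConfigurationError(
            f"{sid}: designated ligand {ligand_code!r} not found in {path}"
        )
    return ParsedStructure(sid, protein, ligand, res)


def extract_binding_site(structure: ParsedStructure, radius: float = 10.0) -> BindingSite:
    """Residues with any heavy atom within `radius` A of any ligand heavy atom.

    Hydrogens are ignored on both sides of the distance test.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not structure.ligand_atoms:
        raise ConfigurationError(f"{structure.structure_id}: no ligand designated")

    lig = np.array([a.xyz for a in structure.ligand_atoms if a.is_heavy])
    if lig.size == 0:
        raise ConfigurationError(f"{structure.structure_id}: ligand has no heavy atoms")

    heavy = [a for a in structure.atoms if a.is_heavy]
    coords = np.array([a.xyz for a in heavy]).reshape(-1, 3)
    # nearest ligand heavy atom per protein heavy atom
    d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
    near = d2.min(axis=1) <= radius * radius

    included: set[tuple[str, int]] = {a.residue_key for a, hit in zip(heavy, near) if hit}
    if not included:
        raise EmptySiteError(
            f"{structure.structure_id}: no residue within {radius} A of the ligand"
        )

    keys = sorted(included)
    ca = np.full((len(keys), 3), np.nan)
    all_coords = []
    by_key: dict[tuple[str, int], int] = {k: i for i, k in enumerate(keys)}
    for a in structure.atoms:
        k = a.residue_key
        if k not in by_key:
            continue
        if a.is_heavy:
            all_coords.append(a.xyz)
        if a.name == "CA" and a.is_heavy:
            ca[by_key[k]] = a.xyz
    return BindingSite(structure.structure_id, keys, ca, np.array(all_coords))


def kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping `mov` onto `ref`.

    Returns (R, t, rmsd) with x' = R x + t and det(R) = +1 (reflections are
    excluded by flipping the sign of the smallest singular vector).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError(f"point sets must both be (n, 3); got {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")

    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    H = (mov - cmov).T @ (ref - cref)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cref - R @ cmov
    diff = (mov @ R.T + t) - ref
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def superpose(ref: np.ndarray, mov: np.ndarray) -> SuperpositionResult:
    """Kabsch superposition of `mov` onto `ref` (proper rotation only)."""
    R, t, rmsd = kabsch(ref, mov)
    return SuperpositionResult(R, t, rmsd, int(np.asarray(ref).shape[0]))


def rmsd_matrix(sites: Sequence[BindingSite], min_shared: int = 3) -> DistanceMatrix:
    """Pairwise Calpha superposition RMSD over shared residue keys."""
    if len(sites) < 2:
        raise ValueError("need at least two binding sites")
    maps = [s.ca_map() for s in sites]
    ids = [s.structure_id for s in sites]
    n = len(sites)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(maps[i]) & set(maps[j]))
            if len(shared) < min_shared:
                raise GeometryError(
                    f"sites {ids[i]} and {ids[j]} share only {len(shared)} residues "
                    f"(minimum {min_shared})"
                )
            a = np.array([maps[i][k] for k in shared])
            b = np.array([maps[j][k] for k in shared])
            values[i, j] = values[j, i] = superpose(a, b).rmsd
    return DistanceMatrix(ids, values)


def upgma_tree(matrix: DistanceMatrix) -> ClusterTree:
    """Average-linkage (UPGMA) agglomeration of the RMSD matrix."""
    Z = linkage(squareform(matrix.values, checks=True), method="average")
    return ClusterTree(Z, matrix.ids)


def select_representatives(
    tree: ClusterTree,
    k: int,
    resolutions: Mapping[str, float],
) -> list[dict]:
    """Cut the tree into k clusters; return the best-resolution id per cluster.

    Resolution ties are broken by lexicographic structure id. Output is ordered
    by cluster label (order of first leaf appearance in the id list).
    """
    missing = [sid for sid in tree.ids if sid not in resolutions]
    if missing:
        raise ConfigurationError(f"missing resolution for structures: {missing}")
    labels = tree.cut(k)
    clusters: dict[int, list[str]] = {}
    for sid in tree.ids:
        clusters.setdefault(labels[sid], []).append(sid)
    out = []
    for label in sorted(clusters):
        members = clusters[label]
        best = min(members, key=lambda s: (resolutions[s], s))
        out.append(
            {
                "structure_id": best,
                "cluster": int(label),
                "resolution": float(resolutions[best]),
                "cluster_size": len(members),
            }
        )
    return out


def representatives_to_json(reps: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(list(reps), fh, indent=2)
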