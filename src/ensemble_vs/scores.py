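"""Docking-score ingestion and validation.

Docking itself is out of scope: any engine's per-structure score tables are
ingested into a compounds x (structure, mode) matrix. Two validation metrics
are implemented:

* scoring power — can the protocol reproduce the crystallographic ligand
  pose? Measured by re-dock heavy-atom RMSD against a pass threshold
  (default 2.0 A, inclusive), with optional graph-automorphism symmetry
  correction so that e.g. a flipped benzene ring scores 0.
* screening power — does the score separate actives from decoys? Measured
  by a two-sided Welch t-test on the two score distributions.

Scores are free energies in kcal/mol: lower is better throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "ScoreMatrix",
    "PoseComparison",
    "ScreeningPowerResult",
    "load_scores",
    "pose_rmsd",
    "scoring_power",
    "screening_power",
    "choose_mode",
]

logger = logging.getLogger(__name__)

MODES = ("SP", "XP")


@dataclass
class ScoreMatrix:
    """Compounds x (structure_id, mode) docking scores; NaN marks missing."""

    df: pd.DataFrame  # index: compound_id; columns: MultiIndex (structure, mode)

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate (structure, mode) columns")

    @property
    def compounds(self) -> list[str]:
        return list(self.df.index)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(self.df.columns)

    def column(self, structure_id: str, mode: str) -> pd.Series:
        return self.df[(structure_id, mode)]


def load_scores(
    paths: Mapping[tuple[str, str], str | Path] | None = None,
    frames: Mapping[tuple[str, str], pd.DataFrame] | None = None,
    id_col: str = "compound_id",
    score_col: str = "score",
    sep: str | None = None,
) -> ScoreMatrix:
    """Merge per-(structure, mode) score tables into one ScoreMatrix.

    Each table needs `id_col` and `score_col` columns. Duplicate compound
    entries within one table keep the better (lower) score; the number of
    such collisions is logged. Compounds absent from a table get NaN in
    that column.
    """
    if (paths is None) == (frames is None):
        raise ValueError("provide exactly one of paths= or frames=")
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    if paths is not None:
        for key, p in paths.items():
            p = Path(p)
            use_sep = sep if sep is not None else ("\t" if p.suffix in (".tsv", ".tab") else ",")
            tables[key] = pd.read_csv(p, sep=use_sep)
    else:
        tables = {k: v.copy() for k, v in frames.items()}

    series = {}
    for (structure, mode), tab in tables.items():
        if id_col not in tab.columns or score_col not in tab.columns:
            raise ValueError(f"table for {(structure, mode)} lacks {id_col}/{score_col}")
        tab[id_col] = tab[id_col].astype(str)
        n_dup = int(tab[id_col].duplicated().sum())
        if n_dup:
            logger.info(
                "%s/%s: %d duplicate compound entries resolved by keeping the lower score",
                structure, mode, n_dup,
            )
        s = tab.groupby(id_col)[score_col].min()
        series[(structure, mode)] = s
    df = pd.DataFrame(series)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["structure", "mode"])
    df.index.name = "compound_id"
    return ScoreMatrix(df.sort_index())


@dataclass
class PoseComparison:
    rmsd: float
    mapping_used: tuple[int, ...]
    symmetry_corrected: bool


def _heavy_conf_coords(mol: Chem.Mol) -> tuple[Chem.Mol, np.ndarray]:
    m = Chem.RemoveHs(mol)
    conf = m.GetConformer()
    return m, np.array(conf.GetPositions(), dtype=float)


def pose_rmsd(ref_pose: Chem.Mol, test_pose: Chem.Mol, symmetry: bool = True) -> PoseComparison:
    """Heavy-atom RMSD between two poses of the same molecule, no re-fitting.

    Both poses must already sit in the same (receptor) frame. With
    symmetry=True the RMSD is minimised over the molecular graph's
    automorphisms (element-preserving self-matches), so topologically
    equivalent atoms may swap.
    """
    ref, xyz_ref = _heavy_conf_coords(ref_pose)
    test, xyz_test = _heavy_conf_coords(test_pose)
    if ref.GetNumAtoms() != test.GetNumAtoms():
        raise ValueError(
            f"atom count mismatch: {ref.GetNumAtoms()} vs {test.GetNumAtoms()}"
        )
    ref_elems = sorted(a.GetSymbol() for a in ref.GetAtoms())
    test_elems = sorted(a.GetSymbol() for a in test.GetAtoms())
    if ref_elems != test_elems:
        raise ValueError("heavy-atom element multisets differ; not the same molecule")

    n = ref.GetNumAtoms()
    identity = tuple(range(n))

    def rms(mapping: Sequence[int]) -> float:
        diff = xyz_ref[list(mapping)] - xyz_test
        return float(np.sqrt((diff**2).sum() / n))

    if not symmetry:
        return PoseComparison(rms(identity), identity, False)

    matches = ref.GetSubstructMatches(ref, uniquify=False, useChirality=False, maxMatches=10000)
    if not matches:
        matches = [identity]
    best = min(matches, key=rms)
    return PoseComparison(rms(best), tuple(best), True)


def scoring_power(
    comparisons: Mapping[str, PoseComparison] | Mapping[str, float],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-structure re-dock pass/fail (rmsd <= threshold, inclusive) + summary.

    Returns a DataFrame indexed by structure with columns rmsd / passed; the
    overall pass fraction is in `df.attrs["fraction_passed"]`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not comparisons:
        raise InsufficientDataError("no pose comparisons supplied")
    rows = {}
    for key, comp in comparisons.items():
        rmsd = comp.rmsd if isinstance(comp, PoseComparison) else float(comp)
        rows[key] = {"rmsd": rmsd, "passed": rmsd <= threshold}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["fraction_passed"] = float(df["passed"].mean())
    df.attrs["threshold"] = threshold
    return df


@dataclass
class ScreeningPowerResult:
    structure_id: str
    mode: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_active: float
    mean_decoy: float
    n_active: int
    n_decoy: int


def screening_power(
    scores_active,
    scores_decoy,
    structure_id: str = "",
    mode: str = "",
) -> ScreeningPowerResult:
    """Two-sided Welch t-test between active and decoy score distributions.

    Missing (NaN) scores are excluded with a logged count. Two groups with
    zero variance and identical means give t = 0, p = 1 with a warning.
    """
    a = np.asarray(scores_active, dtype=float)
    d = np.asarray(scores_decoy, dtype=float)
    n_drop = int(np.isnan(a).sum() + np.isnan(d).sum())
    if n_drop:
        logger.info("screening_power %s/%s: excluded %d missing scores", structure_id, mode, n_drop)
    a = a[~np.isnan(a)]
    d = d[~np.isnan(d)]
    if len(a) < 2 or len(d) < 2:
        raise InsufficientDataError("each group needs at least 2 finite scores")

    if a.var(ddof=1) == 0 and d.var(ddof=1) == 0:
        if a.mean() == d.mean():
            warnings.warn("both groups constant and equal; t-test degenerate (p = 1)")
            return ScreeningPowerResult(
                structure_id, mode, 0.0, float(len(a) + len(d) - 2), 1.0,
                float(a.mean()), float(d.mean()), len(a), len(d),
            )
        warnings.warn("both groups constant but different; reporting p = 0")
        t = np.inf if a.mean() > d.mean() else -np.inf
        return ScreeningPowerResult(
            structure_id, mode, float(t), float(len(a) + len(d) - 2), 0.0,
            float(a.mean()), float(d.mean()), len(a), len(d),
        )

    res = stats.ttest_ind(a, d, equal_var=False)
    return ScreeningPowerResult(
        structure_id, mode,
        float(res.statistic), float(res.df), float(res.pvalue),
        float(a.mean()), float(d.mean()), len(a), len(d),
    )


def choose_mode(
    results: Mapping[str, Mapping[str, ScreeningPowerResult]],
    prefer: str = "smaller_p",
) -> dict[str, str]:
    """Pick one docking precision mode (SP or XP) per structure.

    The default keeps the mode with the *stronger* active/decoy separation,
    i.e. the smaller t-test p-value; ties go to XP. `prefer="larger_p"`
    implements the literal larger-p reading instead.
    """
    if prefer not in ("smaller_p", "larger_p"):
        raise ValueError("prefer must be 'smaller_p' or 'larger_p'")
    chosen: dict[str, str] = {}
    for structure, per_mode in results.items():
        present = {m: r for m, r in per_mode.items() if r is not None}
        if not present:
            raise InsufficientDataError(f"no screening-power result for {structure}")
        if len(present) == 1:
            (mode,) = present
            warnings.warn(f"{structure}: only mode {mode} available; using it")
            chosen[structure] = mode
            continue
        ps = {m: present[m].p_value for m in present}
        if ps.get("SP") == ps.get("XP"):
            chosen[structure] = "XP"
        elif prefer == "smaller_p":
            chosen[structure] = min(ps, key=lambda m: (ps[m], m != "XP"))
        else:
            chosen[structure] = max(ps, key=lambda m: (ps[m], m == "XP"))
    return chosen
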