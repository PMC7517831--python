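"""Validation-set construction: actives plus diversity-selected decoys.

Screening scorers are validated against a labeled benchmark of known actives
and presumed-inactive decoys drawn from a large vendor-style library at a
fixed decoy:active ratio (default 20:1). Decoys are chosen by MaxMin
diversity picking on 2048-bit Morgan fingerprints (radius 2) with Tanimoto
distance, after removing any compound whose canonical structure coincides
with an active (label leakage guard).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.SimDivFilters import rdSimDivPickers

from .errors import InsufficientDataError

__all__ = [
    "CompoundRecord",
    "ValidationSet",
    "deduplicate",
    "diverse_select",
    "build_validation_set",
]

logger = logging.getLogger(__name__)

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class CompoundRecord:
    compound_id: str
    smiles: str
    label: int | None = None  # 1 = inhibitor, 0 = non-inhibitor, None = unknown
    activity: float | None = None
    activity_units: str | None = None

    def canonical_smiles(self) -> str | None:
        mol = Chem.MolFromSmiles(self.smiles)
        return None if mol is None else Chem.MolToSmiles(mol)


@dataclass
class ValidationSet:
    actives: list[CompoundRecord]
    decoys: list[CompoundRecord]
    ratio: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.decoys) != self.ratio * len(self.actives):
            raise ValueError(
                f"decoy count {len(self.decoys)} != ratio {self.ratio} x "
                f"active count {len(self.actives)}"
            )

    @property
    def records(self) -> list[CompoundRecord]:
        return list(self.actives) + list(self.decoys)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"compound_id": r.compound_id, "smiles": r.smiles, "label": r.label}
                for r in self.records
            ]
        )


def deduplicate(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """One record per canonical structure; the earliest id wins.

    Unparseable structures are logged and dropped.
    """
    seen: dict[str, CompoundRecord] = {}
    dropped = 0
    for rec in records:
        can = rec.canonical_smiles()
        if can is None:
            dropped += 1
            logger.warning("dropping unparseable SMILES %r (%s)", rec.smiles, rec.compound_id)
            continue
        if can not in seen:
            seen[can] = rec
    if dropped:
        logger.info("deduplicate: dropped %d unparseable records", dropped)
    return list(seen.values())


def _fingerprints(records: Sequence[CompoundRecord]):
    fps = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {rec.compound_id}: {rec.smiles!r}")
        fps.append(_FP_GEN.GetFingerprint(mol))
    return fps


def diverse_select(
    library: Sequence[CompoundRecord], n: int, seed: int
) -> list[CompoundRecord]:
    """MaxMin diversity pick of n compounds (Tanimoto distance on Morgan bits).

    The first pick is drawn uniformly by a RNG seeded with `seed`; every later
    pick maximises the minimum distance to the already-picked set. Output order
    is pick order.
    """
    if n > len(library):
        raise InsufficientDataError(
            f"requested {n} compounds from a library of {len(library)}"
        )
    if n == 0:
        return []
    if n == len(library):
        return list(library)
    fps = _fingerprints(library)
    first = random.Random(seed).randrange(len(library))
    picker = rdSimDivPickers.MaxMinPicker()
    picks = picker.LazyBitVectorPick(fps, len(fps), n, firstPicks=[first])
    return [library[i] for i in picks]


def build_validation_set(
    actives: Sequence[CompoundRecord],
    library: Sequence[CompoundRecord],
    ratio: int = 20,
    seed: int = 0,
) -> ValidationSet:
    """Assemble the labeled benchmark: actives + ratio x len(actives) decoys.

    Actives are deduplicated by canonical structure; library compounds whose
    canonical structure matches an active are excluded before diversity
    selection.
    """
    uniq_actives = deduplicate(actives)
    active_structures = {r.canonical_smiles() for r in uniq_actives}

    candidates = []
    for rec in deduplicate(library):
        if rec.canonical_smiles() not in active_structures:
            candidates.append(rec)

    n_decoys = ratio * len(uniq_actives)
    if n_decoys > len(candidates):
        raise InsufficientDataError(
            f"library supplies only {len(candidates)} candidate decoys; "
            f"{n_decoys} required (shortfall {n_decoys - len(candidates)})"
        )
    decoys = diverse_select(candidates, n_decoys, seed)

    labeled_actives = [
        CompoundRecord(r.compound_id, r.smiles, 1, r.activity, r.activity_units)
        for r in uniq_actives
    ]
    labeled_decoys = [CompoundRecord(r.compound_id, r.smiles, 0) for r in decoys]
    return ValidationSet(labeled_actives, labeled_decoys, ratio, seed)
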