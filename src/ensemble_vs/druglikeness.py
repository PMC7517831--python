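"""Lipinski and Veber drug-likeness filtering.

Lipinski: MW <= 500, logP <= 5, H-bond donors <= 5, H-bond acceptors <= 10.
Veber: rotatable bonds <= 10, TPSA <= 140 A^2.

The strict default allows zero Lipinski violations; `allow_one_violation`
switches to the common one-violation tolerance. logP is Crippen's
atom-contribution estimate; descriptor provenance is recorded in the report
attrs because absolute logP differs between estimators.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = ["RULES", "lipinski_veber_filter"]

RULES = {
    "mw": 500.0,
    "logp": 5.0,
    "hbd": 5,
    "hba": 10,
    "rotatable_bonds": 10,
    "tpsa": 140.0,
}


def _descriptors(mol: Chem.Mol) -> dict[str, float]:
    return {
        "mw": Descriptors.MolWt(mol),
        "logp": Crippen.MolLogP(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
    }


def lipinski_veber_filter(
    molecules: Sequence[tuple[str, str]] | Iterable[tuple[str, str]],
    allow_one_violation: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the Lipinski + Veber rules to (compound_id, smiles) pairs.

    Returns (ids passing, per-molecule report with descriptor values and
    per-rule pass flags). Unparseable structures are reported with
    parseable=False and excluded from the pass list.
    """
    rows = []
    passing: list[str] = []
    for cid, smiles in molecules:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rows.append({"compound_id": cid, "parseable": False, "passed": False})
            continue
        d = _descriptors(mol)
        flags = {
            "ok_mw": d["mw"] <= RULES["mw"],
            "ok_logp": d["logp"] <= RULES["logp"],
            "ok_hbd": d["hbd"] <= RULES["hbd"],
            "ok_hba": d["hba"] <= RULES["hba"],
            "ok_rotatable_bonds": d["rotatable_bonds"] <= RULES["rotatable_bonds"],
            "ok_tpsa": d["tpsa"] <= RULES["tpsa"],
        }
        lipinski_violations = sum(
            not flags[k] for k in ("ok_mw", "ok_logp", "ok_hbd", "ok_hba")
        )
        veber_ok = flags["ok_rotatable_bonds"] and flags["ok_tpsa"]
        lipinski_ok = lipinski_violations <= (1 if allow_one_violation else 0)
        passed = lipinski_ok and veber_ok
        rows.append(
            {"compound_id": cid, "parseable": True, **d, **flags,
             "lipinski_violations": lipinski_violations, "passed": passed}
        )
        if passed:
            passing.append(cid)
    report = pd.DataFrame(rows).set_index("compound_id")
    report.attrs["logp_estimator"] = "rdkit.Crippen.MolLogP"
    report.attrs["allow_one_violation"] = allow_one_violation
    return passing, report
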