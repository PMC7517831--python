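"""Tiered virtual-screening funnel.

Stage 1 keeps the n1 compounds with the best aggregated docking score
(lower is better), stage 2 the n2 of those with the best pharmacophore fit
value (higher is better), stage 3 the n3 of those with the best naive-Bayes
consensus score (higher is better), and stage 4 removes stage-3 survivors
failing the Lipinski/Veber drug-likeness rules. All ranking is
deterministic: ties are broken by lexicographic compound id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import BayesianFusionResults
from .druglikeness import lipinski_veber_filter
from .errors import InsufficientDataError

__all__ = ["FunnelConfig", "StageResult", "FunnelResult", "top_n", "aggregate_docking", "run_funnel"]

logger = logging.getLogger(__name__)


@dataclass
class FunnelConfig:
    n1: int = 10_000  # docking-rank survivors
    n2: int = 2_000  # fit-rank survivors
    n3: int = 100  # NB-rank survivors
    docking_aggregation: str = "best"  # best | mean | rank-sum
    fit_aggregation: str = "best"  # best | mean
    allow_one_lipinski_violation: bool = False
    apply_druglikeness: bool = True

    def __post_init__(self) -> None:
        if not (self.n1 >= self.n2 >= self.n3 > 0):
            raise ValueError("stage sizes must satisfy n1 >= n2 >= n3 > 0")
        if self.docking_aggregation not in ("best", "mean", "rank-sum"):
            raise ValueError(f"unknown docking aggregation {self.docking_aggregation!r}")
        if self.fit_aggregation not in ("best", "mean"):
            raise ValueError(f"unknown fit aggregation {self.fit_aggregation!r}")


@dataclass
class StageResult:
    name: str
    survivors: list[str]
    scores: pd.Series  # ranking score of every candidate entering the stage
    cut_score: float | None


@dataclass
class FunnelResult:
    stages: list[StageResult]
    final_ranked: pd.DataFrame  # index compound_id, column nb_score, rank order
    filter_report: pd.DataFrame | None
    config: FunnelConfig

    def survivors(self, stage: str) -> list[str]:
        for s in self.stages:
            if s.name == stage:
                return s.survivors
        raise KeyError(stage)


def top_n(scores: pd.Series, n: int, direction: str = "lower") -> list[str]:
    """Best-n ids by score; ties broken by lexicographic compound id.

    direction "lower" = smaller score better (docking), "higher" = larger
    better (fit, NB). Requesting more than available returns everything with
    a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    s = scores.dropna()
    if n >= len(s):
        if n > len(s):
            warnings.warn(f"requested top {n} of only {len(s)} scored compounds")
        n = len(s)
    key = s if direction == "lower" else -s
    order = pd.DataFrame({"key": key, "id": key.index.astype(str)}).sort_values(
        ["key", "id"], kind="mergesort"
    )
    return order["id"].head(n).tolist()


def aggregate_docking(matrix: pd.DataFrame, rule: str = "best") -> pd.Series:
    """Collapse the compounds x structures docking table to one score each.

    best = minimum over structures (the paper-style "best docking score"),
    mean = mean of non-missing, rank-sum = sum of per-column ascending ranks
    (missing cells contribute nothing). Compounds with every score missing
    are excluded with a log message. Lower aggregate is always better.
    """
    if rule not in ("best", "mean", "rank-sum"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        logger.info("aggregate_docking: excluding %d compounds with no score", int(all_missing.sum()))
        matrix = matrix.loc[~all_missing]
    if rule == "best":
        return matrix.min(axis=1)
    if rule == "mean":
        return matrix.mean(axis=1)
    ranks = matrix.rank(axis=0, method="average", na_option="keep")
    return ranks.sum(axis=1, skipna=True)


def run_funnel(
    docking: pd.DataFrame,
    fit_values: pd.DataFrame,
    nb_results: BayesianFusionResults,
    smiles: Mapping[str, str] | None = None,
    config: FunnelConfig | None = None,
) -> FunnelResult:
    """Execute the four screening stages.

    `docking`: compounds x structure columns (kcal/mol, lower better);
    `fit_values`: compounds x pharmacophore-model columns (higher better);
    `nb_results`: a trained consensus re-scorer whose columns are drawn from
    the docking and fit columns; `smiles` maps compound id -> structure for
    the drug-likeness stage (required unless config.apply_druglikeness is
    False).
    """
    config = config or FunnelConfig()
    docking = docking.copy()
    docking.index = docking.index.astype(str)
    fit_values = fit_values.copy()
    fit_values.index = fit_values.index.astype(str)

    # stage 1: aggregated docking rank
    agg = aggregate_docking(docking, config.docking_aggregation)
    stage1 = top_n(agg, config.n1, direction="lower")
    if not stage1:
        raise InsufficientDataError("stage 1 produced no survivors")
    s1 = StageResult("docking", stage1, agg, float(agg.loc[stage1].max()))
    logger.info("stage 1 (docking, %s): %d -> %d survivors, cut %.3f",
                config.docking_aggregation, len(agg), len(stage1), s1.cut_score)

    # stage 2: pharmacophore fit rank within stage-1 survivors
    fit_sub = fit_values.reindex(stage1)
    fit_score = fit_sub.max(axis=1) if config.fit_aggregation == "best" else fit_sub.mean(axis=1)
    fit_score = fit_score.fillna(0.0)  # no fit table entry = no match
    stage2 = top_n(fit_score, config.n2, direction="higher")
    if not stage2:
        raise InsufficientDataError("stage 2 produced no survivors")
    s2 = StageResult("pharmacophore", stage2, fit_score, float(fit_score.loc[stage2].min()))
    logger.info("stage 2 (fit): %d -> %d survivors", len(stage1), len(stage2))

    # stage 3: NB consensus rank within stage-2 survivors
    rows = pd.concat(
        [docking.reindex(stage2).add_prefix("dock:") if not str(docking.columns[0]).startswith("dock:") else docking.reindex(stage2),
         fit_values.reindex(stage2).add_prefix("fit:") if not str(fit_values.columns[0]).startswith("fit:") else fit_values.reindex(stage2)],
        axis=1,
    )
    nb_scores = nb_results.score(rows[nb_results.columns])
    stage3 = top_n(nb_scores, config.n3, direction="higher")
    if not stage3:
        raise InsufficientDataError("stage 3 produced no survivors")
    s3 = StageResult("bayes", stage3, nb_scores, float(nb_scores.loc[stage3].min()))
    logger.info("stage 3 (NB): %d -> %d survivors", len(stage2), len(stage3))

    # stage 4: drug-likeness filter (removal only)
    stages = [s1, s2, s3]
    filter_report = None
    final_ids = stage3
    if config.apply_druglikeness:
        if smiles is None:
            warnings.warn("no structures supplied; skipping drug-likeness stage")
        else:
            passing, filter_report = lipinski_veber_filter(
                [(cid, smiles[cid]) for cid in stage3],
                allow_one_violation=config.allow_one_lipinski_violation,
            )
            keep = set(passing)
            final_ids = [cid for cid in stage3 if cid in keep]
            if not final_ids:
                raise InsufficientDataError("stage 4 (drug-likeness) removed every compound")
            stages.append(
                StageResult("druglikeness", final_ids, nb_scores.loc[stage3], None)
            )
            logger.info("stage 4 (Lipinski/Veber): %d -> %d survivors", len(stage3), len(final_ids))

    final = (
        pd.DataFrame({"nb_score": nb_scores.loc[final_ids]})
        .sort_values("nb_score", ascending=False, kind="mergesort")
    )
    final["rank"] = np.arange(1, len(final) + 1)
    return FunnelResult(stages, final, filter_report, config)
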