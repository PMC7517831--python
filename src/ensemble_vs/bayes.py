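"""Laplacian-corrected naive Bayes consensus re-scoring.

The consensus re-scorer fuses the per-structure docking scores and the
per-model pharmacophore fit values into one descriptor matrix X (one row per
compound, label y in {0, 1}) and learns an additive classifier over binned
descriptors. Each continuous column is discretised by equal-frequency
binning (default 10 bins, frozen at training time); missing values get their
own reserved bin, so failure to dock is itself informative.

For a binned feature F with A actives among B total training rows containing
F, and base rate p = N_active / N, the feature weight is

    w_F = ln((A + 1) / (B * p + 1))

(the Laplacian-corrected estimate: the +1 / +B*p terms act as 1/p virtual
samples at the base rate, so rare features shrink toward weight 0, and a
feature occurring at exactly the base rate, A = B*p, is exactly
uninformative). A compound's score is the sum of the weights of the bins its
row falls in; higher means more active-like.

The module follows the model/results pattern: ``BayesianFusion(X, y)`` holds
the data specification, ``fit()`` returns a ``BayesianFusionResults`` with
the learned weights, apparent and cross-validated AUC, scoring and summary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .metrics import ROCResult, roc_auc

__all__ = [
    "BinningScheme",
    "fit_bins",
    "BayesianFusion",
    "BayesianFusionResults",
    "assemble_matrix",
    "train_nb",
    "score_nb",
]

logger = logging.getLogger(__name__)

MISSING_BIN = -1


@dataclass
class BinningScheme:
    """Per-column strictly increasing cut points; NaN maps to the missing bin."""

    cuts: dict[str, np.ndarray]
    n_bins: int

    def assign(self, column: str, values) -> np.ndarray:
        """Bin indices for values of one column (missing -> MISSING_BIN)."""
        if column not in self.cuts:
            raise KeyError(f"column {column!r} not in binning scheme")
        v = np.asarray(values, dtype=float)
        bins = np.searchsorted(self.cuts[column], v, side="right").astype(int)
        bins[np.isnan(v)] = MISSING_BIN
        return bins

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "cuts": {c: [float(x) for x in v] for c, v in self.cuts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls({c: np.array(v, dtype=float) for c, v in d["cuts"].items()}, d["n_bins"])


def fit_bins(matrix: pd.DataFrame, n_bins: int = 10) -> BinningScheme:
    """Equal-frequency cut points per column (missing excluded, duplicates merged).

    A constant column degenerates to a single bin with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cuts: dict[str, np.ndarray] = {}
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            logger.warning("column %s entirely missing; single (missing) bin", col)
            cuts[str(col)] = np.array([])
            continue
        qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        uniq = np.unique(qs)
        if uniq.size == 0 or v.min() == v.max():
            logger.warning("column %s constant; single bin", col)
            cuts[str(col)] = np.array([])
        else:
            cuts[str(col)] = uniq
    return BinningScheme(cuts, n_bins)


def assemble_matrix(
    score_matrix,
    fit_tables: Mapping[str, Mapping[str, float]] | pd.DataFrame | None,
    chosen_columns: Mapping[str, str] | Sequence[tuple[str, str]] | None,
    labels: Mapping[str, int] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Row-aligned descriptor matrix: chosen docking columns + fit-value columns.

    `chosen_columns` maps structure_id -> mode (the output of choose_mode) or
    lists (structure, mode) pairs; `fit_tables` maps model_id -> {compound:
    fit} (or is a DataFrame). Compounds missing a docking score keep NaN
    (failed-to-dock semantics); compounds with every descriptor missing are
    dropped with a log message.
    """
    parts = []
    if score_matrix is not None and chosen_columns is not None:
        pairs = (
            list(chosen_columns.items())
            if isinstance(chosen_columns, Mapping)
            else [tuple(c) for c in chosen_columns]
        )
        dock = score_matrix.df[[tuple(p) for p in pairs]].copy()
        dock.columns = [f"dock:{s}:{m}" for s, m in pairs]
        parts.append(dock)
    if fit_tables is not None:
        if isinstance(fit_tables, pd.DataFrame):
            fit = fit_tables.copy()
            fit.columns = [
                c if str(c).startswith("fit:") else f"fit:{c}" for c in fit.columns
            ]
        else:
            fit = pd.DataFrame({f"fit:{mid}": pd.Series(vals) for mid, vals in fit_tables.items()})
        fit.index = fit.index.astype(str)
        parts.append(fit)
    if not parts:
        raise ValueError("nothing to assemble")
    X = pd.concat(parts, axis=1)
    X.index = X.index.astype(str)

    all_missing = X.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d compounds with every descriptor missing", int(all_missing.sum()))
        X = X.loc[~all_missing]

    y = None
    if labels is not None:
        y = pd.Series(labels).astype(int)
        y.index = y.index.astype(str)
        y = y.reindex(X.index)
        if y.isna().any():
            missing = y.index[y.isna()].tolist()[:5]
            raise ValueError(f"labels missing for compounds, e.g. {missing}")
    return X, y


def _laplacian_weights(
    binned: pd.DataFrame, y: np.ndarray, p: float
) -> dict[tuple[str, int], float]:
    weights: dict[tuple[str, int], float] = {}
    for col in binned.columns:
        b = binned[col].to_numpy()
        for value in np.unique(b):
            mask = b == value
            B = int(mask.sum())
            A = int((y[mask] == 1).sum())
            weights[(str(col), int(value))] = math.log((A + 1) / (B * p + 1))
    return weights


def train_nb(matrix: pd.DataFrame, y, scheme: BinningScheme) -> "BayesianFusionResults":
    """Train the Laplacian-corrected naive Bayes model on a binned matrix."""
    y = np.asarray(y, dtype=int)
    if len(y) != len(matrix):
        raise ValueError("label vector length mismatch")
    n_active = int((y == 1).sum())
    n_total = len(y)
    if n_active == 0 or n_active == n_total:
        raise InsufficientDataError("training requires both classes")
    p = n_active / n_total

    binned = pd.DataFrame(
        {str(c): scheme.assign(str(c), matrix[c]) for c in matrix.columns},
        index=matrix.index,
    )
    weights = _laplacian_weights(binned, y, p)
    return BayesianFusionResults(
        base_rate=p,
        weights=weights,
        scheme=scheme,
        columns=[str(c) for c in matrix.columns],
        n_active=n_active,
        n_total=n_total,
    )


def score_nb(results: "BayesianFusionResults", rows: pd.DataFrame) -> pd.Series:
    """Additive NB score per row (bins frozen at training; unseen bins weigh 0)."""
    return results.score(rows)


class BayesianFusion:
    """Model specification: descriptor matrix X (continuous, NaN = missing), y in {0,1}."""

    def __init__(self, X: pd.DataFrame, y):
        self.X = X.copy()
        self.X.columns = [str(c) for c in self.X.columns]
        self.y = np.asarray(y, dtype=int)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("y must be binary 0/1")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "BayesianFusion":
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, y)

    def fit(self, n_bins: int = 10) -> "BayesianFusionResults":
        scheme = fit_bins(self.X, n_bins)
        results = train_nb(self.X, self.y, scheme)
        results._training = (self.X, self.y)
        return results

    def fit_cross_validated(
        self, n_bins: int = 10, n_folds: int = 5, seed: int = 0
    ) -> tuple["BayesianFusionResults", float]:
        """Full-data fit plus stratified k-fold cross-validated AUC."""
        rng = np.random.default_rng(seed)
        y = self.y
        folds = np.empty(len(y), dtype=int)
        for cls_value in (0, 1):
            idx = np.flatnonzero(y == cls_value)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
        oof = np.full(len(y), np.nan)
        for k in range(n_folds):
            tr, te = folds != k, folds == k
            scheme = fit_bins(self.X.loc[tr], n_bins)
            res = train_nb(self.X.loc[tr], y[tr], scheme)
            oof[te] = res.score(self.X.loc[te]).to_numpy()
        cv_auc = roc_auc(oof, y).auc
        results = self.fit(n_bins)
        results.cv_auc = cv_auc
        return results, cv_auc


@dataclass
class BayesianFusionResults:
    """Fitted NB re-scorer: per-(column, bin) weights plus the frozen binning."""

    base_rate: float
    weights: dict[tuple[str, int], float]
    scheme: BinningScheme
    columns: list[str]
    n_active: int
    n_total: int
    cv_auc: float | None = None
    _training: tuple | None = None

    def weight(self, column: str, bin_index: int) -> float:
        """Weight of one (column, bin) feature; never-seen bins weigh 0."""
        return self.weights.get((column, int(bin_index)), 0.0)

    def score(self, rows: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.columns if c not in map(str, rows.columns)]
        if missing:
            raise KeyError(f"rows lack trained columns: {missing}")
        rows = rows.copy()
        rows.columns = [str(c) for c in rows.columns]
        total = np.zeros(len(rows))
        for col in self.columns:
            bins = self.scheme.assign(col, rows[col])
            total += np.array([self.weight(col, b) for b in bins])
        return pd.Series(total, index=rows.index, name="nb_score")

    def roc(self, rows: pd.DataFrame | None = None, y=None) -> ROCResult:
        if rows is None:
            if self._training is None:
                raise ValueError("no training data retained; pass rows and y")
            rows, y = self._training
        return roc_auc(self.score(rows).to_numpy(), np.asarray(y, dtype=int))

    def summary(self) -> str:
        lines = [
            "Laplacian-corrected naive Bayes fusion",
            "=" * 46,
            f"training rows:        {self.n_total}",
            f"actives / base rate:  {self.n_active} / {self.base_rate:.4f}",
            f"descriptor columns:   {len(self.columns)}",
            f"bins per column:      {self.scheme.n_bins} (+ missing bin)",
        ]
        if self._training is not None:
            lines.append(f"apparent AUC:         {self.roc().auc:.4f}")
        if self.cv_auc is not None:
            lines.append(f"cross-validated AUC:  {self.cv_auc:.4f}")
        lines.append("-" * 46)
        lines.append(f"{'column':<24}{'bin':>5}{'weight':>12}")
        for (col, b), w in sorted(self.weights.items()):
            lines.append(f"{col:<24}{b:>5}{w:>12.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_rate": self.base_rate,
            "n_active": self.n_active,
            "n_total": self.n_total,
            "columns": self.columns,
            "scheme": self.scheme.to_dict(),
            "weights": [
                {"column": c, "bin": b, "weight": w} for (c, b), w in sorted(self.weights.items())
            ],
            "cv_auc": self.cv_auc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "BayesianFusionResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            base_rate=d["base_rate"],
            weights={(w["column"], int(w["bin"])): float(w["weight"]) for w in d["weights"]},
            scheme=BinningScheme.from_dict(d["scheme"]),
            columns=d["columns"],
            n_active=d["n_active"],
            n_total=d["n_total"],
            cv_auc=d.get("cv_auc"),
        )
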