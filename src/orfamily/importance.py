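"""Per-(dataset, chemical) random-forest models and feature importances.

For every response dataset and every selected chemical, a random-forest
classifier is trained on the residue design table (one-hot encoded, so that
importances exist per (position, residue) feature) to predict the binarized
response. The number of candidate predictors per split (``mtry``) is chosen
by a cross-validated grid search; performance is the mean over the repeated
stratified k-fold resamples at the selected mtry, with the AUC reported
under the best-class convention max(AUC, 1 - AUC). Importances from the
final full-data fit are min-max scaled to [0, 100] per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .features import FeatureTable, build_feature_table, filter_near_zero_variance
from .io import AlignedFamily, ResponseMatrix
from .responses import ChemicalSelection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Random-forest training specification.

    Defaults: 500 trees, mtry grid {20, 50, 100}, 10-fold cross-validation
    repeated 10 times. Importance is mean decrease in impurity by default;
    ``importance="permutation"`` switches to permutation importance on the
    training data. No class reweighting is applied by default (the
    75th-percentile binarization yields roughly 1:3 classes).
    """

    n_trees: int = 500
    mtry_grid: tuple[int, ...] = (20, 50, 100)
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0
    importance: str = "impurity"
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not self.mtry_grid:
            raise ValueError("mtry grid must be non-empty")
        if self.importance not in {"impurity", "permutation"}:
            raise ValueError(f"unknown importance measure {self.importance!r}")


@dataclass
class ImportanceResult:
    """Cross-validated performance and scaled importances for one model."""

    dataset_id: str
    chemical_id: str
    auc: float
    f1: float
    sensitivity: float
    precision: float
    #: (alignment position, residue) -> importance scaled to [0, 100]
    importances: dict[tuple[int, str], float]
    n_train: int
    mtry: int

    def importance_frame(self) -> pd.DataFrame:
        rows = [
            (self.dataset_id, self.chemical_id, pos, res, imp)
            for (pos, res), imp in sorted(self.importances.items())
        ]
        return pd.DataFrame(
            rows, columns=["dataset", "chemical", "position", "residue", "importance"]
        )


def _one_hot(table: FeatureTable) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Encode the residue table as 0/1 columns keyed by (position, residue)."""
    blocks: list[np.ndarray] = []
    keys: list[tuple[int, str]] = []
    for pos in table.data.columns:
        col = table.data[pos]
        for res in sorted(col.unique()):
            blocks.append((col == res).to_numpy(dtype=np.float32))
            keys.append((int(pos), res))
    return np.column_stack(blocks), keys


def _scale_importances(raw: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 100]; an all-equal vector scales to all zero."""
    lo, hi = raw.min(), raw.max()
    if hi <= lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo) * 100.0


def _best_class_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    a = roc_auc_score(y_true, scores)
    return max(a, 1.0 - a)


def train_pair(
    table: FeatureTable,
    labels: pd.Series,
    spec: ModelSpec = ModelSpec(),
    dataset_id: str = "",
    chemical_id: str = "",
) -> ImportanceResult | None:
    """Train one model for a (dataset, chemical) pair.

    ``labels`` is a {0, 1} series indexed by sequence id; only sequences
    with a defined label are used. Returns None (with a warning in the log)
    when only one class is present.
    """
    labels = labels.dropna()
    ids = [s for s in table.seq_ids if s in labels.index]
    y = labels.loc[ids].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        log.warning(
            "pair (%s, %s): single-class labels, skipped", dataset_id, chemical_id
        )
        return None
    sub = FeatureTable(table.data.loc[ids])
    X, keys = _one_hot(sub)

    n = len(y)
    min_class = int(np.bincount(y).min())
    k = min(spec.cv_folds, n, min_class)
    if k < spec.cv_folds:
        log.warning(
            "pair (%s, %s): reduced CV folds from %d to %d (n=%d, minority=%d)",
            dataset_id, chemical_id, spec.cv_folds, k, n, min_class,
        )
    if k < 2:
        log.warning(
            "pair (%s, %s): not enough samples per class for CV, skipped",
            dataset_id, chemical_id,
        )
        return None

    grid = sorted({min(m, X.shape[1]) for m in spec.mtry_grid})
    rng_seed = spec.seed % (2**31)
    cv = RepeatedStratifiedKFold(
        n_splits=k, n_repeats=spec.cv_repeats, random_state=rng_seed
    )
    splits = list(cv.split(X, y))

    per_mtry: dict[int, dict[str, float]] = {}
    for mtry in grid:
        aucs, f1s, sens, precs = [], [], [], []
        for i, (tr, te) in enumerate(splits):
            clf = RandomForestClassifier(
                n_estimators=spec.n_trees,
                max_features=mtry,
                class_weight=spec.class_weight,
                random_state=rng_seed + i,
                n_jobs=1,
            )
            clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
            pred = (proba >= 0.5).astype(int)
            aucs.append(_best_class_auc(y[te], proba))
            f1s.append(f1_score(y[te], pred, zero_division=0))
            sens.append(recall_score(y[te], pred, zero_division=0))
            precs.append(precision_score(y[te], pred, zero_division=0))
        per_mtry[mtry] = {
            "auc": float(np.mean(aucs)),
            "f1": float(np.mean(f1s)),
            "sensitivity": float(np.mean(sens)),
            "precision": float(np.mean(precs)),
        }

    best_mtry = max(grid, key=lambda m: (per_mtry[m]["auc"], -m))
    metrics = per_mtry[best_mtry]

    final = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=best_mtry,
        class_weight=spec.class_weight,
        random_state=rng_seed,
        n_jobs=1,
    )
    final.fit(X, y)
    if spec.importance == "impurity":
        raw = final.feature_importances_
    else:
        raw = permutation_importance(
            final, X, y, n_repeats=10, random_state=rng_seed
        ).importances_mean
    scaled = _scale_importances(np.asarray(raw, dtype=float))
    return ImportanceResult(
        dataset_id=dataset_id,
        chemical_id=chemical_id,
        auc=metrics["auc"],
        f1=metrics["f1"],
        sensitivity=metrics["sensitivity"],
        precision=metrics["precision"],
        importances={key: float(v) for key, v in zip(keys, scaled)},
        n_train=n,
        mtry=best_mtry,
    )


def run_all_pairs(
    family: AlignedFamily,
    matrices: Sequence[ResponseMatrix],
    selection: ChemicalSelection,
    spec: ModelSpec = ModelSpec(),
    id_map: Mapping[str, str] | None = None,
    freq_cut: float = 19.0,
    unique_cut: float = 10.0,
) -> list[ImportanceResult]:
    """Train one model per (dataset, selected chemical) pair.

    Response-matrix protein ids are mapped to alignment sequence ids via
    ``id_map`` (default: identity). For each dataset the design table is
    restricted to proteins carrying at least one response value, and the
    near-zero-variance filter is applied within that training subset.
    Pairs with single-class or absent labels are skipped and counted.
    """
    id_map = dict(id_map or {})
    results: list[ImportanceResult] = []
    skipped = 0
    for matrix in matrices:
        if matrix.binarized is None:
            raise ValueError(
                f"dataset {matrix.dataset_id!r} has not been binarized"
            )
        chems = [c for c in selection.chemicals if c in matrix.binarized.columns]
        mapped = {
            id_map.get(p, p): p for p in matrix.proteins
            if id_map.get(p, p) in set(family.seq_ids)
        }
        labeled = [
            sid for sid, p in mapped.items()
            if matrix.binarized.loc[p, chems].notna().any()
        ]
        if not labeled:
            skipped += len(chems)
            log.warning("dataset %s: no labeled proteins", matrix.dataset_id)
            continue
        table = build_feature_table(family, labeled)
        table = filter_near_zero_variance(table, freq_cut, unique_cut)
        for chem in chems:
            labels = matrix.binarized[chem].rename(index={p: s for s, p in mapped.items()})
            res = train_pair(
                table, labels, spec,
                dataset_id=matrix.dataset_id, chemical_id=chem,
            )
            if res is None:
                skipped += 1
            else:
                results.append(res)
    if skipped:
        log.info("skipped %d (dataset, chemical) pair(s)", skipped)
    return results
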