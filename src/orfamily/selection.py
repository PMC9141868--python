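"""From per-model importances to predictive-position rankings.

A (position, residue, chemical) feature is *kept* when its importance
exceeds ``importance_min`` in a model whose best-class AUC exceeds
``auc_min``. A position's *times predictive* is the number of kept
(residue, chemical) feature instances at that position within a dataset;
ranking positions by this count yields the per-dataset top-10 tables, and
the union of the datasets' top-10 sets defines the predictive positions
used by the conservation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .importance import ImportanceResult

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictiveFeature:
    dataset_id: str
    chemical_id: str
    position: int
    residue: str
    importance: float
    model_auc: float


@dataclass
class PositionRanking:
    """Positions of one dataset ordered by how often they were predictive."""

    dataset_id: str
    #: (position, times_predictive), sorted by count descending; ties broken
    #: by the maximum importance at the position, then by position index
    entries: list[tuple[int, int]]

    def top(self, k: int) -> list[int]:
        if len(self.entries) < k:
            log.warning(
                "ranking for %s has only %d position(s), requested top %d",
                self.dataset_id, len(self.entries), k,
            )
        return [pos for pos, _ in self.entries[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.dataset_id, n, p) for p, n in self.entries],
            columns=["dataset", "times_predictive", "alignment_position"],
        )


def filter_features(
    results: Iterable[ImportanceResult],
    importance_min: float = 10.0,
    auc_min: float = 0.7,
) -> list[PredictiveFeature]:
    """Keep features with importance > importance_min from models with
    best-class AUC > auc_min (both bounds strict)."""
    kept: list[PredictiveFeature] = []
    for res in results:
        if res.auc <= auc_min:
            continue
        for (pos, residue), imp in res.importances.items():
            if imp > importance_min:
                kept.append(
                    PredictiveFeature(
                        dataset_id=res.dataset_id,
                        chemical_id=res.chemical_id,
                        position=pos,
                        residue=residue,
                        importance=imp,
                        model_auc=res.auc,
                    )
                )
    return kept


def rank_positions(
    features: Sequence[PredictiveFeature], dataset_id: str
) -> PositionRanking:
    """Rank one dataset's positions by kept-feature count."""
    feats = [f for f in features if f.dataset_id == dataset_id]
    if not feats:
        log.warning("no kept features for dataset %s", dataset_id)
        return PositionRanking(dataset_id, [])
    count: dict[int, int] = {}
    max_imp: dict[int, float] = {}
    for f in feats:
        count[f.position] = count.get(f.position, 0) + 1
        max_imp[f.position] = max(max_imp.get(f.position, 0.0), f.importance)
    ordered = sorted(count, key=lambda p: (-count[p], -max_imp[p], p))
    return PositionRanking(dataset_id, [(p, count[p]) for p in ordered])


def union_top_positions(
    rankings: Sequence[PositionRanking], k: int = 10
) -> set[int]:
    """Union of the top-k positions of each dataset's ranking."""
    if not rankings:
        raise ValueError("need at least one ranking")
    out: set[int] = set()
    for r in rankings:
        out.update(r.top(k))
    return out
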