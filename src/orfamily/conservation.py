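"""Per-cluster column conservation and the predictive/background ratio.

The conservation score of an alignment column within a cluster is the
frequency of its modal residue among the cluster's members: 1 means fully
conserved, values near 0 mean highly variable. Gaps (and the unknown
residue ``X``) are not residues and are excluded both from the modal count
and from the denominator; columns where every member is gapped receive no
score. A cluster's background conservation ``C_bg`` is the mean score over
all scored columns, its predictive conservation ``C_pred`` the mean over a
supplied set of predictive positions, and the ratio ``R = C_pred / C_bg``
measures whether the putative binding pocket is more (R > 1) or less
(R < 1) conserved than the rest of the protein.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GAP, UNKNOWN, AlignedFamily, ClusterAssignment

#: default minimum cluster size for conservation profiling
MIN_CLUSTER_SIZE = 5


@dataclass
class ConservationProfile:
    cluster_id: str
    n_members: int
    #: 1-based column -> conservation score; unscored columns absent
    scores: dict[int, float]
    background_mean: float
    predictive_mean: float
    ratio: float


class ClusterTooSmall(ValueError):
    pass


def position_conservation(
    family: AlignedFamily,
    clusters: ClusterAssignment,
    cluster_id: str,
    min_size: int = MIN_CLUSTER_SIZE,
    gaps_as_state: bool = False,
) -> dict[int, float]:
    """Per-column conservation scores for one cluster.

    ``gaps_as_state`` counts the gap character as an ordinary category
    (off by default; a gap is not a residue).
    """
    members = clusters.members(cluster_id)
    if len(members) < min_size:
        raise ClusterTooSmall(
            f"cluster {cluster_id!r} has {len(members)} member(s), "
            f"need at least {min_size}"
        )
    seqs = [family.sequence(m) for m in members]
    ignore = {UNKNOWN} if gaps_as_state else {GAP, UNKNOWN}
    scores: dict[int, float] = {}
    for col in range(len(seqs[0])):
        counts = Counter(s[col] for s in seqs)
        for ch in ignore:
            counts.pop(ch, None)
        total = sum(counts.values())
        if total == 0:
            continue
        scores[col + 1] = max(counts.values()) / total
    return scores


def conservation_ratio(
    family: AlignedFamily,
    clusters: ClusterAssignment,
    cluster_id: str,
    predictive_positions: Iterable[int],
    min_size: int = MIN_CLUSTER_SIZE,
    gaps_as_state: bool = False,
) -> ConservationProfile:
    """Background vs predictive conservation for one cluster.

    ``C_bg`` averages the scores of every scored column; ``C_pred``
    averages the scored columns among ``predictive_positions`` (predictive
    columns unscored in this cluster are excluded from the mean).
    """
    predictive = sorted(set(predictive_positions))
    if not predictive:
        raise ValueError("empty predictive position set")
    if any(not 1 <= p <= family.n_columns for p in predictive):
        raise ValueError("predictive positions outside alignment bounds")
    scores = position_conservation(
        family, clusters, cluster_id, min_size=min_size,
        gaps_as_state=gaps_as_state,
    )
    c_bg = float(np.mean(list(scores.values())))
    pred_scores = [scores[p] for p in predictive if p in scores]
    if not pred_scores:
        raise ValueError(
            f"no predictive position is scored in cluster {cluster_id!r}"
        )
    c_pred = float(np.mean(pred_scores))
    return ConservationProfile(
        cluster_id=cluster_id,
        n_members=len(clusters.members(cluster_id)),
        scores=scores,
        background_mean=c_bg,
        predictive_mean=c_pred,
        ratio=c_pred / c_bg,
    )


def profile_all_clusters(
    family: AlignedFamily,
    clusters: ClusterAssignment,
    predictive_positions: Iterable[int],
    min_size: int = MIN_CLUSTER_SIZE,
    gaps_as_state: bool = False,
) -> dict[str, ConservationProfile]:
    """Conservation profiles for every cluster of at least ``min_size``."""
    predictive = list(predictive_positions)
    out: dict[str, ConservationProfile] = {}
    sizes = clusters.sizes()
    for cid in clusters.cluster_ids:
        if sizes[cid] < min_size:
            continue
        out[cid] = conservation_ratio(
            family, clusters, cid, predictive,
            min_size=min_size, gaps_as_state=gaps_as_state,
        )
    return out


def profiles_to_frame(profiles: Mapping[str, ConservationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.cluster_id, p.n_members, p.background_mean, p.predictive_mean, p.ratio)
            for p in profiles.values()
        ],
        columns=["cluster_id", "n_members", "C_bg", "C_pred", "R"],
    )
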