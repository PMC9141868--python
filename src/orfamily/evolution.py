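"""Taxon-enrichment scoring and cluster-level evolutionary comparisons.

For every cluster and taxon, the enrichment score is
``E = log2(sequences in the cluster from the taxon / species in the taxon)``:
positive values flag lineage-specific expansions (more genes than species),
negative values depletion; taxa contributing no sequence are recorded as
absent rather than -inf. Clusters are annotated with their expansion (genes
per represented species) and social fraction, joined with the conservation
ratio R, and compared by median splits and species-specific expansion
groups using two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import MIN_CLUSTER_SIZE, ConservationProfile
from .io import AlignedFamily, ClusterAssignment, Taxonomy


@dataclass
class EnrichmentMatrix:
    """cluster x taxon log2 enrichment; None marks an absent taxon."""

    entries: dict[tuple[str, str], float | None]
    cluster_ids: list[str]
    taxon_codes: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with 'absent' for taxa without sequences."""
        rows = [
            (c, t, "absent" if self.entries[(c, t)] is None else self.entries[(c, t)])
            for c in self.cluster_ids
            for t in self.taxon_codes
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "taxon_code", "E"])


@dataclass
class ClusterAnnotation:
    cluster_id: str
    n_members: int
    n_species_present: int
    expansion: float
    social_fraction: float
    ratio: float | None = None  # conservation ratio R, when profiled


@dataclass
class SplitTestReport:
    criterion: str
    threshold: float | tuple[float, float]
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    p_value: float
    high_clusters: list[str] = field(default_factory=list)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max: int = 25
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have at most ``exact_max``
    observations and no ties are present; otherwise the normal
    approximation with tie and continuity correction.
    """
    x, y = list(x), list(y)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    ties = len(set(x) | set(y)) < len(x) + len(y)
    if len(x) <= exact_max and len(y) <= exact_max and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def enrichment(
    clusters: ClusterAssignment,
    taxonomy: Taxonomy,
    family: AlignedFamily,
    min_size: int = MIN_CLUSTER_SIZE,
) -> EnrichmentMatrix:
    """Log2 taxon enrichment for every cluster of at least ``min_size``."""
    species_of = dict(zip(family.seq_ids, family.species_ids))
    sizes = clusters.sizes()
    cluster_ids = [c for c in clusters.cluster_ids if sizes[c] >= min_size]
    taxon_codes = list(taxonomy.taxa)
    entries: dict[tuple[str, str], float | None] = {}
    for cid in cluster_ids:
        members = clusters.members(cid)
        sp_counts: dict[str, int] = {}
        for m in members:
            sp = species_of[m]
            sp_counts[sp] = sp_counts.get(sp, 0) + 1
        for taxon in taxon_codes:
            n_seqs = sum(sp_counts.get(sp, 0) for sp in taxonomy.taxa[taxon])
            entries[(cid, taxon)] = (
                None if n_seqs == 0
                else math.log2(n_seqs / taxonomy.n_species(taxon))
            )
    return EnrichmentMatrix(entries, cluster_ids, taxon_codes)


def annotate_clusters(
    clusters: ClusterAssignment,
    taxonomy: Taxonomy,
    family: AlignedFamily,
    profiles: Mapping[str, ConservationProfile] | None = None,
    min_size: int = MIN_CLUSTER_SIZE,
) -> list[ClusterAnnotation]:
    """Expansion, social fraction and conservation ratio per cluster."""
    species_of = dict(zip(family.seq_ids, family.species_ids))
    social = taxonomy.social_species()
    sizes = clusters.sizes()
    profiles = profiles or {}
    out: list[ClusterAnnotation] = []
    for cid in clusters.cluster_ids:
        if sizes[cid] < min_size:
            continue
        members = clusters.members(cid)
        sps = [species_of[m] for m in members]
        n_present = len(set(sps))
        n_social = sum(1 for sp in sps if sp in social)
        profile = profiles.get(cid)
        out.append(
            ClusterAnnotation(
                cluster_id=cid,
                n_members=len(members),
                n_species_present=n_present,
                expansion=len(members) / n_present,
                social_fraction=n_social / len(members),
                ratio=None if profile is None else profile.ratio,
            )
        )
    return out


def annotations_to_frame(annotations: Iterable[ClusterAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.cluster_id, a.n_members, a.n_species_present,
             a.expansion, a.social_fraction, a.ratio)
            for a in annotations
        ],
        columns=["cluster_id", "n_members", "n_species_present",
                 "expansion", "social_fraction", "R"],
    )


def median_split_test(
    annotations: Sequence[ClusterAnnotation],
    criterion: str = "both",
) -> SplitTestReport:
    """Compare conservation ratios between clusters above and below the
    median of a criterion.

    ``criterion`` is ``"social"`` (social fraction), ``"expansion"``
    (genes per represented species) or ``"both"`` (strictly above both
    medians). "Above the median" is strict, so clusters sitting exactly at
    the median fall in the low group. Only clusters carrying a conservation
    ratio participate.
    """
    annotated = [a for a in annotations if a.ratio is not None]
    if criterion not in {"social", "expansion", "both"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    social = np.array([a.social_fraction for a in annotated])
    expans = np.array([a.expansion for a in annotated])
    med_s = float(np.median(social)) if len(social) else float("nan")
    med_e = float(np.median(expans)) if len(expans) else float("nan")
    if criterion == "social":
        high_mask = social > med_s
        threshold: float | tuple[float, float] = med_s
    elif criterion == "expansion":
        high_mask = expans > med_e
        threshold = med_e
    else:
        high_mask = (social > med_s) & (expans > med_e)
        threshold = (med_s, med_e)
    high = [a for a, h in zip(annotated, high_mask) if h]
    low = [a for a, h in zip(annotated, high_mask) if not h]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"degenerate split for criterion {criterion!r}: "
            f"{len(high)} high vs {len(low)} low cluster(s)"
        )
    rh = [a.ratio for a in high]
    rl = [a.ratio for a in low]
    return SplitTestReport(
        criterion=criterion,
        threshold=threshold,
        n_high=len(high),
        n_low=len(low),
        mean_high=float(np.mean(rh)),
        mean_low=float(np.mean(rl)),
        p_value=wilcoxon_rank_sum(rh, rl),
        high_clusters=[a.cluster_id for a in high],
    )


def species_specific_clusters(
    clusters: ClusterAssignment,
    family: AlignedFamily,
    species_id: str,
    min_size: int = MIN_CLUSTER_SIZE,
    fraction: float = 1.0,
) -> list[str]:
    """Clusters of at least ``min_size`` whose membership is at least
    ``fraction`` (default: entirely) from ``species_id``."""
    species_of = dict(zip(family.seq_ids, family.species_ids))
    out = []
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        if len(members) < min_size:
            continue
        frac = sum(1 for m in members if species_of[m] == species_id) / len(members)
        if frac >= fraction:
            out.append(cid)
    return out


def species_specific_comparison(
    annotations: Sequence[ClusterAnnotation],
    clusters: ClusterAssignment,
    family: AlignedFamily,
    species_a: str,
    species_b: str,
    min_size: int = MIN_CLUSTER_SIZE,
    fraction: float = 1.0,
) -> SplitTestReport:
    """Compare conservation ratios of clusters specifically expanded in two
    species (e.g., a non-social beetle versus a social ant)."""
    by_id = {a.cluster_id: a for a in annotations if a.ratio is not None}
    groups: dict[str, list[float]] = {}
    names: dict[str, list[str]] = {}
    for sp in (species_a, species_b):
        ids = [
            c for c in species_specific_clusters(
                clusters, family, sp, min_size=min_size, fraction=fraction
            )
            if c in by_id
        ]
        if len(ids) < 2:
            raise ValueError(
                f"species {sp!r} has only {len(ids)} specifically expanded "
                f"cluster(s) with a conservation ratio; need at least 2"
            )
        groups[sp] = [by_id[c].ratio for c in ids]
        names[sp] = ids
    return SplitTestReport(
        criterion=f"species:{species_a}|{species_b}",
        threshold=fraction,
        n_high=len(groups[species_a]),
        n_low=len(groups[species_b]),
        mean_high=float(np.mean(groups[species_a])),
        mean_low=float(np.mean(groups[species_b])),
        p_value=wilcoxon_rank_sum(groups[species_a], groups[species_b]),
        high_clusters=names[species_a],
    )
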