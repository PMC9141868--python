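"""Taxon enrichment, cluster annotations, median splits and rank tests."""

import itertools
import math

import numpy as np
import pytest

from orfamily.evolution import (
    ClusterAnnotation,
    annotate_clusters,
    enrichment,
    median_split_test,
    species_specific_clusters,
    species_specific_comparison,
    wilcoxon_rank_sum,
)
from orfamily.conservation import profile_all_clusters
from orfamily.io import AlignedFamily, ClusterAssignment, Taxonomy
from orfamily.simulate import SimConfig, simulate_family


def _setup(counts: dict[str, dict[str, int]], species: dict[str, bool]):
    """Build a family + clusters with the given cluster->species->n counts."""
    records, assignments = [], {}
    for cid, sp_counts in counts.items():
        for sp, n in sp_counts.items():
            for g in range(n):
                sid = f"{sp}_{cid}g{g}"
                records.append((sid, sp, "AAAA"))
                assignments[sid] = cid
    fam = AlignedFamily(tuple(records))
    names = list(species)
    taxa = {"ROOT": frozenset(names)}
    parents = {}
    for sp in names:
        taxa[f"T_{sp}"] = frozenset({sp})
        parents[f"T_{sp}"] = "ROOT"
    social = frozenset(s for s, f in species.items() if f)
    if social:
        taxa["SOC"] = social
        parents["SOC"] = "ROOT"
    tax = Taxonomy(species=species, taxa=taxa, parents=parents)
    return fam, ClusterAssignment(assignments), tax


EIGHT_ANTS = {f"Ant{i}": True for i in range(8)}


class TestEnrichment:
    def test_log2_arithmetic_expanded_cluster(self):
        # 14 sequences from an 8-species taxon -> log2(14/8)
        counts = {"C40": {f"Ant{i}": (3 if i < 2 else 2) for i in range(6)}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        e = enrichment(clu, tax, fam)
        assert e.entries[("C40", "ROOT")] == pytest.approx(math.log2(14 / 8))

    def test_n_sequences_from_n_species_is_zero(self):
        counts = {"C47": {f"Ant{i}": 1 for i in range(8)}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        assert enrichment(clu, tax, fam).entries[("C47", "ROOT")] == 0.0

    def test_absent_taxon_is_none_not_minus_inf(self):
        counts = {"C1": {"Ant0": 5}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        e = enrichment(clu, tax, fam)
        assert e.entries[("C1", "T_Ant1")] is None
        frame = e.to_frame()
        assert (
            frame.loc[
                (frame.cluster_id == "C1") & (frame.taxon_code == "T_Ant1"), "E"
            ].item()
            == "absent"
        )

    def test_doubling_membership_adds_one(self):
        base = {"C1": {"Ant0": 3, "Ant1": 2}}
        double = {"C1": {"Ant0": 6, "Ant1": 4}}
        fam1, clu1, tax1 = _setup(base, EIGHT_ANTS)
        fam2, clu2, tax2 = _setup(double, EIGHT_ANTS)
        v1 = enrichment(clu1, tax1, fam1).entries[("C1", "ROOT")]
        v2 = enrichment(clu2, tax2, fam2).entries[("C1", "ROOT")]
        assert v2 - v1 == pytest.approx(1.0)

    def test_small_clusters_excluded(self):
        counts = {"C1": {"Ant0": 2}, "C2": {"Ant0": 5}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        assert enrichment(clu, tax, fam).cluster_ids == ["C2"]


class TestAnnotations:
    def test_expansion_one_for_single_copy_cluster(self):
        counts = {"C47": {f"Ant{i}": 1 for i in range(8)}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        ann = annotate_clusters(clu, tax, fam)[0]
        assert ann.expansion == 1.0
        assert ann.n_species_present == 8

    def test_expansion_for_duplicated_cluster(self):
        counts = {"C1": {"Ant0": 3, "Ant1": 3}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        assert annotate_clusters(clu, tax, fam)[0].expansion == 3.0

    def test_all_social_cluster_fraction_one(self):
        species = {**{f"Ant{i}": True for i in range(4)}, "Fly": False}
        counts = {"C1": {f"Ant{i}": 2 for i in range(4)}}
        fam, clu, tax = _setup(counts, species)
        assert annotate_clusters(clu, tax, fam)[0].social_fraction == 1.0

    def test_cluster_without_profile_has_no_ratio(self):
        counts = {"C1": {"Ant0": 5}}
        fam, clu, tax = _setup(counts, EIGHT_ANTS)
        ann = annotate_clusters(clu, tax, fam, profiles={})[0]
        assert ann.ratio is None


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p-value by enumerating all assignments of
    the pooled values to the first group."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(x)
    stats = [
        sum(combo)
        for combo in itertools.combinations(
            [ranks[v] for v in pooled], n
        )
    ]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        # groups [1,2,3] vs [4,5,6]: 20 arrangements, 2 as extreme -> 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert wilcoxon_enumeration_oracle(
            [1, 2, 3], [4, 5, 6]
        ) == pytest.approx(0.1)

    def test_agrees_with_enumeration_small_groups(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            nx, ny = rng.integers(2, 9), rng.integers(2, 9)
            vals = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = list(vals[:nx]), list(vals[nx:])
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_enumeration_oracle(x, y)
            )

    def test_identical_distributions_large_p(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(20):
            x = list(rng.normal(size=12))
            y = list(rng.normal(size=12))
            ps.append(wilcoxon_rank_sum(x, y))
        assert np.mean(ps) > 0.3  # roughly uniform null

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def _annotations(ratios, socials, expansions):
    return [
        ClusterAnnotation(
            cluster_id=f"C{i}", n_members=10, n_species_present=5,
            expansion=e, social_fraction=s, ratio=r,
        )
        for i, (r, s, e) in enumerate(zip(ratios, socials, expansions))
    ]


class TestMedianSplit:
    def test_strictly_above_median_rule(self):
        # expansions [1,2,3,4,5]: median 3 -> high group {4,5}
        anns = _annotations(
            ratios=[1.0, 1.1, 0.9, 1.2, 0.8],
            socials=[0.5] * 5,
            expansions=[1, 2, 3, 4, 5],
        )
        rep = median_split_test(anns, "expansion")
        assert rep.n_high == 2 and rep.n_low == 3
        assert set(rep.high_clusters) == {"C3", "C4"}

    def test_groups_partition_annotated_clusters(self):
        rng = np.random.default_rng(1)
        anns = _annotations(
            rng.uniform(0.8, 1.2, 30), rng.uniform(0, 1, 30),
            rng.uniform(1, 6, 30),
        )
        for criterion in ("social", "expansion", "both"):
            rep = median_split_test(anns, criterion)
            assert rep.n_high + rep.n_low == 30

    def test_both_requires_above_both_medians(self):
        anns = _annotations(
            ratios=[1.0, 1.1, 0.9, 1.2, 1.0, 0.95, 1.05, 0.85],
            socials=[0.1, 0.9, 0.1, 0.9, 0.1, 0.9, 0.1, 0.9],
            expansions=[1.0, 1.0, 5.0, 5.0, 1.0, 1.0, 5.0, 5.0],
        )
        rep = median_split_test(anns, "both")
        assert rep.n_high == 2  # only clusters high on both axes
        assert set(rep.high_clusters) == {"C3", "C7"}

    def test_degenerate_split_is_error(self):
        anns = _annotations([1.0] * 3, [0.5] * 3, [2.0] * 3)
        with pytest.raises(ValueError, match="social"):
            median_split_test(anns, "social")

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(20):
            anns = _annotations(
                rng.normal(1, 0.05, 20), rng.uniform(0, 1, 20),
                rng.uniform(1, 5, 20),
            )
            ps.append(median_split_test(anns, "social").p_value)
        assert np.mean(ps) > 0.3


class TestSpeciesSpecific:
    def test_specific_cluster_detection(self):
        species = {"Beetle": False, "Ant": True, "Fly": False}
        counts = {
            "C1": {"Beetle": 6},
            "C2": {"Beetle": 5, "Ant": 1},
            "C3": {"Ant": 7},
        }
        fam, clu, tax = _setup(counts, species)
        assert species_specific_clusters(clu, fam, "Beetle") == ["C1"]
        assert species_specific_clusters(
            clu, fam, "Beetle", fraction=0.8
        ) == ["C1", "C2"]

    def test_generator_contrast_detected(self):
        """Clusters private to species A are generated with binding columns
        more conserved than background; those private to B with less. The
        comparison must put the mean ratios on opposite sides and reject."""
        n_private = 8
        spec_clusters = {}
        theta_over = {}
        for i in range(n_private):
            spec_clusters[i] = 0          # species 0 ("A")
            theta_over[i] = 0.95
            spec_clusters[n_private + i] = 1  # species 1 ("B")
            theta_over[n_private + i] = 0.30
        cfg = SimConfig(
            seed=11, n_species=6, n_social=3, n_clusters=2 * n_private + 4,
            n_columns=80, theta_bg=0.6, theta_bind=0.6,
            binding_positions=(10, 25, 40, 55, 70), gap_rate=0.0,
            species_specific_clusters=spec_clusters,
            theta_bind_by_cluster=theta_over,
            species_specific_size=8, p_absent=0.2, mean_extra_genes=0.5,
        )
        fam, clu, tax = simulate_family(cfg)
        profiles = profile_all_clusters(fam, clu, cfg.binding_positions)
        anns = annotate_clusters(clu, tax, fam, profiles)
        rep = species_specific_comparison(anns, clu, fam, "Sp00", "Sp01")
        assert rep.n_high >= 8 and rep.n_low >= 8
        assert rep.mean_high > 1.0 > rep.mean_low
        assert rep.p_value < 0.05

    def test_too_few_clusters_is_error(self):
        species = {"Beetle": False, "Ant": True}
        counts = {"C1": {"Beetle": 6}, "C2": {"Ant": 6}}
        fam, clu, tax = _setup(counts, species)
        anns = annotate_clusters(clu, tax, fam, {})
        with pytest.raises(ValueError):
            species_specific_comparison(anns, clu, fam, "Beetle", "Ant")
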