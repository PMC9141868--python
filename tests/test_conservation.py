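"""Cluster conservation scores and predictive/background ratios,
checked against an explicit residue-tally oracle."""

from collections import Counter

import numpy as np
import pytest

from orfamily.conservation import (
    ClusterTooSmall,
    conservation_ratio,
    position_conservation,
    profile_all_clusters,
)
from orfamily.io import AlignedFamily, ClusterAssignment
from orfamily.simulate import SimConfig, simulate_family


def oracle_scores(seqs: list[str], gaps_as_state=False) -> dict[int, float]:
    """Brute-force per-column modal-residue frequency."""
    out = {}
    for col in range(len(seqs[0])):
        chars = [s[col] for s in seqs]
        counted = [
            c for c in chars
            if c != "X" and (gaps_as_state or c != "-")
        ]
        if counted:
            out[col + 1] = Counter(counted).most_common(1)[0][1] / len(counted)
    return out


def _cluster(seqs: list[str]):
    fam = AlignedFamily(
        tuple((f"Sp{i}_g", f"Sp{i}", s) for i, s in enumerate(seqs))
    )
    clusters = ClusterAssignment({sid: "C0" for sid in fam.seq_ids})
    return fam, clusters


class TestPositionConservation:
    def test_modal_counting(self):
        fam, clu = _cluster(["WAAAA", "WAAAA", "WAAAA", "FAAAA", "WAAAA"])
        scores = position_conservation(fam, clu, "C0", min_size=4)
        assert scores[1] == pytest.approx(4 / 5)
        assert scores[2] == 1.0

    def test_fully_conserved_is_one_all_distinct_is_quarter(self):
        fam, clu = _cluster(["AAAAA", "CAAAA", "DAAAA", "EAAAA"])
        scores = position_conservation(fam, clu, "C0", min_size=4)
        assert scores[1] == pytest.approx(0.25)
        assert scores[2] == 1.0

    def test_gaps_excluded_from_numerator_and_denominator(self):
        fam, clu = _cluster(["W-AAA", "W-AAA", "F-AAA", "--AAA"])
        scores = position_conservation(fam, clu, "C0", min_size=4)
        assert scores[1] == pytest.approx(2 / 3)
        assert 2 not in scores  # all-gap column unscored

    def test_gaps_as_state_switch(self):
        fam, clu = _cluster(["WAAAA", "WAAAA", "-AAAA", "-AAAA"])
        default = position_conservation(fam, clu, "C0", min_size=4)
        gappy = position_conservation(
            fam, clu, "C0", min_size=4, gaps_as_state=True
        )
        assert default[1] == 1.0
        assert gappy[1] == pytest.approx(0.5)

    def test_below_min_size_rejected(self):
        fam, clu = _cluster(["AA", "AA", "AA"])
        with pytest.raises(ClusterTooSmall):
            position_conservation(fam, clu, "C0", min_size=5)

    def test_oracle_equivalence_small_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, m = rng.integers(5, 11), rng.integers(3, 11)
            seqs = [
                "".join(rng.choice(list("ACDE-X"), m)) for _ in range(n)
            ]
            if all(set(s) <= {"-", "X"} for s in seqs):
                continue
            fam, clu = _cluster(seqs)
            got = position_conservation(fam, clu, "C0", min_size=3)
            assert got == pytest.approx(oracle_scores(seqs))

    def test_member_order_invariance(self):
        seqs = ["WAACA", "WAAAA", "FAAAA", "WACAA", "WAAAA"]
        fam, clu = _cluster(seqs)
        fwd = position_conservation(fam, clu, "C0")
        fam2, clu2 = _cluster(seqs[::-1])
        assert fwd == position_conservation(fam2, clu2, "C0")


class TestConservationRatio:
    def test_all_columns_ratio_exactly_one(self):
        fam, clu = _cluster(["WAAAA", "WAAAA", "WACAA", "FAAAA", "WAAAA"])
        prof = conservation_ratio(fam, clu, "C0", range(1, 6))
        assert prof.ratio == pytest.approx(1.0)

    def test_arithmetic_fully_conserved_predictive(self):
        # predictive column fully conserved (1.0), background mean 0.8
        # -> ratio 1.25
        fam, clu = _cluster(["WA", "WA", "WC", "WA", "WA"])
        prof = conservation_ratio(fam, clu, "C0", [1])
        assert prof.background_mean == pytest.approx(0.9)
        assert prof.predictive_mean == pytest.approx(1.0)
        fam2, clu2 = _cluster(["WAC", "WAC", "WCA", "WAC", "WCC"])
        prof2 = conservation_ratio(fam2, clu2, "C0", [1])
        assert prof2.background_mean == pytest.approx((1.0 + 0.8 + 0.6) / 3)
        assert prof2.ratio == pytest.approx(1.0 / prof2.background_mean)

    def test_empty_predictive_set_rejected(self):
        fam, clu = _cluster(["WA"] * 5)
        with pytest.raises(ValueError):
            conservation_ratio(fam, clu, "C0", [])

    def test_out_of_bounds_predictive_rejected(self):
        fam, clu = _cluster(["WA"] * 5)
        with pytest.raises(ValueError):
            conservation_ratio(fam, clu, "C0", [3])

    def test_generator_contrast_recovered_in_expectation(self):
        """Clusters conserved more strongly at planted positions than at
        the background yield ratio > 1 on average, and vice versa."""
        def mean_ratio(theta_bind, theta_bg, seed):
            cfg = SimConfig(
                seed=seed, n_species=8, n_social=4, n_clusters=6,
                n_columns=60, theta_bg=theta_bg, theta_bind=theta_bind,
                binding_positions=(10, 25, 40, 55), gap_rate=0.0,
                p_absent=0.1, mean_extra_genes=0.5,
            )
            fam, clu, _ = simulate_family(cfg)
            profs = profile_all_clusters(fam, clu, cfg.binding_positions)
            return np.mean([p.ratio for p in profs.values()])

        high = np.mean([mean_ratio(0.9, 0.5, s) for s in range(3)])
        low = np.mean([mean_ratio(0.3, 0.7, s) for s in range(3)])
        assert high > 1.0 > low


class TestProfileAllClusters:
    def test_small_clusters_excluded(self):
        fam = AlignedFamily(
            tuple((f"Sp{i}_g", f"Sp{i}", "WWAA") for i in range(7))
        )
        clu = ClusterAssignment(
            {sid: ("C0" if i < 5 else "C1")
             for i, sid in enumerate(fam.seq_ids)}
        )
        profs = profile_all_clusters(fam, clu, [1, 2])
        assert set(profs) == {"C0"}
        assert profs["C0"].n_members == 5
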