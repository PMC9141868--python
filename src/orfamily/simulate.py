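"""Synthetic receptor families with planted binding positions.

The generator emulates the statistical structure the downstream analysis
assumes: a set of orthologous clusters over a nested species taxonomy, each
cluster built around a consensus sequence, with members conserved towards
that consensus more strongly at a set of planted "binding" columns than at
background columns; a continuous chemical response is then driven by the
residues at the planted columns plus Gaussian noise.

All sampling flows from the single config seed through one
``numpy.random.Generator``; the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    AlignedFamily,
    ClusterAssignment,
    ResponseMatrix,
    Taxonomy,
)


class ConfigError(ValueError):
    """Raised on an inconsistent simulation configuration."""


def _default_background() -> tuple[float, ...]:
    return tuple([1.0 / 20] * 20)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated family.

    Defaults describe a desk-scale but structurally realistic family:
    21 species (8 social), 20 clusters, member counts drawn from a
    zero-inflated geometric (a species is absent from a cluster with
    probability 0.4, else carries 1 + Geometric(mean 1) genes, so clusters
    mix single-copy orthology with small expansions), 400 alignment
    columns, 10 planted binding columns conserved at 0.9 within clusters
    against a 0.7 background, and a response model with effect-to-noise
    ratio beta/sigma = 1.0/0.3 > 3.
    """

    seed: int = 0
    n_species: int = 21
    n_social: int = 8
    n_clusters: int = 20
    n_columns: int = 400
    #: probability a species contributes no gene to a cluster
    p_absent: float = 0.4
    #: mean extra gene count beyond the first (geometric) for present species
    mean_extra_genes: float = 1.0
    background_freqs: tuple[float, ...] = field(default_factory=_default_background)
    theta_bg: float = 0.7
    theta_bind: float = 0.9
    binding_positions: tuple[int, ...] = (30, 60, 90, 120, 150, 180, 210, 240, 270, 300)
    gap_rate: float = 0.05
    # response model
    n_chemicals: int = 8
    beta: float = 1.0
    sigma: float = 0.3
    #: number of amino acids in each (chemical, position) responsive set
    responsive_set_size: int = 6
    missing_fraction: float = 0.3
    #: optional per-cluster overrides of theta_bind (cluster index -> value)
    theta_bind_by_cluster: Mapping[int, float] = field(default_factory=dict)
    #: optional per-cluster restriction to a single species (cluster index ->
    #: species index); used to emulate species-specific expansions
    species_specific_clusters: Mapping[int, int] = field(default_factory=dict)
    #: member count per species-specific cluster
    species_specific_size: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.theta_bg <= 1 or not 0 <= self.theta_bind <= 1:
            raise ConfigError("theta values must lie in [0, 1]")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9 or len(self.background_freqs) != 20:
            raise ConfigError("background_freqs must be a 20-vector summing to 1")
        if any(not 1 <= p <= self.n_columns for p in self.binding_positions):
            raise ConfigError("binding positions must lie within 1..n_columns")
        if len(self.binding_positions) > self.n_columns:
            raise ConfigError("more binding positions than alignment columns")
        if self.n_social > self.n_species:
            raise ConfigError("n_social cannot exceed n_species")


def _species_names(config: SimConfig) -> list[str]:
    return [f"Sp{i:02d}" for i in range(config.n_species)]


def simulate_taxonomy(config: SimConfig) -> Taxonomy:
    """A three-level taxonomy: root, a social and a solitary clade, and one
    leaf taxon per species. Species ``Sp00..`` up to ``n_social`` are social."""
    names = _species_names(config)
    social = set(names[: config.n_social])
    taxa: dict[str, frozenset[str]] = {"ROOT": frozenset(names)}
    parents: dict[str, str] = {}
    if social:
        taxa["SOC"] = frozenset(social)
        parents["SOC"] = "ROOT"
    solitary = frozenset(set(names) - social)
    if solitary:
        taxa["SOL"] = solitary
        parents["SOL"] = "ROOT"
    for name in names:
        taxa[f"T_{name}"] = frozenset({name})
        parents[f"T_{name}"] = "SOC" if name in social else "SOL"
    return Taxonomy(
        species={n: n in social for n in names}, taxa=taxa, parents=parents
    )


def _draw_seq(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    return rng.choice(
        np.frombuffer(AMINO_ACIDS.encode(), dtype="S1"),
        size=config.n_columns,
        p=np.asarray(config.background_freqs),
    )


def simulate_family(
    config: SimConfig,
) -> tuple[AlignedFamily, ClusterAssignment, Taxonomy]:
    """Draw a clustered, aligned family over the configured taxonomy.

    Per cluster a consensus is drawn from the background frequencies; each
    member copies the consensus at every column with probability
    ``theta_bind`` (at planted binding columns) or ``theta_bg`` (elsewhere)
    and otherwise redraws from the background. Gaps are inserted i.i.d. at
    ``gap_rate`` per cell afterwards, sparing the binding columns so the
    planted signal stays a residue signal.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = simulate_taxonomy(config)
    names = _species_names(config)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    bind_idx = np.array([p - 1 for p in config.binding_positions], dtype=int)
    theta = np.full(config.n_columns, config.theta_bg)

    records: list[tuple[str, str, str]] = []
    assignments: dict[str, str] = {}
    for c in range(config.n_clusters):
        consensus = _draw_seq(rng, config)
        theta_c = theta.copy()
        theta_c[bind_idx] = config.theta_bind_by_cluster.get(c, config.theta_bind)
        if c in config.species_specific_clusters:
            counts = {names[config.species_specific_clusters[c]]: config.species_specific_size}
        else:
            present = rng.random(config.n_species) >= config.p_absent
            extra = rng.geometric(
                1.0 / (1.0 + config.mean_extra_genes), size=config.n_species
            ) - 1
            counts = {
                names[s]: int(1 + extra[s])
                for s in range(config.n_species)
                if present[s]
            }
        for sp, k in counts.items():
            for g in range(k):
                copy = rng.random(config.n_columns) < theta_c
                seq = np.where(copy, consensus, rng.choice(
                    aa, size=config.n_columns,
                    p=np.asarray(config.background_freqs)))
                if config.gap_rate > 0:
                    gap = rng.random(config.n_columns) < config.gap_rate
                    gap[bind_idx] = False
                    seq = np.where(gap, np.bytes_(b"-"), seq)
                sid = f"{sp}_C{c}g{g}"
                records.append((sid, sp, b"".join(seq).decode()))
                assignments[sid] = f"C{c}"
    family = AlignedFamily(tuple(records))
    return family, ClusterAssignment(assignments), taxonomy


def simulate_responses(
    family: AlignedFamily,
    config: SimConfig,
    dataset_id: str = "sim",
    seed_offset: int = 1,
) -> ResponseMatrix:
    """Continuous chemical responses driven by the planted binding residues.

    For every protein and chemical the response is ``beta`` times the number
    of planted columns whose residue falls in that chemical's responsive
    amino-acid set, plus N(0, sigma) noise; a ``missing_fraction`` of cells
    is then masked to emulate untested combinations.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    chems = [f"chem{j}" for j in range(config.n_chemicals)]
    aa = list(AMINO_ACIDS)
    responsive: dict[tuple[str, int], set[str]] = {}
    for chem in chems:
        for p in config.binding_positions:
            chosen = rng.choice(len(aa), size=config.responsive_set_size, replace=False)
            responsive[(chem, p)] = {aa[i] for i in chosen}

    mat = np.zeros((len(family.records), len(chems)))
    for i, (_, _, seq) in enumerate(family.records):
        for j, chem in enumerate(chems):
            hits = sum(
                seq[p - 1] in responsive[(chem, p)]
                for p in config.binding_positions
            )
            mat[i, j] = config.beta * hits
    mat = mat + rng.normal(0.0, config.sigma, size=mat.shape)
    if config.missing_fraction > 0:
        mask = rng.random(mat.shape) < config.missing_fraction
        mat = np.where(mask, np.nan, mat)
    values = pd.DataFrame(mat, index=list(family.seq_ids), columns=chems)
    return ResponseMatrix(dataset_id=dataset_id, values=values)
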