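"""Model/Results facade over the full receptor-family analysis.

:class:`ReceptorFamilyModel` bundles the data (alignment, cluster
assignment, taxonomy, response matrices) with the analysis settings;
``fit()`` runs chemical selection, binarization, per-pair random-forest
training, predictive-position ranking, per-cluster conservation profiling
and the evolutionary comparisons, returning a
:class:`ReceptorFamilyResults` that carries all estimates and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import conservation, evolution, responses, selection
from .conservation import ConservationProfile, profile_all_clusters, profiles_to_frame
from .evolution import (
    ClusterAnnotation,
    EnrichmentMatrix,
    SplitTestReport,
    annotate_clusters,
    annotations_to_frame,
    enrichment,
    median_split_test,
)
from .importance import ImportanceResult, ModelSpec, run_all_pairs
from .io import (
    AlignedFamily,
    ClusterAssignment,
    ResponseMatrix,
    Taxonomy,
    read_aligned_fasta,
    read_tables,
)
from .responses import ChemicalSelection, binarize, select_chemicals
from .selection import PositionRanking, PredictiveFeature, filter_features, rank_positions, union_top_positions
from .simulate import SimConfig, simulate_family, simulate_responses


@dataclass(frozen=True)
class AnalysisSettings:
    """All thresholds of the pipeline, with the published defaults."""

    min_values: int = 100
    importance_min: float = 10.0
    auc_min: float = 0.7
    top_k: int = 10
    min_cluster_size: int = 5
    freq_cut: float = 19.0
    unique_cut: float = 10.0
    gaps_as_state: bool = False
    model_spec: ModelSpec = field(default_factory=ModelSpec)


class ReceptorFamilyModel:
    """The family analysis, bound to one data bundle.

    Parameters
    ----------
    family, clusters, taxonomy
        The master alignment, cluster assignment and species taxonomy.
    matrices
        Response matrices, one per published dataset.
    settings
        Analysis thresholds; defaults follow the published pipeline.
    id_map
        Optional response-protein-id -> alignment-sequence-id mapping.
    """

    def __init__(
        self,
        family: AlignedFamily,
        clusters: ClusterAssignment,
        taxonomy: Taxonomy,
        matrices: Sequence[ResponseMatrix] = (),
        settings: AnalysisSettings = AnalysisSettings(),
        id_map: Mapping[str, str] | None = None,
    ) -> None:
        clusters.validate_against(family)
        unknown = set(family.species_ids) - set(taxonomy.species)
        if unknown:
            raise ValueError(f"species absent from taxonomy: {sorted(unknown)}")
        self.family = family
        self.clusters = clusters
        self.taxonomy = taxonomy
        self.matrices = list(matrices)
        self.settings = settings
        self.id_map = dict(id_map or {})

    @classmethod
    def from_files(
        cls,
        alignment_path: str | Path,
        cluster_path: str | Path,
        taxonomy_path: str | Path,
        response_paths: Sequence[str | Path] = (),
        settings: AnalysisSettings = AnalysisSettings(),
        id_map: Mapping[str, str] | None = None,
    ) -> "ReceptorFamilyModel":
        family = read_aligned_fasta(alignment_path)
        clusters, taxonomy, matrices = read_tables(
            cluster_path, taxonomy_path, response_paths, family=family
        )
        return cls(family, clusters, taxonomy, matrices, settings, id_map)

    @classmethod
    def from_simulation(
        cls,
        config: SimConfig,
        n_datasets: int = 3,
        settings: AnalysisSettings = AnalysisSettings(),
    ) -> "ReceptorFamilyModel":
        """Simulate a family and ``n_datasets`` response matrices from it."""
        family, clusters, taxonomy = simulate_family(config)
        matrices = [
            simulate_responses(family, config, dataset_id=f"ds{i}", seed_offset=i + 1)
            for i in range(n_datasets)
        ]
        return cls(family, clusters, taxonomy, matrices, settings)

    def fit(self, seed: int | None = None) -> "ReceptorFamilyResults":
        """Run the full analysis and return the results object.

        ``seed`` overrides the model spec's seed for the random-forest
        stage; everything else is deterministic.
        """
        s = self.settings
        spec = s.model_spec if seed is None else replace(s.model_spec, seed=seed)

        chem_selection = None
        importance_results: list[ImportanceResult] = []
        kept: list[PredictiveFeature] = []
        rankings: list[PositionRanking] = []
        predictive_positions: set[int] = set()
        binarized: list[ResponseMatrix] = []
        if self.matrices:
            chem_selection = select_chemicals(self.matrices, s.min_values)
            binarized = [binarize(m) for m in self.matrices]
            if chem_selection.chemicals:
                importance_results = run_all_pairs(
                    self.family, binarized, chem_selection, spec,
                    id_map=self.id_map,
                    freq_cut=s.freq_cut, unique_cut=s.unique_cut,
                )
                kept = filter_features(
                    importance_results, s.importance_min, s.auc_min
                )
                dataset_ids = [m.dataset_id for m in binarized]
                rankings = [
                    rank_positions(kept, ds) for ds in dataset_ids
                    if any(f.dataset_id == ds for f in kept)
                ]
                if rankings:
                    predictive_positions = union_top_positions(rankings, s.top_k)

        profiles: dict[str, ConservationProfile] = {}
        if predictive_positions:
            profiles = profile_all_clusters(
                self.family, self.clusters, predictive_positions,
                min_size=s.min_cluster_size, gaps_as_state=s.gaps_as_state,
            )
        enr = enrichment(
            self.clusters, self.taxonomy, self.family, s.min_cluster_size
        )
        annotations = annotate_clusters(
            self.clusters, self.taxonomy, self.family, profiles,
            s.min_cluster_size,
        )
        split_tests: dict[str, SplitTestReport] = {}
        if profiles:
            for criterion in ("social", "expansion", "both"):
                try:
                    split_tests[criterion] = median_split_test(
                        annotations, criterion
                    )
                except ValueError:
                    pass
        return ReceptorFamilyResults(
            model=self,
            chemical_selection=chem_selection,
            binarized=binarized,
            importance_results=importance_results,
            kept_features=kept,
            rankings=rankings,
            predictive_positions=predictive_positions,
            profiles=profiles,
            enrichment=enr,
            annotations=annotations,
            split_tests=split_tests,
        )


@dataclass
class ReceptorFamilyResults:
    """Everything the fitted analysis estimated."""

    model: ReceptorFamilyModel
    chemical_selection: ChemicalSelection | None
    binarized: list[ResponseMatrix]
    importance_results: list[ImportanceResult]
    kept_features: list[PredictiveFeature]
    rankings: list[PositionRanking]
    predictive_positions: set[int]
    profiles: dict[str, ConservationProfile]
    enrichment: EnrichmentMatrix
    annotations: list[ClusterAnnotation]
    split_tests: dict[str, SplitTestReport]

    # ---- tabular views -----------------------------------------------
    def performance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.dataset_id, r.chemical_id, r.n_train, r.mtry,
                 r.auc, r.f1, r.sensitivity, r.precision)
                for r in self.importance_results
            ],
            columns=["dataset", "chemical", "n_train", "mtry",
                     "auc", "f1", "sensitivity", "precision"],
        )

    def ranking_frame(self) -> pd.DataFrame:
        if not self.rankings:
            return pd.DataFrame(
                columns=["dataset", "times_predictive", "alignment_position"]
            )
        return pd.concat(
            [r.to_frame().head(self.model.settings.top_k) for r in self.rankings],
            ignore_index=True,
        )

    def conservation_frame(self) -> pd.DataFrame:
        return profiles_to_frame(self.profiles)

    def annotation_frame(self) -> pd.DataFrame:
        return annotations_to_frame(self.annotations)

    def species_specific_comparison(
        self, species_a: str, species_b: str, fraction: float = 1.0
    ) -> SplitTestReport:
        return evolution.species_specific_comparison(
            self.annotations, self.model.clusters, self.model.family,
            species_a, species_b,
            min_size=self.model.settings.min_cluster_size, fraction=fraction,
        )

    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        lines = ["Receptor family analysis", "=" * 24]
        fam = self.model.family
        lines.append(
            f"alignment: {len(fam.records)} sequences x {fam.n_columns} columns, "
            f"{len(set(fam.species_ids))} species"
        )
        sizes = self.model.clusters.sizes()
        lines.append(
            f"clusters: {len(sizes)} total, "
            f"{sum(1 for n in sizes.values() if n >= self.model.settings.min_cluster_size)} "
            f"with >= {self.model.settings.min_cluster_size} members"
        )
        if self.chemical_selection is not None:
            lines.append(
                f"chemicals selected (> {self.chemical_selection.threshold} "
                f"values): {len(self.chemical_selection.chemicals)}"
            )
        if self.importance_results:
            perf = self.performance_frame()
            lines.append(
                f"models trained: {len(perf)}; "
                f"mean best-class AUC {perf['auc'].mean():.3f}"
            )
            lines.append(
                f"kept features (importance > "
                f"{self.model.settings.importance_min}, AUC > "
                f"{self.model.settings.auc_min}): {len(self.kept_features)}"
            )
            lines.append(
                f"predictive positions (union of top-"
                f"{self.model.settings.top_k}): {len(self.predictive_positions)}"
            )
        if self.profiles:
            ratios = [p.ratio for p in self.profiles.values()]
            lines.append(
                f"conservation ratio R over {len(ratios)} clusters: "
                f"median {np.median(ratios):.3f}, "
                f"min {min(ratios):.3f}, max {max(ratios):.3f}"
            )
        for name, rep in self.split_tests.items():
            lines.append(
                f"median split [{name}]: {rep.n_high} vs {rep.n_low} clusters, "
                f"mean R {rep.mean_high:.3f} vs {rep.mean_low:.3f}, "
                f"p = {rep.p_value:.3g}"
            )
        return "\n".join(lines)

    # ---- plots --------------------------------------------------------
    def plot_conservation(self, ax=None):
        """Predictive vs background conservation per cluster, with the
        identity diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = [p.background_mean for p in self.profiles.values()]
        ys = [p.predictive_mean for p in self.profiles.values()]
        ax.scatter(xs, ys, s=14)
        lim = [min(xs + ys, default=0), max(xs + ys, default=1)]
        ax.plot(lim, lim, ls="--", c="gray", lw=1)
        ax.set_xlabel("background conservation")
        ax.set_ylabel("predictive-position conservation")
        return ax

    def plot_enrichment(self, ax=None):
        """Cluster x taxon log2 enrichment heatmap; absent taxa blank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.enrichment.to_frame()
        df["E"] = pd.to_numeric(df["E"], errors="coerce")
        pivot = df.pivot(index="cluster_id", columns="taxon_code", values="E")
        im = ax.imshow(pivot.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="log2 enrichment")
        return ax
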