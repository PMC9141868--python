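# Methods

## The analysis

The package operates on a fixed-coordinate multiple sequence alignment of
a receptor family (columns addressed 1-based throughout), a partition of
the sequences into orthologous clusters, a nested species taxonomy with
per-species sociality flags, and one or more protein-by-chemical response
matrices in which a missing cell means "not tested", never "no response".

### Response preparation

Chemicals enter training when the union of the datasets holds strictly
more than `min_values` (default 100) tested cells for them. Within each
dataset, each chemical's responses are binarized at that chemical's 75th
percentile of defined values: strictly greater becomes 1, ties and below
become 0, missing stays missing. The percentile uses linear interpolation
between order statistics (the common default of statistical tooling; a
nearest-rank switch exists because the convention is not universal).
Binarization is never pooled across datasets — the source measurements
(electrophysiology from different laboratories) are not on a common scale.

### Random-forest stage

For each (dataset, chemical) pair with both classes present, the residue
design table — rows = proteins with a defined label, columns = alignment
positions, cells = residue characters with the gap `-` as a first-class
category — is one-hot encoded so that importances exist per
(position, residue) feature. Near-zero-variance columns are removed per
training subset using the conventional rule (frequency ratio > 19, i.e.
95/5, together with fewer distinct categories than 10% of rows; constants
always drop). A random forest (default 500 trees) is trained with the
number of candidate predictors per split (`mtry`) selected from the grid
{20, 50, 100} by repeated stratified k-fold cross-validation (default
10-fold × 10 repeats; folds shrink automatically when the minority class
is smaller than k). Reported performance is the mean over resamples at
the selected mtry; the AUC uses the best-class convention
max(AUC, 1 − AUC), so it is ≥ 0.5 by construction. Importances are mean
decrease in impurity from the final full-data fit (permutation importance
is available by configuration), min–max scaled to [0, 100] per model.

Class imbalance (~1:3 from the quartile rule) is not reweighted by
default; `ModelSpec.class_weight` exposes it.

### Position selection

A feature is kept when its scaled importance exceeds 10 in a model whose
best-class AUC exceeds 0.7 (both strict). A position's *times predictive*
within a dataset counts kept (residue, chemical) feature instances — not
distinct chemicals, since several residues at one position can be
predictive for the same chemical. Positions are ranked by this count;
ties break by the maximum importance observed at the position, then by
position index (deterministic and logged). The family's predictive
position set is the union of each dataset's top-10.

### Conservation

Within a cluster of at least `min_cluster_size` (default 5) members, a
column's conservation is the frequency of its modal residue. Gaps and the
unknown residue `X` are excluded from both numerator and denominator — a
gap is not a residue — and columns in which every member is gapped receive
no score and are excluded from the background mean. (A `gaps_as_state`
switch treats `-` as an ordinary category for sensitivity analysis.) The
background conservation `C_bg` averages all scored columns; the
predictive conservation `C_pred` averages the scored columns among the
predictive positions; their ratio `R = C_pred / C_bg` is the cluster's
binding-pocket conservation relative to its own baseline, which removes
between-cluster differences in overall divergence. Both means are
per-column across the cluster (not per-sequence then averaged): this
makes `C_pred` and `C_bg` commensurable, since both are then means of the
same per-column statistic.

### Evolutionary comparisons

Taxon enrichment is `E = log2(n_seqs / n_species)` per (cluster, taxon),
with taxa contributing no sequence recorded as absent rather than −∞.
Clusters are annotated with expansion (members per represented species)
and social fraction (members from flagged-social species). Median splits
put a cluster in the high group only when strictly above the median (for
the combined criterion: above both medians), so clusters at the median
fall low. Group ratios are compared by a two-sided Wilcoxon rank-sum
test: exact null distribution when both groups have ≤ 25 observations and
no ties, otherwise the normal approximation with tie and continuity
correction. "Specifically expanded in species X" means a cluster of at
least `min_cluster_size` members all (configurable fraction, default
100%) from X.

### Structure mapping

Alignment columns map to a linking reference sequence present in the
alignment by cumulative non-gap count (gap columns unmapped), and the
reference maps to a template by pairwise global alignment (BLOSUM62, gap
open −10, extend −0.5, all logged and configurable; the template's
numbering may be shifted by an offset table). Both partial maps are
strictly increasing; composition gives column → template. No structure
files are parsed — the template is only a residue-numbering frame.

## The synthetic generator

`SimConfig` states a family: a three-level taxonomy (root, one social and
one solitary clade, leaf taxa per species), per-cluster consensus
sequences drawn from background residue frequencies, members copying the
consensus with probability θ_bind at planted binding columns and θ_bg
elsewhere (redrawing from the background otherwise), i.i.d. per-cell gaps
at `gap_rate` sparing binding columns, and a response model: for every
chemical, each binding position carries a responsive amino-acid set, and
a protein's response is β × (number of binding positions whose residue is
responsive) + N(0, σ), with a fraction of cells masked as untested.
Per-cluster overrides of θ_bind and single-species cluster restrictions
let tests construct conservation contrasts and species-specific
expansions. One `numpy.random.Generator` seeded from the config drives
everything; equal seeds give bit-identical families.

Defaults state a desk-scale but structurally realistic family: 21
species, 8 of them social; 20 clusters; species absent from a cluster
with probability 0.4, otherwise carrying 1 + Geometric(mean 1) genes; 400
columns with 10 planted binding positions; θ_bind = 0.9 > θ_bg = 0.7
(binding sites more conserved, the family's biology); β/σ = 1.0/0.3
(effect-to-noise above 3); 30% untested cells.

For machine-learning recovery benchmarks a different regime is stated:
θ_bind = 0.6 ("moderate", so binding columns vary among labeled proteins)
over θ_bg = 0.35 (a deeply diverged background, as real OR alignments
are). This matters because the generator has a deliberate limitation:
when the background is strongly conserved within clusters
(θ_bg ≥ θ_bind), every column fingerprints its cluster, cluster identity
predicts the response, and no residue-level method can attribute the
signal to the planted columns — a phylogenetic confounding that the
random-forest stage does not model (nor does the analysis it implements).
A green recovery test therefore establishes that planted residue signal
is found when the background does not mirror cluster structure, not that
the method is immune to lineage-response correlation.

Other features of real data the generator does not emulate: no
phylogenetic tree within or between clusters (members are conditionally
i.i.d. around the consensus), no indel evolution (gaps are i.i.d. noise),
no across-dataset heterogeneity of measurement scale, and no correlation
between sociality and cluster structure unless planted explicitly.

## Numerical choices

- Strict inequalities everywhere the published thresholds are stated as
  "greater than": binarization, chemical selection (> 100), feature gates
  (> 10, > 0.7), median splits.
- Min–max importance scaling maps an all-equal importance vector to all
  zeros (no signal, nothing kept).
- mtry values exceeding the number of encoded predictors are clamped with
  deduplication; grids are sorted, AUC ties between mtry values resolve
  to the smaller value.
- Cross-validation folds reduce to the minority class size when needed
  (minimum 2); pairs that still cannot be stratified are skipped with a
  warning, as are single-class labelings.
- Percentile method, gap-as-state conservation, species-specific fraction
  threshold and the exact/asymptotic rank-sum crossover (25) are
  configuration switches; defaults are the package's stated conventions.
- `X` is accepted on input and excluded from all residue counting; in the
  design table it remains a category (the forest treats it as any other).

## Known limitations

- Importance is mean decrease in impurity, which inflates high-cardinality
  one-hot groups slightly; the permutation alternative is slower but
  available.
- The conservation ratio uses a single union set of predictive positions
  for all clusters; clusters fully gapped at many predictive positions
  have their `C_pred` averaged over fewer columns.
- The Wilcoxon exact path requires tie-free data; ratios are continuous
  so ties are rare, but tied inputs silently use the corrected
  approximation.
- Real-data reproduction of the published cluster-conservation summary
  requires the full family alignment and cluster assignment, which are
  not shipped; the corresponding test documents where to place them.
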