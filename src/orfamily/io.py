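"""Readers, writers and validation for the file formats the pipeline consumes.

The pipeline works on four kinds of input:

* an aligned FASTA of family members (the master multiple sequence alignment,
  gap character ``-``, 1-based column coordinates),
* a sequence-to-cluster assignment table (TSV: ``seq_id``, ``cluster_id``),
* a species taxonomy table with sociality flags (TSV: ``taxon_code``,
  ``parent_code``, ``species_id``, ``social``), and
* one or more protein-by-chemical response matrices (CSV, first column
  ``protein_id``, remaining columns one per chemical; empty cells mean
  "not tested", never zero).

All objects are cross-validated on load: cluster members must exist in the
alignment, every species must appear in the taxonomy, and taxon membership
must form a nested tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: characters legal in an aligned sequence: the 20 amino acids, unknown, gap
ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}
GAP = "-"
UNKNOWN = "X"


class AlignmentError(ValueError):
    """Raised when records of an alignment disagree in length."""


class ValidationError(ValueError):
    """Raised on illegal characters or broken referential integrity."""


class TaxonomyError(ValueError):
    """Raised when the taxon membership sets do not nest into a tree."""


def default_species_parser(seq_id: str) -> str:
    """Extract the species label from a sequence id: prefix before the first
    underscore (``"Dmel_Or22a" -> "Dmel"``)."""
    return seq_id.split("_", 1)[0]


@dataclass(frozen=True)
class AlignedFamily:
    """A fixed-coordinate multiple sequence alignment of a protein family.

    Parameters
    ----------
    records
        Ordered ``(seq_id, species_id, aligned_seq)`` triples. All aligned
        sequences must have identical length; columns are addressed 1-based
        everywhere in this package.
    """

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment contains no sequences")
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) != 1:
            n = max(lengths)
            bad = [sid for sid, _, seq in self.records if len(seq) != n]
            raise AlignmentError(
                f"records are not all the same length (offending ids: {bad})"
            )
        seen: set[str] = set()
        for sid, _, seq in self.records:
            if sid in seen:
                raise ValidationError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
            for col, ch in enumerate(seq, start=1):
                if ch not in ALPHABET:
                    raise ValidationError(
                        f"illegal character {ch!r} in {sid!r} at column {col}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.records[0][2])

    @property
    def seq_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _, _ in self.records)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sp for _, sp, _ in self.records)

    def sequence(self, seq_id: str) -> str:
        for sid, _, seq in self.records:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def species_of(self, seq_id: str) -> str:
        for sid, sp, _ in self.records:
            if sid == seq_id:
                return sp
        raise KeyError(seq_id)

    def subset(self, seq_ids: Iterable[str]) -> "AlignedFamily":
        wanted = set(seq_ids)
        missing = wanted - set(self.seq_ids)
        if missing:
            raise ValidationError(f"unknown sequence ids: {sorted(missing)}")
        return AlignedFamily(
            tuple(r for r in self.records if r[0] in wanted)
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Rows = sequences, columns = 1-based alignment positions."""
        return pd.DataFrame(
            [list(seq) for _, _, seq in self.records],
            index=list(self.seq_ids),
            columns=range(1, self.n_columns + 1),
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """Mapping of every sequence to exactly one orthologous cluster."""

    assignments: Mapping[str, str]

    def members(self, cluster_id: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster_id]

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return out

    def validate_against(self, family: AlignedFamily) -> None:
        unknown = set(self.assignments) - set(family.seq_ids)
        if unknown:
            raise ValidationError(
                f"cluster table references unknown sequence ids: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class Taxonomy:
    """Nested taxon structure over the species set, with sociality flags.

    ``species`` maps species_id -> social flag.  ``taxa`` maps a taxon code
    (e.g. ``"L"`` for an order, ``"Q"`` for a single species) to its member
    species; ``parents`` gives each non-root taxon's parent code.  Member
    sets must nest: a child's members are a subset of its parent's, and the
    root contains every species.
    """

    species: Mapping[str, bool]
    taxa: Mapping[str, frozenset[str]]
    parents: Mapping[str, str]

    def __post_init__(self) -> None:
        roots = [t for t in self.taxa if t not in self.parents]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root taxon, got {roots}")
        root = roots[0]
        if self.taxa[root] != frozenset(self.species):
            raise TaxonomyError("root taxon must contain every species")
        for taxon, members in self.taxa.items():
            if not members:
                raise TaxonomyError(f"taxon {taxon!r} has no member species")
            if taxon in self.parents:
                parent = self.parents[taxon]
                if parent not in self.taxa:
                    raise TaxonomyError(f"unknown parent taxon {parent!r}")
                if not members <= self.taxa[parent]:
                    raise TaxonomyError(
                        f"taxon {taxon!r} has members outside its parent {parent!r}"
                    )

    @property
    def root(self) -> str:
        return next(t for t in self.taxa if t not in self.parents)

    def social_species(self) -> frozenset[str]:
        return frozenset(s for s, flag in self.species.items() if flag)

    def n_species(self, taxon_code: str) -> int:
        return len(self.taxa[taxon_code])


@dataclass
class ResponseMatrix:
    """Protein-by-chemical numeric responses for one published dataset.

    ``values`` holds raw (continuous) responses with NaN for untested
    combinations; ``binarized`` (same shape, filled in by the response-
    preparation stage) holds {0, 1} with NaN preserved.
    """

    dataset_id: str
    values: pd.DataFrame
    binarized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.binarized is not None:
            if not self.binarized.shape == self.values.shape:
                raise ValidationError("binarized matrix shape mismatch")
            if (self.binarized.isna() != self.values.isna()).any().any():
                raise ValidationError(
                    "binarized must be defined exactly where values is defined"
                )

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def chemicals(self) -> list[str]:
        return list(self.values.columns)

    def defined_counts(self) -> pd.Series:
        """Number of tested proteins per chemical."""
        return self.values.notna().sum(axis=0)


# ---------------------------------------------------------------------------
# readers


def read_aligned_fasta(
    path: str | Path,
    species_parser: Callable[[str], str] = default_species_parser,
    species_map: Mapping[str, str] | None = None,
) -> AlignedFamily:
    """Read an aligned FASTA into an :class:`AlignedFamily`.

    ``species_map`` (seq_id -> species_id), when given, overrides header
    parsing; otherwise ``species_parser`` is applied to each record id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        sp = (species_map or {}).get(sid) or species_parser(sid)
        records.append((sid, sp, str(rec.seq).upper()))
    return AlignedFamily(tuple(records))


def write_aligned_fasta(family: AlignedFamily, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, _, seq in family.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_clusters(path: str | Path) -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"seq_id", "cluster_id"} <= set(df.columns):
        raise ValidationError("cluster table needs columns seq_id, cluster_id")
    if df["seq_id"].duplicated().any():
        dup = df.loc[df["seq_id"].duplicated(), "seq_id"].tolist()
        raise ValidationError(f"sequences assigned to multiple clusters: {dup}")
    return ClusterAssignment(dict(zip(df["seq_id"], df["cluster_id"])))


def write_clusters(clusters: ClusterAssignment, path: str | Path) -> None:
    pd.DataFrame(
        sorted(clusters.assignments.items()), columns=["seq_id", "cluster_id"]
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read the taxonomy TSV (taxon_code, parent_code, species_id, social).

    One row per (taxon, member species); the parent_code must be stated
    consistently across a taxon's rows and empty for the root.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"taxon_code", "parent_code", "species_id", "social"}
    if not need <= set(df.columns):
        raise ValidationError(f"taxonomy table needs columns {sorted(need)}")
    species: dict[str, bool] = {}
    taxa: dict[str, set[str]] = {}
    parents: dict[str, str] = {}
    for _, row in df.iterrows():
        t, p, s = row["taxon_code"], row["parent_code"], row["species_id"]
        taxa.setdefault(t, set()).add(s)
        if p:
            if parents.setdefault(t, p) != p:
                raise TaxonomyError(f"taxon {t!r} has conflicting parents")
        social = str(row["social"]).strip().lower() in {"1", "true", "yes"}
        if s in species and species[s] != social:
            raise TaxonomyError(f"species {s!r} has conflicting social flags")
        species[s] = social
    return Taxonomy(
        species=species,
        taxa={t: frozenset(m) for t, m in taxa.items()},
        parents=parents,
    )


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = []
    for t, members in taxonomy.taxa.items():
        parent = taxonomy.parents.get(t, "")
        for s in sorted(members):
            rows.append((t, parent, s, int(taxonomy.species[s])))
    pd.DataFrame(
        rows, columns=["taxon_code", "parent_code", "species_id", "social"]
    ).to_csv(path, sep="\t", index=False)


def read_response_matrix(path: str | Path, dataset_id: str | None = None) -> ResponseMatrix:
    """Read a response CSV (protein_id column, then one column per chemical).

    Empty cells are missing values, not zeros.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if dataset_id is None:
        stem = Path(path).stem
        dataset_id = stem.removeprefix("responses_")
    return ResponseMatrix(dataset_id=dataset_id, values=df)


def write_response_matrix(matrix: ResponseMatrix, path: str | Path, binarized: bool = False) -> None:
    df = matrix.binarized if binarized else matrix.values
    if df is None:
        raise ValidationError("matrix has no binarized form yet")
    out = df.copy()
    if binarized:
        # keep {0,1} cells integral in the emitted CSV
        out = out.astype("Int64")
    out.to_csv(path, index_label="protein_id", na_rep="")


def read_tables(
    cluster_path: str | Path,
    taxonomy_path: str | Path,
    response_paths: Sequence[str | Path],
    family: AlignedFamily | None = None,
) -> tuple[ClusterAssignment, Taxonomy, list[ResponseMatrix]]:
    """Read and cross-validate the cluster, taxonomy and response tables."""
    clusters = read_clusters(cluster_path)
    taxonomy = read_taxonomy(taxonomy_path)
    matrices = [read_response_matrix(p) for p in response_paths]
    if family is not None:
        clusters.validate_against(family)
        unknown_sp = set(family.species_ids) - set(taxonomy.species)
        if unknown_sp:
            raise ValidationError(
                f"species absent from taxonomy: {sorted(unknown_sp)}"
            )
    return clusters, taxonomy, matrices


# ---------------------------------------------------------------------------
# curation


def apply_curation_flags(
    family: AlignedFamily, flags: Mapping[str, str]
) -> AlignedFamily:
    """Drop sequences flagged ``pseudogene`` or ``fragment``.

    Unflagged sequences default to ``ok``; flags for unknown ids are ignored
    with a warning. Manual curation beyond these explicit flags (removal of
    sequences with large unique indels) is expert judgment and is not
    reproduced algorithmically.
    """
    known = set(family.seq_ids)
    stray = set(flags) - known
    if stray:
        warnings.warn(f"curation flags for unknown ids ignored: {sorted(stray)}")
    drop = {
        sid for sid, flag in flags.items()
        if sid in known and flag in {"pseudogene", "fragment"}
    }
    kept = [r for r in family.records if r[0] not in drop]
    if not kept:
        raise ValidationError("curation removed every sequence in the family")
    if drop:
        warnings.warn(f"curation removed {len(drop)} sequence(s)")
    return AlignedFamily(tuple(kept))


def load_top_positions() -> pd.DataFrame:
    """The published table of top predictive alignment positions.

    Ten positions per chemical-response dataset (1 = *D. melanogaster*,
    2 = *A. gambiae*, 3 = *H. saltator*) with their times-predictive counts
    and the corresponding *D. melanogaster* / *A. bakeri* Orco residue
    numbers, as distributed with the iOrME resource. Unmapped positions
    carry ``-``.
    """
    path = Path(__file__).parent / "data" / "top_positions.tsv"
    return pd.read_csv(path, sep="\t", dtype={"dataset": int, "times_predictive": int, "alignment_position": int})
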