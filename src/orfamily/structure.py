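"""Mapping alignment columns to reference and template residue numbers.

Predictive alignment positions are interpreted structurally by composing
two partial maps: alignment column -> residue number of a linking reference
sequence present in the alignment (the *D. melanogaster* Orco co-receptor
in the published analysis), and reference residue -> residue number of a
homologous template for which a 3D structure exists (*A. bakeri* Orco,
PDB 6C70). The template is consumed as a plain sequence plus a numbering
offset; no structure files are parsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import GAP, AlignedFamily

log = logging.getLogger(__name__)


@dataclass
class PositionMap:
    """Partial maps from alignment columns through reference to template.

    ``column_to_ref`` and ``ref_to_template`` are strictly increasing over
    their mapped entries; unmapped positions are simply absent.
    """

    reference_id: str
    template_id: str
    column_to_ref: dict[int, int]
    ref_to_template: dict[int, int]

    def column_to_template(self, column: int) -> int | None:
        ref = self.column_to_ref.get(column)
        if ref is None:
            return None
        return self.ref_to_template.get(ref)


def column_to_reference(
    family: AlignedFamily, reference_seq_id: str
) -> dict[int, int]:
    """Map each alignment column to the reference's 1-based residue number.

    Column ``p`` maps to the count of non-gap reference characters up to
    and including ``p`` when the reference is not gapped at ``p``; columns
    where the reference carries a gap are unmapped.
    """
    seq = family.sequence(reference_seq_id)
    mapping: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            residue += 1
            mapping[col] = residue
    return mapping


def reference_to_template(
    reference_seq: str,
    template_seq: str,
    numbering_offset: int = 0,
    matrix: str = "BLOSUM62",
    open_gap_score: float = -10.0,
    extend_gap_score: float = -0.5,
    identity_floor: float = 0.2,
) -> dict[int, int]:
    """Residue-number correspondence from a pairwise global alignment.

    Both inputs are ungapped sequences. A global alignment (substitution
    matrix and affine gap penalties as configured, logged) pairs residues;
    template numbers are shifted by ``numbering_offset`` to match the
    structure's numbering. A warning is emitted when alignment identity
    falls below ``identity_floor``.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = open_gap_score
    aligner.extend_gap_score = extend_gap_score
    log.info(
        "pairwise alignment: matrix=%s open=%s extend=%s",
        matrix, open_gap_score, extend_gap_score,
    )
    aln = aligner.align(reference_seq, template_seq)[0]
    mapping: dict[int, int] = {}
    identical = 0
    for (r_start, r_end), (t_start, t_end) in zip(*aln.aligned):
        for i in range(r_end - r_start):
            r_pos, t_pos = r_start + i, t_start + i
            mapping[r_pos + 1] = t_pos + 1 + numbering_offset
            if reference_seq[r_pos] == template_seq[t_pos]:
                identical += 1
    identity = identical / max(len(reference_seq), len(template_seq))
    if identity < identity_floor:
        log.warning(
            "reference-template identity %.1f%% below %.0f%%: mapping may "
            "be unreliable", 100 * identity, 100 * identity_floor,
        )
    return mapping


def build_position_map(
    family: AlignedFamily,
    reference_seq_id: str,
    template_seq: str,
    template_id: str = "template",
    numbering_offset: int = 0,
    **align_kwargs,
) -> PositionMap:
    col2ref = column_to_reference(family, reference_seq_id)
    ref_seq = family.sequence(reference_seq_id).replace(GAP, "")
    ref2tmpl = reference_to_template(
        ref_seq, template_seq, numbering_offset, **align_kwargs
    )
    return PositionMap(
        reference_id=reference_seq_id,
        template_id=template_id,
        column_to_ref=col2ref,
        ref_to_template=ref2tmpl,
    )


def emit_annotation(
    positions: set[int],
    position_map: PositionMap,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Annotation table for a set of alignment positions.

    Columns: alignment position, reference residue number, template residue
    number, label. Unmapped entries carry ``-``.
    """
    labels = labels or {}
    rows = []
    for pos in sorted(positions):
        ref = position_map.column_to_ref.get(pos)
        tmpl = None if ref is None else position_map.ref_to_template.get(ref)
        rows.append(
            (
                pos,
                "-" if ref is None else ref,
                "-" if tmpl is None else tmpl,
                labels.get(pos, "unmapped" if ref is None else "top10"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "alignment_position", "reference_residue", "template_residue", "label",
        ],
    )
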