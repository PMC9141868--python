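"""The machine-learning design table: residues by alignment position.

A *variable* is an alignment position (a table column); a *feature* is a
specific amino acid at that position. The gap character ``-`` is a
first-class category, since indel presence can itself be predictive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import AlignedFamily

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Residue-per-position design table over a sequence subset.

    ``data`` has one row per sequence and one (single-character) column per
    retained alignment position; column labels are 1-based positions.
    """

    data: pd.DataFrame

    @property
    def seq_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def retained_positions(self) -> list[int]:
        return list(self.data.columns)


def build_feature_table(
    family: AlignedFamily, subset: Iterable[str] | None = None
) -> FeatureTable:
    """One row per sequence in ``subset``, one column per alignment column."""
    if subset is None:
        subset = family.seq_ids
    subset = list(subset)
    if not subset:
        raise ValueError("empty sequence subset")
    df = family.to_dataframe().loc[subset]
    return FeatureTable(df)


def filter_near_zero_variance(
    table: FeatureTable, freq_cut: float = 19.0, unique_cut: float = 10.0
) -> FeatureTable:
    """Drop constant and near-constant columns.

    A column is dropped when it is constant, or when the frequency ratio of
    its most-common to second-most-common category exceeds ``freq_cut``
    *and* its number of distinct categories is below ``unique_cut`` percent
    of the number of rows (the conventional 95/5 + 10% near-zero-variance
    rule).
    """
    n = len(table.data)
    keep: list[int] = []
    for col in table.data.columns:
        counts = table.data[col].value_counts()
        if len(counts) < 2:
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = 100.0 * len(counts) / n
        if ratio > freq_cut and pct_unique < unique_cut:
            continue
        keep.append(col)
    dropped = len(table.data.columns) - len(keep)
    if dropped:
        log.info("near-zero-variance filter dropped %d column(s)", dropped)
    if not keep:
        raise ValueError(
            "every column was dropped as near-zero-variance; "
            "consider a smaller freq_cut"
        )
    return FeatureTable(table.data[keep])
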