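"""Training-chemical selection and response binarization.

Chemicals are admitted to training when the union of the datasets holds
strictly more than ``min_values`` tested (protein, chemical) cells for them.
Responses are binarized per dataset and per chemical at that chemical's
75th percentile: values strictly above the threshold become 1 (responder),
the rest 0; untested cells stay missing. Binarization never pools values
across datasets, so differing measurement units cannot leak between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ResponseMatrix


@dataclass(frozen=True)
class ChemicalSelection:
    """Chemicals admitted to model training, most-tested first."""

    chemicals: tuple[str, ...]
    counts: dict[str, int]
    threshold: int

    def __post_init__(self) -> None:
        assert all(self.counts[c] > self.threshold for c in self.chemicals)


def select_chemicals(
    matrices: list[ResponseMatrix], min_values: int = 100
) -> ChemicalSelection:
    """Chemicals with more than ``min_values`` tested cells across datasets.

    Sorted by count descending; ties broken by chemical id for determinism.
    The bound is strict: a chemical with exactly ``min_values`` cells is
    not selected.
    """
    if not matrices:
        raise ValueError("need at least one response matrix")
    total: dict[str, int] = {}
    for m in matrices:
        for chem, n in m.defined_counts().items():
            total[chem] = total.get(chem, 0) + int(n)
    selected = sorted(
        (c for c, n in total.items() if n > min_values),
        key=lambda c: (-total[c], c),
    )
    return ChemicalSelection(tuple(selected), total, min_values)


def binarize(
    matrix: ResponseMatrix,
    percentile: float = 75.0,
    method: str = "linear",
) -> ResponseMatrix:
    """Binarize each chemical's responses at its own percentile threshold.

    The threshold is the ``percentile``-th percentile of the chemical's
    defined values within this dataset, computed by linear interpolation
    between order statistics (``method="nearest"`` switches to the
    nearest-rank convention). Cells strictly above the threshold become 1;
    ties at the threshold and everything below become 0; missing stays
    missing. All-missing chemicals are left missing with a warning.
    """
    if method not in {"linear", "nearest"}:
        raise ValueError(f"unknown percentile method {method!r}")
    out = pd.DataFrame(
        np.nan, index=matrix.values.index, columns=matrix.values.columns
    )
    for chem in matrix.values.columns:
        col = matrix.values[chem]
        defined = col.dropna()
        if defined.empty:
            warnings.warn(
                f"chemical {chem!r} has no defined values in dataset "
                f"{matrix.dataset_id!r}; left missing"
            )
            continue
        threshold = float(np.percentile(defined.to_numpy(), percentile, method=method))
        out[chem] = (col > threshold).astype(float).where(col.notna())
    return ResponseMatrix(
        dataset_id=matrix.dataset_id, values=matrix.values, binarized=out
    )
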