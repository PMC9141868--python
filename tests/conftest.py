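import numpy as np
import pandas as pd
import pytest

from orfamily.io import AlignedFamily, ClusterAssignment, ResponseMatrix, Taxonomy


@pytest.fixture
def tiny_family() -> AlignedFamily:
    """Four sequences from two species, five columns."""
    return AlignedFamily(
        (
            ("Sp1_a", "Sp1", "ACDE-"),
            ("Sp1_b", "Sp1", "ACDEF"),
            ("Sp2_a", "Sp2", "ACDFF"),
            ("Sp2_b", "Sp2", "AWDFF"),
        )
    )


@pytest.fixture
def tiny_taxonomy() -> Taxonomy:
    return Taxonomy(
        species={"Sp1": True, "Sp2": False},
        taxa={
            "ROOT": frozenset({"Sp1", "Sp2"}),
            "T_Sp1": frozenset({"Sp1"}),
            "T_Sp2": frozenset({"Sp2"}),
        },
        parents={"T_Sp1": "ROOT", "T_Sp2": "ROOT"},
    )


@pytest.fixture
def tiny_clusters() -> ClusterAssignment:
    return ClusterAssignment(
        {"Sp1_a": "C0", "Sp1_b": "C0", "Sp2_a": "C0", "Sp2_b": "C1"}
    )


@pytest.fixture
def tiny_matrix() -> ResponseMatrix:
    values = pd.DataFrame(
        {
            "chemA": [0.0, 0.0, 0.0, 10.0],
            "chemB": [1.0, 2.0, np.nan, 4.0],
        },
        index=["Sp1_a", "Sp1_b", "Sp2_a", "Sp2_b"],
    )
    return ResponseMatrix(dataset_id="tiny", values=values)
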