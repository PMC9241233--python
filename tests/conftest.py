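import numpy as np
import pandas as pd
import pytest

from contextnet import (
    ExpressionMatrix,
    FeatureTable,
    FitnessMatrix,
    MutationTable,
    SampleMetadata,
)


@pytest.fixture
def toy_fitness() -> FitnessMatrix:
    """4 genes x 3 cell lines of raw BF, spanning both modes of the distribution."""
    values = pd.DataFrame(
        {
            "CL1": [25.0, -5.0, 12.0, -1.0],
            "CL2": [30.0, -6.0, 9.9, 10.0],
            "CL3": [-8.0, -4.0, 15.0, 3.0],
        },
        index=["GA", "GB", "GC", "GD"],
    )
    return FitnessMatrix(values)


@pytest.fixture
def toy_mutations() -> MutationTable:
    rec = pd.DataFrame(
        [
            ("TP53", "CL1", "damaging", False, False),
            ("TP53", "CL2", "damaging", True, False),
            ("KRAS", "CL1", "other non-conserving", True, False),
            ("KRAS", "CL3", "other non-conserving", False, True),
            ("BRAF", "CL2", "other non-conserving", False, False),  # no hotspot: no feature
            ("EGFR", "CL3", "silent", False, False),  # matches neither rule
        ],
        columns=["gene", "cell_line", "variant_annotation", "is_tcga_hotspot", "is_cosmic_hotspot"],
    )
    return MutationTable(rec)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    values = pd.DataFrame(
        {"CL1": [8.0, 5.5], "CL2": [5.0, 5.0], "CL3": [1.0, 5.0]},
        index=["CDH1", "VIM"],
    )  # ratios: 2.5 (hi), 0.0 (mid), -4.0 (boundary)
    return ExpressionMatrix(values)


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    table = pd.DataFrame(
        {"lineage": ["lung", "lung", "skin"], "sex": ["F", None, "M"]},
        index=pd.Index(["CL1", "CL2", "CL3"], name="cell_line"),
    )
    return SampleMetadata(table)


def make_feature_table(columns: dict[str, list[int]], category: str = "lineage") -> FeatureTable:
    """Small helper: binary FeatureTable from literal columns, one shared category."""
    values = pd.DataFrame(columns, dtype="int8")
    values.index = pd.Index([f"CL{i}" for i in range(len(values))], name="cell_line")
    return FeatureTable(values, pd.Series({name: category for name in values.columns})[values.columns])
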