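import numpy as np
import pandas as pd
import pytest

from metaplast.pathways import PathwayDatabase, PathwayDefinition
from metaplast.scoring import ExpressionMatrix, SampleMetadata


@pytest.fixture
def tiny_db():
    """Three 3-gene pathways with uniform weights."""
    return PathwayDatabase(
        pathways=(
            PathwayDefinition("P1", "one", ("A", "B", "C")),
            PathwayDefinition("P2", "two", ("D", "E", "F")),
            PathwayDefinition("P3", "three", ("G", "H", "I")),
        ),
        source_tag="fixture",
    )


@pytest.fixture
def tiny_expr():
    """Log-scale 9-gene x 4-sample matrix; P1 > P2 > P3 in every sample."""
    genes = list("ABCDEFGHI")
    rng = np.random.default_rng(7)
    base = np.array([6.0] * 3 + [4.0] * 3 + [2.0] * 3)
    values = base[:, None] + rng.normal(0, 0.1, size=(9, 4))
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=[f"S{i}" for i in range(4)]),
        scale_tag="log",
    )


@pytest.fixture
def two_group_meta():
    return SampleMetadata(
        table=pd.DataFrame(
            {"age": [40.0, 42.0, 70.0, 72.0], "group": ["young", "young", "old", "old"]},
            index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"),
        )
    )


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("P1\tdesc one\tG1\tG2\tG3\nP2\tdesc two\tG2\tG4\n")
    return path
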