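import numpy as np
import pandas as pd
import pytest

from organtx.io import CountMatrix, ExpressionMatrix, PipelineConfig


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 samples, two organs x two replicates, hand-checkable."""
    counts = pd.DataFrame(
        {
            "F1": [100, 0, 50],
            "F2": [120, 0, 40],
            "L1": [10, 30, 50],
            "L2": [12, 28, 60],
        },
        index=["g1", "g2", "g3"],
    )
    lengths = pd.Series([2000, 1000, 500], index=["g1", "g2", "g3"])
    organ = {"F1": "F", "F2": "F", "L1": "L", "L2": "L"}
    rep = {"F1": 1, "F2": 2, "L1": 1, "L2": 2}
    return CountMatrix(counts, lengths, organ, rep)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_expression(values: dict, organ: dict, rep: dict | None = None,
                    genes: list | None = None) -> ExpressionMatrix:
    df = pd.DataFrame(values)
    if genes is not None:
        df.index = genes
    else:
        df.index = [f"g{i}" for i in range(len(df))]
    rep = rep or {s: i + 1 for i, s in enumerate(df.columns)}
    return ExpressionMatrix(df.astype(float), organ, rep)
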