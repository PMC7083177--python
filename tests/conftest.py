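import numpy as np
import pandas as pd
import pytest

from admeta.types import ExpressionStudy


@pytest.fixture
def tiny_intensity_study() -> ExpressionStudy:
    """3 genes × 6 samples on the log2 scale, gene Gup shifted up in cases."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(6)]
    group = pd.Series(["case"] * 3 + ["control"] * 3, index=samples)
    values = pd.DataFrame(
        rng.normal(8.0, 0.3, size=(3, 6)),
        index=["Gup", "Gnull1", "Gnull2"],
        columns=samples,
    )
    values.loc["Gup", group == "case"] += 3.0
    return ExpressionStudy("T0", "hippocampus", "intensity", values, group, log_scale=True)


@pytest.fixture
def grouped_matrix():
    """10 genes × 8 samples with labels, for direct test-statistic checks."""
    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(8)]
    group = pd.Series(["case"] * 4 + ["control"] * 4, index=samples)
    matrix = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(10, 8)),
        index=[f"G{i}" for i in range(10)],
        columns=samples,
    )
    return matrix, group
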