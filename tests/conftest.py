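import numpy as np
import pandas as pd
import pytest

from ffpeqc import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Two groups x three paired replicates, 4 genes, log2 scale."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8.0, 1.5, (4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=["FF_1", "FF_2", "FF_3", "FFPE_1", "FFPE_2", "FFPE_3"],
    )
    groups = {c: ("FF" if c.startswith("FF_") else "FFPE") for c in values.columns}
    pairing = {c: int(c.split("_")[-1]) for c in values.columns}
    return ExpressionMatrix(values=values, scale="log2", groups=groups, pairing=pairing)


def make_matrix(values: np.ndarray, groups: dict[str, str], scale: str = "log2") -> ExpressionMatrix:
    cols = list(groups)
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols)
    return ExpressionMatrix(values=df, scale=scale, groups=groups)
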