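import numpy as np
import pandas as pd
import pytest

from coexnet.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_expr(rng):
    """20 genes x 10 samples of plain noise."""
    data = pd.DataFrame(
        rng.standard_normal((20, 10)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"S{j}" for j in range(10)],
    )
    return ExpressionMatrix(data)


def make_expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
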