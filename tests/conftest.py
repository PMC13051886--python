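import numpy as np
import pandas as pd
import pytest

from mircell.diffexpr import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """6-sample, 5-feature log2 matrix with known means."""
    vals = pd.DataFrame(
        {
            "s1": [10.0, 9, 8, 7, 6],
            "s2": [10.1, 9.1, 8.1, 7.1, 6.1],
            "s3": [9.9, 8.9, 7.9, 6.9, 5.9],
            "s4": [10.0, 9, 8, 7, 6],
            "s5": [10.2, 9.2, 8.2, 7.2, 6.2],
            "s6": [9.8, 8.8, 7.8, 6.8, 5.8],
        },
        index=[f"f{i}" for i in range(1, 6)],
    )
    ann = pd.DataFrame(
        {"group": ["case"] * 3 + ["control"] * 3}, index=vals.columns
    )
    return ExpressionMatrix(vals, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
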