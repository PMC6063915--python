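import numpy as np
import pandas as pd
import pytest

from procnet.expression import ExpressionMatrix, SampleGroup
from procnet.gsea import Contrast


def make_matrix(rows, row_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array-like (rows x samples)."""
    arr = np.asarray(rows, dtype=float)
    if row_ids is None:
        row_ids = [f"g{i + 1}" for i in range(arr.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=row_ids, columns=sample_ids))


def make_contrast(test_ids, ref_ids) -> Contrast:
    return Contrast(
        SampleGroup("test", tuple(test_ids)), SampleGroup("ref", tuple(ref_ids))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
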