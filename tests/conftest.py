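import numpy as np
import pandas as pd
import pytest

from dieltx.matrixio import ExpressionMatrix, Scale, matrix_from_frame
from dieltx.timecourse import UCYNA_LABELS, parse_series


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def ucyna_timepoints():
    return parse_series(UCYNA_LABELS)


@pytest.fixture
def ucyna_hours(ucyna_timepoints):
    return np.array([tp.absolute_hour for tp in ucyna_timepoints])


def _make_matrix(values, labels, scale=Scale.LOG2, gene_ids=None, dark_first=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=gene_ids, columns=list(labels))
    return matrix_from_frame(df, scale, dark_first=dark_first)


@pytest.fixture
def make_matrix():
    """Factory: build an ExpressionMatrix from an array and column labels."""
    return _make_matrix
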