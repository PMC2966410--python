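import numpy as np
import pandas as pd
import pytest

from swangtest.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20231104)


def make_matrix(values, n_case, n_control, gene_ids=None):
    """Build an ExpressionMatrix from a (genes, n_case + n_control) array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    case_ids = [f"c{j}" for j in range(n_case)]
    control_ids = [f"k{j}" for j in range(n_control)]
    data = pd.DataFrame(values, index=genes, columns=case_ids + control_ids)
    groups = {s: "case" for s in case_ids} | {s: "control" for s in control_ids}
    return ExpressionMatrix(data, groups)


@pytest.fixture
def toy_matrix():
    """2 genes x 4 samples (2 case / 2 control)."""
    return make_matrix([[1.0, 2.0, 3.0, 4.0], [5.0, 5.5, 4.5, 5.0]], 2, 2)
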