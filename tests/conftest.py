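import numpy as np
import pandas as pd
import pytest

from cernet.matrix import ExpressionMatrix


def make_matrix(values: np.ndarray, n_pairs: int, feature_ids=None) -> ExpressionMatrix:
    """Paired tumor/normal matrix; columns alternate P01_T, P01_N, ..."""
    cols, rows = [], []
    for i in range(1, n_pairs + 1):
        cols += [f"P{i:02d}_T", f"P{i:02d}_N"]
        rows += [(f"P{i:02d}_T", "tumor", f"P{i:02d}"), (f"P{i:02d}_N", "normal", f"P{i:02d}")]
    meta = pd.DataFrame(rows, columns=["sample_id", "condition", "pair_id"]).set_index("sample_id")
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"F{i:03d}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=cols), meta=meta
    )


@pytest.fixture
def paired_matrix():
    """Two features, four pairs, with known tumor-normal differences."""
    # feature 0: diff +1 per pair; feature 1: diff 0
    vals = np.array(
        [
            [9.0, 8.0, 9.5, 8.5, 8.8, 7.8, 9.2, 8.2],
            [8.0, 8.0, 8.4, 8.4, 7.9, 7.9, 8.1, 8.1],
        ]
    )
    return make_matrix(vals, n_pairs=4)
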