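import numpy as np
import pandas as pd
import pytest

from mirsys.io import ExpressionDataset


def make_dataset(values, probe_names=None, n_disease=None):
    """ExpressionDataset from a 2-D array; first n_disease columns = disease."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if probe_names is None:
        probe_names = [f"hsa-mir-t{i:03d}" for i in range(n_probes)]
    if n_disease is None:
        n_disease = n_samples // 2
    samples = ([f"PD_{i:02d}" for i in range(n_disease)]
               + [f"CT_{i:02d}" for i in range(n_samples - n_disease)])
    groups = pd.Series(["disease"] * n_disease
                       + ["control"] * (n_samples - n_disease), index=samples)
    return ExpressionDataset(pd.DataFrame(values, index=probe_names,
                                          columns=samples), groups)


@pytest.fixture
def tiny_dataset():
    """Two probes, three-vs-three samples, hand-checkable numbers."""
    return make_dataset([[3, 4, 5, 1, 2, 3],
                         [1, 1, 1, 1, 1, 1]], n_disease=3)
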