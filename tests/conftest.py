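import numpy as np
import pandas as pd
import pytest

from premodmir import CtMatrix


def make_ct(values, feature_ids=None, sample_ids=None, metadata=None, **kwargs):
    """Build a CtMatrix from a 2-D array (NaN = nondetect)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"hsa-miR-t{i:03d}" for i in range(n_feat)]
    if sample_ids is None:
        sample_ids = [f"S{j:03d}" for j in range(n_samp)]
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return CtMatrix(df, metadata=metadata, **kwargs)


@pytest.fixture
def small_ct():
    """6 features x 4 samples, all detected, Cq around 25."""
    rng = np.random.default_rng(42)
    return make_ct(25 + rng.normal(0, 1, size=(6, 4)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
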