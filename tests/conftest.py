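import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from polypcontinuum.core import CountsMatrix
from polypcontinuum.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced synthetic cohort shared by read-only tests."""
    return generate_cohort(SimConfig.small(seed=42))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig.small(seed=42)


@pytest.fixture()
def tiny_counts():
    """3 features x 4 cells, two samples, fully deterministic."""
    values = sp.csr_matrix(
        np.array([[0, 1, 5, 0], [2, 0, 0, 3], [1, 1, 1, 1]], dtype=np.int64)
    )
    barcodes = np.array(["c1", "c2", "c3", "c4"], dtype=object)
    return CountsMatrix(
        values=values,
        feature_ids=np.array(["f1", "f2", "f3"], dtype=object),
        feature_kind="peak",
        barcodes=barcodes,
        sample_of=pd.Series(["s1", "s1", "s2", "s2"], index=barcodes),
    )
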