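import numpy as np
import pandas as pd
import pytest

from permomics import OmicsMatrix, ComparisonSpec


def make_matrix(values, layer="protein", groups=None):
    """Small matrix helper: values is 2-D, samples s0..sn, one 'group' column."""
    values = np.asarray(values, dtype=float)
    ids = [f"g{i:03d}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    if groups is None:
        half = values.shape[1] // 2
        groups = ["a"] * half + ["b"] * (values.shape[1] - half)
    meta = pd.DataFrame({"sample_id": cols, "group": groups}).set_index("sample_id")
    return OmicsMatrix(pd.DataFrame(values, index=ids, columns=cols), meta, layer)


@pytest.fixture
def null_matrix_3v3():
    """60 all-null features, 3 vs 3, standard normal."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(0, 1, (60, 6)))


@pytest.fixture
def spec_3v3():
    return ComparisonSpec(
        group_a=["s0", "s1", "s2"], group_b=["s3", "s4", "s5"],
        n_permutations=1000, seed=0, exhaustive_if_possible=True,
    )
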