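import numpy as np
import pandas as pd
import pytest

from germid import GenotypeMatrix, PassportTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240104)


@pytest.fixture
def small_matrix():
    """4 samples x 4 loci with one missing call."""
    calls = np.array(
        [
            [0, 1, 2, 0],
            [0, 2, 2, 1],
            [0, 0, 2, 0],
            [2, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    missing = np.zeros((4, 4), dtype=bool)
    missing[1, 3] = True
    return GenotypeMatrix(
        ["s1", "s2", "s3", "s4"], ["L1", "L2", "L3", "L4"], calls, missing
    )


def make_matrix(calls, missing=None, prefix="s"):
    calls = np.asarray(calls, dtype=np.int8)
    ids = [f"{prefix}{i}" for i in range(calls.shape[0])]
    loci = [f"L{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(ids, loci, calls, missing)


def make_passport(codes, names=None, species=None, replicate_group=None):
    n = len(codes)
    return PassportTable(
        pd.DataFrame(
            {
                "clone_code": codes,
                "clone_name": names if names is not None else list(codes),
                "recorded_species": species if species is not None else ["A"] * n,
                "replicate_group": replicate_group if replicate_group is not None
                else [None] * n,
            }
        )
    )
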