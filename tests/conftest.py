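import numpy as np
import pytest

from ydna.core import GenotypeMatrix, MutationRateSpec, RegionSet
from ydna.tree import default_df27_tree


def mk_matrix(calls, positions=None, sample_ids=None, snp_names=None):
    """Build a GenotypeMatrix from a 2-D array-like of 0/1/-1 calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = list(range(100, 100 + 10 * m, 10))
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if snp_names is None:
        snp_names = [f"snp{j}" for j in range(m)]
    alleles = [("A", "G")] * m
    return GenotypeMatrix(sample_ids, snp_names, positions, alleles, calls)


@pytest.fixture
def rate():
    return MutationRateSpec()


@pytest.fixture
def small_regions():
    return RegionSet([(1_000, 26_000), (40_000, 55_000), (60_000, 72_500)])


@pytest.fixture
def df27_tree():
    return default_df27_tree()
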