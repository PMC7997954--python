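import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nucleofoot.io import FragmentSet, TssTable

settings.register_profile(
    "suite",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_fragment_set(rng, n, chroms=("chr1",), span=100_000, sample_id="s1",
                      min_len=60, max_len=260):
    """Random fragment fixture used by oracle-equivalence tests."""
    chrom = rng.choice(np.array(chroms, dtype=object), size=n)
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(min_len, max_len, size=n)
    return FragmentSet(sample_id=sample_id, chroms=chrom, starts=starts,
                       ends=starts + lengths)


def make_tss_table(rng, n, chroms=("chr1",), span=100_000):
    pos = rng.integers(2000, span - 2000, size=n)
    strand = rng.choice(np.array(["+", "-"], dtype=object), size=n)
    chrom = rng.choice(np.array(chroms, dtype=object), size=n)
    return TssTable(pd.DataFrame(
        {"chrom": chrom, "tss": pos, "strand": strand},
        index=pd.Index([f"G{i:04d}" for i in range(n)], name="gene_id"),
    ))


@pytest.fixture
def random_fragments(rng):
    return make_fragment_set(rng, 500)


@pytest.fixture
def random_tss(rng):
    return make_tss_table(rng, 20)
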