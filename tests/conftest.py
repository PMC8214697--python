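import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scwga.genome import Genome
from scwga.coverage import CoverageProfile

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_profile(counts, bin_size=100, chrom="c1", masked=None):
    counts = list(counts)
    n = len(counts)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * bin_size,
        "end": (np.arange(n) + 1) * bin_size,
        "count": counts,
        "masked": masked if masked is not None else [False] * n,
    })
    return CoverageProfile(df, bin_size)


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(20_240_901)
    seq = "".join(rng.choice(list("ACGT"), size=50_000))
    return Genome({"chr1": seq})


@pytest.fixture
def two_chrom_genome():
    rng = np.random.default_rng(7)
    return Genome(
        {
            "chr1": "".join(rng.choice(list("ACGT"), size=12_000)),
            "chr2": "".join(rng.choice(list("ACGT"), size=8_000)),
        },
        masks={"chr1": [(4_000, 5_000)]},
    )
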