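import numpy as np
import pytest

import survscan as ss


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def staggered_pheno():
    """Three subjects: (0, event@1), (0, censor@3), (1.5, event@2)."""
    return ss.SurvivalPhenotype(
        entry=[0.0, 0.0, 1.5], exit=[1.0, 3.0, 2.0], status=[1, 0, 1]
    )


def random_staggered_pheno(rng, n=40, censor_frac=0.4):
    entry = rng.uniform(0, 1, n)
    exit_ = entry + rng.exponential(1.5, n)
    status = (rng.uniform(size=n) > censor_frac).astype(int)
    if status.sum() == 0:
        status[0] = 1
    return ss.SurvivalPhenotype(entry, exit_, status)
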