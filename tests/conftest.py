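import numpy as np
import pytest

from mitopool.simulate import CircularGenome, PlatformProfile, simulate_reads


@pytest.fixture(scope="session")
def random_genome():
    """A 5 kb random circular genome with mitogenome-like composition."""
    rng = np.random.default_rng(20160609)
    seq = "".join(rng.choice(list("ACGT"), 5000, p=[0.31, 0.26, 0.14, 0.29]))
    return CircularGenome(id="toy", seq=seq)


@pytest.fixture(scope="session")
def clean_reads(random_genome):
    """Error-free ~100 bp reads at 20x coverage of the toy genome."""
    profile = PlatformProfile(name="hiseq", mean_read_len=100, read_len_sd=5,
                              yield_reads=1000)
    return simulate_reads(random_genome, profile, seed=7)
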