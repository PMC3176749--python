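import numpy as np
import pytest

from pairfuse.synthetic_data import LocusSpec, build_locus


@pytest.fixture(scope="session")
def locus():
    """The default two-gene fusion locus used across the suite."""
    return build_locus(LocusSpec(), seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_genome(rng):
    from pairfuse.refalign import Genome

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=3000).tobytes().decode()
    return Genome({"toy": seq})
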