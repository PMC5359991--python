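import pytest

from refqzip import MapperConfig
from refqzip.fixtures import FixtureSpec, gen_records, gen_reference


@pytest.fixture(scope="session")
def small_config():
    """Mapper config with a short k so tiny hand-written references index."""
    return MapperConfig(k=4, prefix=b"CG", L=4, e=0.1, segment_len=8)


@pytest.fixture(scope="session")
def default_config():
    return MapperConfig()


@pytest.fixture(scope="session")
def std_fixture():
    """A mid-size synthetic dataset shared across mapper/container tests."""
    spec = FixtureSpec(seed=34, ref_len=30_000, n_reads=400, read_len=100,
                       sub_rate=0.02, revcomp_frac=0.3, junk_frac=0.05, n_frac=0.02)
    ref = gen_reference(spec)
    records, truths = gen_records(spec, ref)
    return spec, ref, records, truths
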