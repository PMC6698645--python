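import pytest
from hypothesis import HealthCheck, settings

from mitofibre import pipeline
from mitofibre.mtgenome import load_genome_map

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures():
    return pipeline.load_reference_tables()


@pytest.fixture(scope="session")
def deletion_table(fixtures):
    return fixtures["deletions"]


@pytest.fixture(scope="session")
def smpcr_table(fixtures):
    return fixtures["smpcr"]


@pytest.fixture(scope="session")
def rcrs_map():
    return load_genome_map()
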