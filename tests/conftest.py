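import pytest

from zonemap import ZoneModel, make_fixture, normalize_table
from zonemap.simulate import PACKAGED_SEEDS

#: single seed used for the shared session fixtures (first packaged seed)
FIXTURE_SEED = PACKAGED_SEEDS[0]


@pytest.fixture(scope="session")
def raw_table():
    return make_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def normalized(raw_table):
    return normalize_table(raw_table)


@pytest.fixture(scope="session")
def results(normalized):
    return ZoneModel(normalized).fit(seed=FIXTURE_SEED)
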