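import pytest

from capko.database_io import build_database
from capko.datamodel import load_config, scale_from_config


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def scale(config):
    """Default (computation-consistent) five-level spiciness scale."""
    return scale_from_config(config)


@pytest.fixture(scope="session")
def narrative_scale(config):
    return scale_from_config(config, "narrative")


@pytest.fixture(scope="session")
def built_db(config):
    """One shared full database build: (entries, report)."""
    return build_database(config)


@pytest.fixture(scope="session")
def db_by_name(built_db):
    entries, _ = built_db
    return {e.name: e for e in entries}
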