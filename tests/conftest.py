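import pytest

from bhlhsurvey.domain_profile import default_profile, load_site_config
from bhlhsurvey.gene_structure import load_registry


@pytest.fixture(scope="session")
def site_config():
    return load_site_config()


@pytest.fixture(scope="session")
def profile(site_config):
    return default_profile(site_config)


@pytest.fixture(scope="session")
def registry():
    return load_registry()
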