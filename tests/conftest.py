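import pytest

from ichnos import calibration
from ichnos.io import summaries_from_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return calibration.load_all_fixtures()


@pytest.fixture(scope="session")
def specs(fixtures):
    return calibration.recover_paper_specs(fixtures)


@pytest.fixture(scope="session")
def summaries(fixtures):
    return summaries_from_fixtures(fixtures)
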