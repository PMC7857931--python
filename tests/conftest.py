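import pytest

from flavonet.candidate_library import generate_candidates, load_preset
from flavonet.synthetic_data import reference_standards, table1_fixture


@pytest.fixture(scope="session")
def extended_skeletons():
    return load_preset("extended")


@pytest.fixture(scope="session")
def full_library(extended_skeletons):
    """Workflow library: ten aglycones, <=1 phase I, <=3 phase II, C30H60O20."""
    return generate_candidates(extended_skeletons)


@pytest.fixture(scope="session")
def fixture_data():
    records, rows = table1_fixture()
    return records, rows


@pytest.fixture(scope="session")
def standards():
    return reference_standards()
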