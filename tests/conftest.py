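import pytest

from diagval import PairedTable, ReferenceProfile, study_fixture_table


@pytest.fixture(scope="session")
def study_table() -> PairedTable:
    """The 2x2 table reconstructed from the study's printed summaries."""
    return study_fixture_table()


@pytest.fixture(scope="session")
def mammogram_profile() -> ReferenceProfile:
    """The imperfect reference's operating characteristics."""
    return ReferenceProfile(alpha=0.869, beta=0.889)
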