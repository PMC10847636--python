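import pytest

from fallscreen import build_fixture, write_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 416-patient constraint-solution cohort."""
    return build_fixture()


@pytest.fixture(scope="session")
def fixture_csv(fixture_cohort, tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort") / "fixture.csv"
    write_cohort(fixture_cohort, path)
    return path
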