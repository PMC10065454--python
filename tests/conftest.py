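import pytest

from washera import demography, washera_fixture, scaling


@pytest.fixture(scope="session")
def fixture():
    return washera_fixture()


@pytest.fixture(scope="session")
def demog_table(fixture):
    return demography.demography_table(fixture.clusters, fixture.rates)


@pytest.fixture(scope="session")
def demog_report(demog_table):
    return demography.demography_report(demog_table)


@pytest.fixture(scope="session")
def upscale_table(fixture, demog_report):
    return scaling.upscaling_table(fixture.clusters, demog_report, fixture.rates)
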