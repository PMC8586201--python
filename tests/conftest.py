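import pytest

from empacea import (
    MarkovCEA,
    taiwan_base,
    taiwan_distributions,
    taiwan_settings,
)


@pytest.fixture(scope="session")
def setting():
    return taiwan_base()


@pytest.fixture(scope="session")
def distributions():
    return taiwan_distributions()


@pytest.fixture(scope="session")
def settings():
    return taiwan_settings()


@pytest.fixture(scope="session")
def model(setting, distributions, settings):
    return MarkovCEA(setting, settings=settings, distributions=distributions)


@pytest.fixture(scope="session")
def base_results(model):
    return model.fit()
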