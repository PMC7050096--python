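import pytest

import nsclc_cea as nc


@pytest.fixture(scope="session")
def us_inputs():
    return nc.default_inputs("US")


@pytest.fixture(scope="session")
def cn_inputs():
    return nc.default_inputs("CN")


@pytest.fixture(scope="session")
def us_model():
    return nc.build_model(nc.load_config(nc.example_config_path("us")))


@pytest.fixture(scope="session")
def cn_model():
    return nc.build_model(nc.load_config(nc.example_config_path("cn")))
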