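import numpy as np
import pytest

from pollengel import ExineShell, default_gel, environment


@pytest.fixture
def gel():
    return default_gel()


@pytest.fixture
def shell():
    return ExineShell()


@pytest.fixture
def env_ph7():
    return environment(7.0, KCl=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
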