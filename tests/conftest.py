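import pytest

import olfpt
from olfpt.synthetic import S_L_TRUE, S_W_TRUE


@pytest.fixture(scope="session")
def default_config():
    return olfpt.default_study_config(seed=20150429)


@pytest.fixture(scope="session")
def default_study(default_config):
    """One realization of the six-test, 38-participant campaign."""
    return olfpt.generate_study(default_config)


@pytest.fixture(scope="session")
def noise_free_config():
    return olfpt.default_study_config(
        seed=7,
        s_w_true={c: 0.0 for c in S_W_TRUE},
        s_L_true={c: 0.0 for c in S_L_TRUE},
        dosing_drift_rel=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    """Same campaign with all noise sources switched off."""
    return olfpt.generate_study(noise_free_config)
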