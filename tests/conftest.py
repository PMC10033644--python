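import warnings

import numpy as np
import pytest

from preypatterns.fixtures import get_fixture


@pytest.fixture(autouse=True)
def _quiet_permissive_warning():
    # fig4's l=-2 permissive entry warns on construction; tests that care
    # about the warning assert it explicitly
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def fig3():
    return get_fixture("fig3")


@pytest.fixture
def fig5():
    return get_fixture("fig5")


@pytest.fixture
def fig7():
    return get_fixture("fig7")


def random_model_params(rng, n, allee=True):
    """Seeded stream of valid dimensionless parameter sets."""
    from preypatterns.model_core import ModelParams

    for _ in range(n):
        yield ModelParams(
            l=float(rng.uniform(-0.9, 0.9)) if allee else 0.0,
            beta=float(rng.uniform(0.1, 12.0)),
            a=float(rng.uniform(0.05, 12.0)),
            b=float(rng.uniform(0.05, 6.0)),
            d=float(rng.uniform(0.05, 1.0)),
            allee=allee,
        )
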