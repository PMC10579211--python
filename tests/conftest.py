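import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from petiq.phantom import GridSpec, PhantomSpec, build_nema_phantom
from petiq.pipeline import beta_sweep

#: single experiment seed for every stochastic fixture in the suite
SUITE_SEED = 17


@pytest.fixture(scope="session")
def phantom_2d():
    return build_nema_phantom(PhantomSpec.for_lbr(4), GridSpec.fast_2d())


@pytest.fixture(scope="session")
def phantom_3d():
    return build_nema_phantom(PhantomSpec.for_lbr(4), GridSpec.default_3d())


@pytest.fixture(scope="session")
def sweep_lbr4():
    """Full beta sweep at LBR 4:1 under the default study conditions."""
    return beta_sweep(lbr=4, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def sweeps_all_lbr(sweep_lbr4):
    """Sweeps at all three lesion-to-background ratios."""
    return {
        2: beta_sweep(lbr=2, seed=SUITE_SEED),
        4: sweep_lbr4,
        8: beta_sweep(lbr=8, seed=SUITE_SEED),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
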