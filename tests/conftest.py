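import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def applicator():
    from brachydmf.geometry import build_applicator

    return build_applicator()


@pytest.fixture(scope="session")
def kernel(applicator):
    """Session kernel (symmetrized) for planning/grid tests."""
    from brachydmf.tg43 import derive_kernel
    from brachydmf.transport import EngineConfig

    return derive_kernel(EngineConfig(n_histories=2_500_000, seed=101))


@pytest.fixture(scope="session")
def kernel_raw(applicator):
    """Unsymmetrized kernel for checking the mirror-symmetry property."""
    from brachydmf.tg43 import derive_kernel
    from brachydmf.transport import EngineConfig

    return derive_kernel(
        EngineConfig(n_histories=1_500_000, seed=103), symmetrize=False
    )


@pytest.fixture(scope="session")
def sym_plan(applicator, kernel):
    from brachydmf.planning import make_symmetric_plan

    return make_symmetric_plan(applicator, kernel)


@pytest.fixture(scope="session")
def asym_plan(applicator, kernel):
    from brachydmf.planning import make_asymmetric_plan

    return make_asymmetric_plan(applicator, kernel)
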