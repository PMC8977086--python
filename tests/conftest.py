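import pytest
from hypothesis import HealthCheck, settings

from preterm_fahp import (
    Dimension,
    Factor,
    RiskHierarchy,
    default_case_scale,
    default_comparison_scale,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def case_scale():
    return default_case_scale()


@pytest.fixture(scope="session")
def comparison_scale():
    return default_comparison_scale()


@pytest.fixture(scope="session")
def uniform_hierarchy():
    """Six dimensions x three factors, all weights uniform."""
    dims = []
    for j in range(6):
        factors = tuple(Factor(f"f{j}_{i}", 1 / 3) for i in range(3))
        dims.append(Dimension(f"dim{j}", 1 / 6, factors))
    return RiskHierarchy(goal="toy", dimensions=tuple(dims))
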