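import numpy as np
import pytest

from toftskit import AIFModel, AcquisitionParams, GridGeometry, PhantomSpec

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=30,
                              database=None, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def aif() -> AIFModel:
    return AIFModel()


@pytest.fixture(scope="session")
def aif_t0() -> AIFModel:
    """AIF with bolus at t = 0 (smooth on any grid starting at 0)."""
    return AIFModel(t0_s=0.0)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def t_min(acq) -> np.ndarray:
    return acq.times_s() / 60.0


@pytest.fixture
def small_spec() -> PhantomSpec:
    """16×16×1 phantom with a ~0.25 mm tumor: fast but nondegenerate."""
    return PhantomSpec(grid=GridGeometry(16, 16, 1),
                       semi_axes_mm=(0.25, 0.25, 0.3), seed=1)
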