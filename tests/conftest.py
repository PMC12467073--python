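import pytest
from hypothesis import settings

from viscowork import HillParams, ViscoelasticParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tendon_kv() -> ViscoelasticParams:
    """Tendon-like Kelvin-Voigt specimen used across the reference rows."""
    return ViscoelasticParams(k=1000.0, eta=50.0)


@pytest.fixture
def muscle() -> HillParams:
    """Reference Hill muscle (fmax=100 N, a=10 N, b=0.5 m/s)."""
    return HillParams(fmax=100.0, a=10.0, b=0.5)


@pytest.fixture
def membrane_np() -> ViscoelasticParams:
    """Worked-example membrane element (k=0.010 N/m, eta=1e-6 N·s/m)."""
    return ViscoelasticParams(k=0.010, eta=1.0e-6)
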