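import numpy as np
import pytest

from nucscatter.nuclear_models import NuclearModelSpec, build_model
from nucscatter.scattering import PlaneWaveConfig, ScatteringPattern, born_far_field


@pytest.fixture(scope="session")
def default_wave():
    return PlaneWaveConfig()


@pytest.fixture(scope="session")
def homog_sphere_volume():
    """Homogeneous sphere small enough for fast solver tests (R=2 um, 0.1 um pitch)."""
    spec = NuclearModelSpec(shape_kind="sphere", R=2.0, n=1.40, n_out=1.36,
                            lc=0.7, delta_n=0.0, spacing=0.1)
    return build_model(spec)


@pytest.fixture(scope="session")
def homog_sphere_pattern(homog_sphere_volume, default_wave):
    return born_far_field(homog_sphere_volume, default_wave)


def make_pattern(intensity, solver="test") -> ScatteringPattern:
    return ScatteringPattern(intensity=np.asarray(intensity, dtype=float),
                             wave=PlaneWaveConfig(), solver=solver)


@pytest.fixture
def pattern_factory():
    return make_pattern
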