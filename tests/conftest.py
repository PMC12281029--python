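import numpy as np
import pytest

from voxview import (PhantomSpec, Primitive, Scene, WindowedLayer,
                     default_brain_like_spec, make_phantom, volume_from_array)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom():
    """The default seeded head-like phantom (32x32x24, anisotropic voxels)."""
    return make_phantom(default_brain_like_spec(seed=1))


@pytest.fixture
def ramp_volume():
    """f(i, j, k) = i on a 16^3 isotropic grid: trilinear must reproduce it."""
    data = np.fromfunction(lambda i, j, k: i, (16, 16, 16), dtype=float)
    return volume_from_array(data.astype(np.float32))


@pytest.fixture
def sphere_spec():
    return PhantomSpec(
        shape=(16, 16, 16),
        primitives=(Primitive("sphere", center=(7.5, 7.5, 7.5), radius=4,
                              intensity=100.0),),
    )


@pytest.fixture
def simple_scene(phantom):
    return Scene(base=WindowedLayer.auto(phantom))
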