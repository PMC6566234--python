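import numpy as np
import pytest

from voxreflect import PhantomSpec, TubeSpec, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_tube_spec():
    """One centered tube on a unit-spacing grid (analytically checkable)."""
    tube = TubeSpec((12.0, 12.0, 12.0), 4.0, 20.0, signal=100.0, role="test")
    return PhantomSpec(
        grid_shape=(25, 25, 25),
        spacing_mm=(1.0, 1.0, 1.0),
        tubes=(tube,),
        background_level=0.0,
        noise_sigma=0.0,
        seed=0,
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0), **kw):
    return Volume3D(np.asarray(values, dtype=float), spacing, **kw)


@pytest.fixture
def make_vol():
    return make_volume
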