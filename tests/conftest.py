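import numpy as np
import pytest

from cvi3d.io import BScan, ChoroidBoundaries, VolumeScan
from cvi3d.synth import PhantomSpec, generate_phantom_volume


def make_volume(n_scans=5, rows=40, cols=30, scale_x=0.01, scale_y=0.004,
                spacing_um=240.0, signal=30.0, seed=0):
    rng = np.random.default_rng(seed)
    scans = [
        BScan(pixels=rng.integers(0, 256, size=(rows, cols), dtype=np.uint8),
              scale_x=scale_x, scale_y=scale_y, index=i)
        for i in range(1, n_scans + 1)
    ]
    return VolumeScan(scans=scans, spacing_um=spacing_um,
                      fovea_index=n_scans // 2 + 1, signal_strength=signal,
                      eye_id="test-eye")


def flat_boundaries(n_scans=5, cols=30, upper=10, lower=30):
    return ChoroidBoundaries(
        upper=np.full((n_scans, cols), upper),
        lower=np.full((n_scans, cols), lower),
    )


@pytest.fixture
def small_volume():
    return make_volume()


@pytest.fixture
def small_boundaries():
    return flat_boundaries()


@pytest.fixture(scope="session")
def small_phantom():
    """A compact noise-free phantom shared by fast tests."""
    spec = PhantomSpec(n_scans=7, rows=120, cols=160, upper_depth=40,
                       thickness_um=250.0, target_cvi=0.6, seed=11)
    return spec, generate_phantom_volume(spec)
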