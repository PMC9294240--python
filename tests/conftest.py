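import numpy as np
import pytest

from ezseg import phantom


@pytest.fixture(scope="session")
def small_geometry():
    """A compact geometry used throughout: 9-mm field, 41 lines."""
    return phantom.ScanGeometry(n_cols=256, n_rows=256, n_lines=41)


@pytest.fixture(scope="session")
def flat_spec(small_geometry):
    """Noise-free phantom with flat surfaces at known rows."""
    return phantom.PhantomSpec.flat(
        small_geometry, rows=(50, 120, 150, 170, 180),
        ez_semi_axes_mm=(40.0, 40.0),   # EZ band over the whole field
        noise_level=0.0, noise_floor=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
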