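import numpy as np
import pytest

import dalff


@pytest.fixture(scope="session")
def atlas90():
    """Default 90-parcel mirrored atlas on the 12x14x12 toy grid."""
    return dalff.generate_atlas(90)


@pytest.fixture(scope="session")
def small_series():
    """A small deterministic 4D series for I/O and preprocessing tests."""
    rng = np.random.default_rng(0)
    data = rng.normal(size=(6, 6, 6, 40)) + 100.0
    affine = np.eye(4) * 3.0
    affine[3, 3] = 1.0
    return dalff.VolumeSeries(data=data, tr=2.0, affine=affine)
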