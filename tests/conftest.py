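import numpy as np
import pytest

from mtflim.probes import AcquisitionContext, default_hairpin_probe
from mtflim.scene import Scene


@pytest.fixture
def probe():
    return default_hairpin_probe()


@pytest.fixture
def acq():
    return AcquisitionContext()


def make_uniform_scene(
    shape=(32, 32),
    fraction_open=0.0,
    density=1.0,
    tilt_deg=0.0,
    azimuth_deg=0.0,
    pixel_size=0.1,
    seed=0,
):
    """Uniform bilayer scene helper shared by the rendering tests."""
    return Scene(
        shape=shape,
        pixel_size=pixel_size,
        density_field=np.full(shape, float(density)),
        fraction_open_field=np.full(shape, float(fraction_open)),
        tilt_field=np.full(shape, float(tilt_deg)),
        azimuth_field=np.full(shape, float(azimuth_deg)),
        podosome_truth=[],
        cluster_truth=[],
        cell_mask=np.ones(shape, dtype=bool),
        seed=seed,
    )
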