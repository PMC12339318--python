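import numpy as np
import pytest

import heflim as hf
from heflim.fitting import FitSettings, fit_cube
from heflim.synth import default_region_specs, uniform_layout


@pytest.fixture(scope="session")
def acq_small():
    """Standard timing (256 bins over one 76 MHz period) on a small raster."""
    return hf.AcquisitionConfig(image_size=(16, 16))


@pytest.fixture(scope="session")
def default_specs():
    return default_region_specs(photons_per_pixel=5000.0)


def simulate_region_image(region, shape, seed, photons=5000.0):
    """Simulate and fit one uniform-region cube; returns (cube, image, table)."""
    acq = hf.AcquisitionConfig(image_size=shape)
    specs = default_region_specs(photons)
    cube = hf.simulate_cube(uniform_layout(shape, region), specs, acq, seed)
    image, table = fit_cube(cube, settings=FitSettings())
    return cube, image, table


@pytest.fixture(scope="session")
def fitted_study():
    """Three fitted peritumoral and three cancerous images (the synthetic
    analogue of imaging three regions per tissue class), 32x32 pixels.

    Session-scoped: the fits are the slow step and several statistical tests
    consume the same study.
    """
    study = {"peritumoral": [], "cancerous": []}
    for region in study:
        for i in range(3):
            seed = 100 + i if region == "peritumoral" else 200 + i
            _, image, _ = simulate_region_image(region, (32, 32), seed)
            study[region].append(image)
    return study
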