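import numpy as np
import pytest

from tendonquant.image import CalibratedImage
from tendonquant.synthdata import (
    DabPhantomSpec, FiberPhantomSpec, NucleiPhantomSpec,
    generate_dab_phantom, generate_fiber_phantom, generate_nuclei_phantom,
)


@pytest.fixture(scope="session")
def nuclei_phantom():
    """512x512 px, 1 um/px field at 2000 nuclei/mm2 (524 nuclei), seed 7."""
    spec = NucleiPhantomSpec(
        image_size=(512, 512), pixel_size_um=1.0, target_density=2000.0, seed=7
    )
    image, truth = generate_nuclei_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def fiber_phantom_20_30_50():
    """Fiber field with mask-relative fractions exactly 20/30/50 percent."""
    spec = FiberPhantomSpec(
        image_size=(100, 100), fraction_green=0.2, fraction_yellow=0.3,
        fraction_red=0.5, fraction_background=0.0, seed=11,
    )
    image, truth = generate_fiber_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def dab_phantom_35():
    """200x200 px DAB field, 35% positive, mild OD noise."""
    spec = DabPhantomSpec(
        image_size=(200, 200), positive_fraction=0.35, noise_sd=0.02, seed=13
    )
    image, truth = generate_dab_phantom(spec)
    return spec, image, truth


@pytest.fixture()
def white_image():
    px = np.full((32, 32, 3), 255, dtype=np.uint8)
    return CalibratedImage(px, 1.0, "brightfield")


@pytest.fixture()
def black_polarized():
    px = np.zeros((32, 32, 3), dtype=np.uint8)
    return CalibratedImage(px, 1.0, "polarized")
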