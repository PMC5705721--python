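import numpy as np
import pytest

from ermech.chains import FiberChain, resample_polyline
from ermech.synthetic import RenderParams, render_image


@pytest.fixture(scope="session")
def sinusoid_chain() -> FiberChain:
    """Sinusoidal tube backbone: amplitude 1 um, period 8 um, length 16 um."""
    x = np.linspace(0.0, 16.0, 321)
    y = np.sin(2.0 * np.pi * x / 8.0)
    return FiberChain(resample_polyline(np.stack([x, y], 1), 0.05), 0.05)


@pytest.fixture(scope="session")
def sinusoid_render(sinusoid_chain):
    """Diffraction-limited rendering of the sinusoidal tube at SNR ~ 6."""
    params = RenderParams(
        pixel_size=0.1,
        psf_sigma=0.125,
        tube_outer_radius=44.1,
        wall_thickness=0.0,
        photon_peak=50,
        background=10,
        noise_model="poisson",
        seed=2,
    )
    image, gt = render_image(sinusoid_chain, params)
    return image, gt, params


@pytest.fixture(scope="session")
def straight_chain() -> FiberChain:
    x = np.linspace(0.0, 4.0, 81)
    return FiberChain(np.stack([x, np.zeros_like(x)], 1), 0.05)
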