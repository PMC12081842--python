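import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elastigate.imaging import DensityImage
from elastigate.model import PlotSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def gaussian_blob_image(size: int, cx: float, cy: float, sigma: float) -> DensityImage:
    """Quantized Gaussian blob used as a registration fixture."""
    jj, ii = np.meshgrid(np.arange(size), np.arange(size))
    g = np.exp(-(((jj - cx) ** 2 + (ii - cy) ** 2) / (2.0 * sigma ** 2)))
    gray = np.rint(255 * g).astype(np.uint8)
    return DensityImage(gray, PlotSpec("x", "y", size, size), 0, 256)


def gaussian_peak_hist(size: int, centre: float, sigma: float) -> DensityImage:
    x = np.arange(size)
    g = np.exp(-(((x - centre) ** 2) / (2.0 * sigma ** 2)))
    gray = np.rint(255 * g).astype(np.uint8)
    return DensityImage(gray, PlotSpec("x", None, size, 16), 0, 256)


@pytest.fixture(scope="session")
def blob_256():
    return gaussian_blob_image(256, 128.0, 128.0, 12.0)


@pytest.fixture(scope="session")
def blob_256_shifted():
    return gaussian_blob_image(256, 133.0, 128.0, 12.0)


@pytest.fixture(scope="session")
def shift_registration(blob_256, blob_256_shifted):
    """Default-config registration of the 5 px-shifted blob pair, shared
    by the tests that probe different properties of the same solution."""
    from elastigate.registration import register

    return register(blob_256, blob_256_shifted)


@pytest.fixture(scope="session")
def scatter_fixture():
    """Small scatter panel: training sample + template + 3 drifted targets."""
    from elastigate.synth import generate_panel, scatter_panel

    spec = scatter_panel(seed=7, n_samples=4)
    training, template, targets = generate_panel(spec, 4)
    return spec, training, template, targets
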