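import numpy as np
import pytest

from sweclip.colormap import ColormapSpec, ElasticityScale
from sweclip.synthetic import SyntheticClipConfig, render_clip

TWO_STOP = ColormapSpec(stops=((0.0, (0, 0, 255)), (1.0, (255, 0, 0))))


@pytest.fixture(scope="session")
def default_cmap():
    return ColormapSpec()


@pytest.fixture(scope="session")
def scale300():
    return ElasticityScale(300.0)


@pytest.fixture(scope="session")
def small_config():
    """A compact clip layout used throughout the suite (10 x 16 mm elastogram)."""
    return SyntheticClipConfig(
        height=200, width=300,
        box=(40, 140, 70, 230),
        ruler_region=(40, 160, 15, 35),
        colorbar_region=(40, 141, 260, 282),
        n_frames=3, seed=42,
    )


@pytest.fixture(scope="session")
def small_clip(small_config):
    """Rendered frames plus ground-truth fields for the compact layout."""
    return render_clip(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
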