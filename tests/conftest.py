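import numpy as np
import pytest

from txlive import simgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_spot_scene():
    """One noiseless Gaussian spot at a sub-pixel position."""
    scene = simgen.GroundTruthScene(
        shape=(80, 80), background=5.0,
        spots=[simgen.SpotTruth(frame=0, channel=0, y_px=50.3, x_px=20.7,
                                amplitude=100.0, psf_sigma_px=1.5)],
    )
    return scene, simgen.render_scene(scene)[0, 0]
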