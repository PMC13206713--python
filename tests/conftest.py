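import numpy as np
import pytest

from choromap import quant, synthetic


@pytest.fixture(scope="session")
def noiseless_cube():
    """Full 61-B-scan noiseless bimodal cube (lumen fraction 0.65, no shadows).

    Returns (volume, truth, grid): the exactness oracle for binarization and
    grid aggregation.
    """
    scene = synthetic.SceneParams(
        lumen_fraction=0.65, noise_sd=0.0, n_shadow_columns=0, seed=7)
    volume, truth = synthetic.generate_volume(scene)
    grid = quant.quantify_volume(volume)
    return volume, truth, grid


@pytest.fixture(scope="session")
def noisy_cube():
    """Full cube with speckle-like noise (sd 20) and retinal-vessel shadows."""
    scene = synthetic.SceneParams(lumen_fraction=0.5, noise_sd=20.0, seed=11)
    volume, truth = synthetic.generate_volume(scene)
    grid = quant.quantify_volume(volume)
    return volume, truth, grid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
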