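import numpy as np
import pytest

from gutchol import calibrate


@pytest.fixture(scope="session")
def calib():
    """Default calibration with the saturating BS-synthesis retro-control
    (the variant used for the model-exploration results)."""
    return calibrate(hbs_feedback="saturating")


@pytest.fixture(scope="session")
def calib_printed():
    """Calibration with the bilinear BS-synthesis term exactly as printed
    in the balance equations."""
    return calibrate(hbs_feedback="as_printed")


@pytest.fixture(scope="session")
def params(calib):
    return calib.params


@pytest.fixture(scope="session")
def d8_assays():
    from gutchol import NoiseSpec, gen_growth_assay
    return gen_growth_assay("d8", noise=NoiseSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)
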