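import numpy as np
import pytest

from pvretina.materials import blend_dispersion, gold_dispersion
from pvretina.photocurrent import (
    TRIPLE_R10_I026,
    ActiveLayerSpec,
    IlluminationSpec,
    calibrate_kappa,
)
from pvretina.plasmonics import NanoparticleSpec


@pytest.fixture(scope="session")
def gold():
    return gold_dispersion()


@pytest.fixture(scope="session")
def blend():
    return blend_dispersion()


@pytest.fixture(scope="session")
def np10(gold, blend):
    return NanoparticleSpec(10.0, gold, blend)


@pytest.fixture(scope="session")
def base_layer(blend):
    return ActiveLayerSpec(blend=blend)


@pytest.fixture(scope="session")
def gain_r10(base_layer, np10):
    gain, _ = calibrate_kappa(
        TRIPLE_R10_I026, IlluminationSpec(610.0, 0.26), base_layer, np10
    )
    return gain


@pytest.fixture(scope="session")
def threshold_result():
    """Full-resolution cathodic threshold search (shared: ~10 s)."""
    from pvretina.neuro import find_threshold

    return find_threshold()
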