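import numpy as np
import pytest

from odornav import neural_models as nm
from odornav import odor_field as of
from odornav import synthetic as syn


@pytest.fixture(scope="session")
def published_field() -> of.GradientParams:
    """The fitted 2-nonanone gradient constants with the default sources."""
    return of.GradientParams()


@pytest.fixture(scope="session")
def stim_up_90() -> of.ConcentrationSeries:
    return syn.gen_stimulus_program("up", 90)


@pytest.fixture(scope="session")
def stim_down_90() -> of.ConcentrationSeries:
    return syn.gen_stimulus_program("down", 90)


@pytest.fixture(scope="session")
def stim_down_45() -> of.ConcentrationSeries:
    return syn.gen_stimulus_program("down", 45)
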