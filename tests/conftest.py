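import numpy as np
import pytest

from replisim.reaction_core import Form, KineticParams, Role
from replisim.surface_ca import (Grid, PopulationSpec, SurfaceScenario,
                                 initialize_surface)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_params():
    """No mutations, default kinetics."""
    return KineticParams()


@pytest.fixture
def selfrep_spec():
    return [PopulationSpec(Role.Rp, Form.RNA, 0.4, 0.0, 1.0)]


@pytest.fixture
def transcription_spec():
    return [PopulationSpec(Role.Rp, Form.RNA, 0.0, 1.0, 0.25),
            PopulationSpec(Role.Rp, Form.DNA, 0.0, 1.0, 0.25),
            PopulationSpec(Role.Dp, Form.RNA, 0.0, 1.0, 0.25),
            PopulationSpec(Role.Dp, Form.DNA, 0.0, 1.0, 0.25)]


@pytest.fixture
def small_selfrep_grid(quiet_params, selfrep_spec):
    sc = SurfaceScenario(48, 48, 0.3, selfrep_spec, quiet_params, seed=7)
    return initialize_surface(sc)


def make_grid(width=32, height=32, density=0.0, composition=(),
              params=None, seed=0, wellmixed=False, bands=None):
    params = params or KineticParams()
    sc = SurfaceScenario(width, height, density, list(composition), params,
                         seed=seed, wellmixed=wellmixed, bands=bands)
    return initialize_surface(sc)
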