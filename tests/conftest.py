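import numpy as np
import pytest

from pgrange import (
    BeamConfig,
    CameraGeometry,
    DetectorResponse,
    EmissionModel,
    RunConfig,
    generate_events,
    select_compton_events,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return RunConfig(seed=1)


def make_noiseless_config(seed: int = 5, point_source: bool = False) -> RunConfig:
    """Config with no energy smearing and no background; optionally a
    point source at the Bragg-peak depth on the beam axis."""
    cfg = RunConfig(seed=seed)
    cfg.response.fwhm_frac_at_662 = 0.0
    cfg.response.background_fraction = 0.0
    cfg.emission.plateau_fraction = 0.0
    if point_source:
        cfg.beam.lateral_sigma = 1e-12
        cfg.emission.peak_sigma = 0.0
    return cfg


@pytest.fixture
def noiseless_config():
    return make_noiseless_config()


@pytest.fixture
def noiseless_events(noiseless_config):
    """~180 selected noiseless Compton events from the default beam."""
    cfg = noiseless_config
    rng = np.random.default_rng(cfg.seed)
    groups = generate_events(cfg.beam, cfg.geometry, cfg.emission,
                             cfg.response, 200, rng)
    return select_compton_events(groups)
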