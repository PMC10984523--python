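import numpy as np
import pytest

from crcburden import config as cfgmod
from crcburden.impact import DelayImpactParams, SurvivalModel
from crcburden.natural_history import ParticipationSeries
from crcburden.scenarios import RunConfig

HORIZON = 396  # Jan 2018 .. Dec 2050


@pytest.fixture(scope="session")
def default_cfg():
    return cfgmod.load_config()


@pytest.fixture(scope="session")
def small_params(default_cfg):
    """A small cohort for fast unit tests."""
    return cfgmod.population_params(default_cfg, seed=0).__class__(
        **{**default_cfg["population"], "cohort_size": 8000}
    )


@pytest.fixture(scope="session")
def survival():
    return SurvivalModel.exponential_from_5yr()


@pytest.fixture()
def impact_params():
    return DelayImpactParams()


@pytest.fixture(scope="session")
def small_run_config(default_cfg, survival):
    cfg = cfgmod.run_config(default_cfg)
    cfg.population = cfgmod.population_params(
        {**default_cfg, "population": {**default_cfg["population"], "cohort_size": 8000}}
    )
    return cfg


@pytest.fixture()
def unit_participation():
    return ParticipationSeries.constant(1.0, HORIZON)
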