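import numpy as np
import pytest

from harvestlab.ibm import (
    FecundityParams,
    GrowthParams,
    MaturationParams,
    PopulationState,
    SimConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """No mortality, no growth, no reproduction: nothing happens by itself."""
    return SimConfig(
        natural_mortality_week=0.0,
        growth=GrowthParams(c=0.0),
        maturation=MaturationParams(lp50_mm=1e9, deterministic=True),
        fecundity=FecundityParams(intercept=-100.0, length_slope=0.0),
        growth_density_exponent=0.0,
    )


def make_state(lengths, sexes=None, mature=None, config=None):
    """Hand-build a population from explicit lengths."""
    cfg = config or SimConfig()
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    if sexes is None:
        sexes = np.zeros(n, dtype=np.int8)
    if mature is None:
        mature = np.zeros(n, dtype=bool)
    state = PopulationState()
    state.add(np.asarray(sexes, dtype=np.int8), np.zeros(n), lengths,
              cfg.growth.weight_from_length(lengths), np.asarray(mature, dtype=bool))
    return state


@pytest.fixture
def make_population():
    return make_state
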